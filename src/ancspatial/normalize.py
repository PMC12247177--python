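"""Ordered-quantile (rank inverse-normal) response transform.

Areal prevalence proportions are bounded and typically heavily skewed,
which violates the Gaussian error assumption of an identity-link
geo-additive model.  The ordered-quantile normalizing transform maps the
observed values to normal scores through their ranks,

    z_r = Phi^{-1}((r - c) / (n - 2c + 1)),   c = 0.5 by default,

with ties receiving the score of their average rank.  New values are
transformed by monotone piecewise-linear interpolation between the
(observed value, score) pairs, with linear extrapolation from the two
extreme pairs beyond the training range, so the transform is invertible
on (and beyond) the observed values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TransformModel", "fit_rank_normal"]


@dataclass
class TransformModel:
    """Fitted rank-normal transform (a monotone piecewise-linear map).

    ``sorted_originals`` and ``normal_scores`` are matched ascending
    arrays of the unique training values and their normal scores.
    """

    sorted_originals: np.ndarray
    normal_scores: np.ndarray
    offset: float
    n: int

    def transform(self, y_new) -> np.ndarray:
        """Map values to the normal-score scale (monotone, extrapolating)."""
        return _interp_extrap(
            np.asarray(y_new, dtype=float), self.sorted_originals, self.normal_scores
        )

    def inverse_transform(self, z) -> np.ndarray:
        """Map normal scores back to the original scale."""
        return _interp_extrap(
            np.asarray(z, dtype=float), self.normal_scores, self.sorted_originals
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sorted_originals": self.sorted_originals.tolist(),
                "normal_scores": self.normal_scores.tolist(),
                "offset": self.offset,
                "n": self.n,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransformModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["sorted_originals"], dtype=float),
            np.asarray(d["normal_scores"], dtype=float),
            float(d["offset"]),
            int(d["n"]),
        )


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp plus linear extrapolation from the extreme segments."""
    if xp.size == 1:
        return np.full_like(x, fp[0])
    out = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        out[lo] = fp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        out[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return out


def fit_rank_normal(y, offset: float = 0.5) -> TransformModel:
    """Fit the ordered-quantile normalizing transform.

    Parameters
    ----------
    y : array-like
        Training values, n >= 3, not all equal.
    offset : float in (0, 1)
        Plotting-position constant c in ``(r - c) / (n - 2c + 1)``;
        0.5 by default, 0.375 gives the Blom variant.

    Returns
    -------
    TransformModel
        Round-trips its training data exactly (to floating precision):
        ``model.inverse_transform(model.transform(y)) == y``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    if np.all(y == y[0]):
        raise ValueError("constant vector cannot be normalized")
    if not 0.0 < offset < 1.0:
        raise ValueError("offset must lie in (0, 1)")

    ranks = stats.rankdata(y, method="average")
    scores = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))

    # collapse to unique (value, score) knots; ties share one average-rank
    # score, so the knot map stays strictly increasing
    order = np.argsort(y, kind="stable")
    uniq_vals, first = np.unique(y[order], return_index=True)
    uniq_scores = scores[order][first]
    return TransformModel(uniq_vals, uniq_scores, float(offset), n)
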