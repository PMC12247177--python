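"""Model comparison and predictive calibration for Gaussian MCMC fits.

Implements the deviance-based and fully Bayesian criteria used to pick
among geo-additive model variants, all computed from the S x N matrix of
per-draw, per-observation Gaussian log-densities:

* **DIC** — ``Dbar + pD`` with ``pD = Dbar - D(thetabar)``, the plug-in
  evaluated at the posterior means of the fitted values and of tau_eps;
* **WAIC** — ``-2 (lppd - pWAIC)`` with the variance-based penalty
  ``pWAIC = sum_i var_s log p(y_i | theta_s)``;
* **CPO** — the conditional predictive ordinate, a leave-one-out
  predictive density per observation estimated by the harmonic mean of
  per-draw densities; reported as ``sum_i log CPO_i`` (larger is better);
* **PIT** — the probability integral transform, uniform on [0, 1] under
  a calibrated predictive distribution, tested by Kolmogorov-Smirnov.

Smaller DIC/WAIC and larger sum-log-CPO indicate better predictive fit;
:func:`compare` ranks models by DIC, then WAIC, then sum-log-CPO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from ancspatial.model import GibbsFit

__all__ = [
    "CriteriaReport",
    "pointwise_loglik",
    "dic",
    "waic",
    "cpo",
    "pit",
    "evaluate_fit",
    "compare",
]

_LOG_2PI = np.log(2.0 * np.pi)


def pointwise_loglik(fit: GibbsFit) -> np.ndarray:
    """S x N matrix of per-draw, per-observation Gaussian log-densities.

    Entry (s, i) = log N(y_i | eta_i^(s), var^(s)) with the structural
    predictor eta (beta, smooths, structured effect) and predictive
    variance 1/tau_eps^(s), plus 1/tau_v^(s) when the model has an
    unstructured i.i.d. effect.  Integrating v out of the pointwise
    density is deliberate: with one observation per unit, conditioning
    on v rewards interpolation and makes DIC/WAIC/CPO favor whichever
    model drifts furthest along the unidentified v-vs-noise ridge,
    whereas the marginal density depends only on identified quantities.
    """
    fitted = fit.fitted_draws(include_v=False)
    var = fit.predictive_variance_draws()[:, None]
    resid2 = (fit.y[None, :] - fitted) ** 2
    return -0.5 * (np.log(var) + _LOG_2PI + resid2 / var)


def dic(loglik: np.ndarray, loglik_at_mean: np.ndarray) -> tuple[float, float]:
    """Deviance information criterion.

    Parameters
    ----------
    loglik : (S, N) per-draw pointwise log-likelihood
    loglik_at_mean : (N,) pointwise log-likelihood at the plug-in
        (posterior-mean fitted values and posterior-mean tau_eps)

    Returns
    -------
    (DIC, pD)
        ``pD = Dbar - D(thetabar)`` may come out negative for badly
        behaved posteriors; it is returned as computed, not clipped.
    """
    _check_draws(loglik)
    dbar = float(-2.0 * loglik.sum(axis=1).mean())
    dhat = float(-2.0 * np.asarray(loglik_at_mean).sum())
    pd_ = dbar - dhat
    return dbar + pd_, pd_


def plugin_loglik(fit: GibbsFit) -> np.ndarray:
    """Pointwise log-likelihood at the plug-in: posterior-mean structural
    predictor and posterior-mean predictive variance (DIC's D(thetabar))."""
    fitted = fit.fitted_draws(include_v=False).mean(axis=0)
    var = float(fit.predictive_variance_draws().mean())
    return -0.5 * (np.log(var) + _LOG_2PI + (fit.y - fitted) ** 2 / var)


def waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion.

    Returns ``(WAIC, pWAIC, lppd)`` with
    ``lppd = sum_i log mean_s exp loglik[s, i]`` (log-sum-exp stabilized)
    and ``pWAIC = sum_i var_s loglik[s, i]``.  Observations whose
    pointwise variance exceeds 0.4 make the penalty unreliable and
    trigger a warning.
    """
    _check_draws(loglik)
    s = loglik.shape[0]
    lppd_i = logsumexp(loglik, axis=0) - np.log(s)
    p_i = loglik.var(axis=0, ddof=1)
    n_bad = int((p_i > 0.4).sum())
    if n_bad:
        import warnings

        warnings.warn(
            f"WAIC penalty unreliable for {n_bad} observation(s) "
            "(pointwise loglik variance > 0.4)",
            stacklevel=2,
        )
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return -2.0 * (lppd - p_waic), p_waic, lppd


def cpo(loglik: np.ndarray) -> tuple[np.ndarray, float]:
    """Conditional predictive ordinates via the harmonic-mean identity.

    ``CPO_i = [mean_s exp(-loglik[s, i])]^{-1}`` computed in log space.
    Returns the per-observation CPO vector and ``sum_i log CPO_i``.
    Observations with numerically vanishing CPO are reported in the
    warning rather than silently dropped.
    """
    _check_draws(loglik)
    s = loglik.shape[0]
    log_cpo = -(logsumexp(-loglik, axis=0) - np.log(s))
    if not np.isfinite(log_cpo).all():
        import warnings

        bad = np.flatnonzero(~np.isfinite(log_cpo)).tolist()
        warnings.warn(f"numerically zero CPO for observation(s) {bad}", stacklevel=2)
    return np.exp(log_cpo), float(log_cpo.sum())


def pit(fit: GibbsFit, method: str = "conditional") -> tuple[np.ndarray, float, float]:
    """Probability integral transform per observation plus uniformity test.

    ``PIT_i = mean_s Phi((y_i - eta_i^(s)) / sd^(s))``: the posterior-
    predictive probability that a replicate falls below the observed
    value, using the marginal predictive (structural predictor, i.i.d.
    effect integrated into the variance).  Under a well-calibrated model
    the PIT values are approximately U(0, 1).

    ``method="loo"`` reweights draws by importance weights 1/p(y_i |
    theta_s) (harmonic-mean style) to approximate the leave-one-out PIT;
    noisier, but closer to a cross-validated diagnostic.

    Returns ``(pit_values, ks_distance, ks_pvalue)`` from a
    Kolmogorov-Smirnov test against uniformity.
    """
    fitted = fit.fitted_draws(include_v=False)
    sd = np.sqrt(fit.predictive_variance_draws())[:, None]
    cdf = stats.norm.cdf((fit.y[None, :] - fitted) / sd)
    if method == "conditional":
        pit_vals = cdf.mean(axis=0)
    elif method == "loo":
        logw = -pointwise_loglik(fit)
        logw -= logw.max(axis=0, keepdims=True)
        w = np.exp(logw)
        pit_vals = (w * cdf).sum(axis=0) / w.sum(axis=0)
    else:
        raise ValueError("method must be 'conditional' or 'loo'")
    ks = stats.kstest(pit_vals, "uniform")
    return pit_vals, float(ks.statistic), float(ks.pvalue)


@dataclass
class CriteriaReport:
    """All comparison criteria for one fitted model."""

    model: str
    sum_log_cpo: float
    dic: float
    p_d: float
    waic: float
    p_waic: float
    lppd: float
    pit_values: np.ndarray = field(repr=False, default=None)
    ks_distance: float = float("nan")
    ks_pvalue: float = float("nan")
    n_obs: int = 0
    #: fingerprint of the response vector, used to refuse cross-data comparison
    data_key: tuple = ()

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "sum_log_cpo": self.sum_log_cpo,
            "DIC": self.dic,
            "pD": self.p_d,
            "WAIC": self.waic,
            "pWAIC": self.p_waic,
            "lppd": self.lppd,
            "KS_distance": self.ks_distance,
            "KS_pvalue": self.ks_pvalue,
        }


def evaluate_fit(fit: GibbsFit, name: str | None = None, with_pit: bool = True) -> CriteriaReport:
    """Compute DIC, WAIC, CPO (and optionally PIT) for one fit."""
    ll = pointwise_loglik(fit)
    d, p_d = dic(ll, plugin_loglik(fit))
    w, p_w, lppd = waic(ll)
    _, slc = cpo(ll)
    pit_vals, ks_d, ks_p = (None, float("nan"), float("nan"))
    if with_pit:
        pit_vals, ks_d, ks_p = pit(fit)
    y = np.asarray(fit.y, dtype=float)
    return CriteriaReport(
        model=name or fit.spec.variant,
        sum_log_cpo=slc,
        dic=d,
        p_d=p_d,
        waic=w,
        p_waic=p_w,
        lppd=lppd,
        pit_values=pit_vals,
        ks_distance=ks_d,
        ks_pvalue=ks_p,
        n_obs=y.size,
        data_key=(y.size, float(y.sum()), float((y**2).sum())),
    )


def compare(reports: list[CriteriaReport]) -> pd.DataFrame:
    """Rank models: DIC ascending, then WAIC ascending, then CPO descending.

    All reports must refer to the same response data; exact ties on every
    criterion are reported explicitly via the ``tied_with_best`` column.
    """
    if not reports:
        raise ValueError("no models to compare")
    keys = {r.data_key for r in reports}
    if len(keys) > 1:
        raise ValueError("criteria were computed on differing data; refusing to rank")
    rows = pd.DataFrame([r.as_row() for r in reports])
    rows = rows.sort_values(
        ["DIC", "WAIC", "sum_log_cpo"], ascending=[True, True, False], kind="stable"
    ).reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    best = rows.iloc[0]
    rows["best"] = rows["rank"] == 1
    rows["tied_with_best"] = (
        (rows["DIC"] == best["DIC"])
        & (rows["WAIC"] == best["WAIC"])
        & (rows["sum_log_cpo"] == best["sum_log_cpo"])
    )
    return rows


def _check_draws(loglik: np.ndarray) -> None:
    loglik = np.asarray(loglik)
    if loglik.ndim != 2:
        raise ValueError("pointwise log-likelihood must be an S x N matrix")
    if loglik.shape[0] < 1:
        raise ValueError("no draws supplied")
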