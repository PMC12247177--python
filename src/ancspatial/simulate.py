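"""Synthetic areal scenarios with known truth.

Generates lattice datasets with exactly the structure the geo-additive
model assumes — an iCAR-distributed structured spatial field, an i.i.d.
unstructured field, linear fixed effects, nonlinear smooth covariate
effects, and Gaussian or binomial observation noise — so that every
stage of the pipeline (aggregation, autocorrelation tests, normalizing
transform, Gibbs fitting, criteria) can be validated end to end against
stored ground truth.

The smooth library is fixed to four named shapes on [0, 1], each centred
to mean zero over a dense grid so it is comparable to the model's
sum-to-zero smooth coefficients:

* ``sinusoid``    — sin(2 pi x)
* ``quadratic``   — 4 (x - 0.5)^2 - 1/3
* ``changepoint`` — flat at zero below x = 0.5, slope 4 above (centred)
* ``flat``        — identically zero
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ancspatial.graphs import SpatialGraph, lattice_graph
from ancspatial.model import icar_structure
from ancspatial.regions import RegionTable

__all__ = [
    "SMOOTH_LIBRARY",
    "SyntheticScenario",
    "sample_icar_field",
    "make_scenario",
    "make_table_like",
    "lattice_polygons",
]


def _sinusoid(x):
    return np.sin(2.0 * np.pi * x)


def _quadratic(x):
    return 4.0 * (x - 0.5) ** 2 - 1.0 / 3.0


def _changepoint(x):
    raw = np.where(x > 0.5, 4.0 * (x - 0.5), 0.0)
    return raw - 0.5  # mean of raw over U(0,1) is 0.5

def _flat(x):
    return np.zeros_like(np.asarray(x, dtype=float))


SMOOTH_LIBRARY = {
    "sinusoid": _sinusoid,
    "quadratic": _quadratic,
    "changepoint": _changepoint,
    "flat": _flat,
}


@dataclass
class SyntheticScenario:
    """A generated dataset plus the ground truth that produced it."""

    graph: SpatialGraph
    table: RegionTable
    truth: dict
    seed: int | None
    observation_model: str  # "gaussian" | "binomial"

    @property
    def y(self) -> np.ndarray:
        """Gaussian response (only for observation_model='gaussian')."""
        return self.table.df["y"].to_numpy(float)


def sample_icar_field(graph: SpatialGraph, tau_u: float, seed=None) -> np.ndarray:
    """Draw a zero-mean intrinsic CAR field on a graph.

    The iCAR density is proportional to ``exp(-tau_u/2 * u' Q u)`` with
    ``Q = D - A``, improper along the per-component constant directions.
    Sampling is by eigendecomposition of Q with the null directions
    removed, i.e. a proper Gaussian on the sum-to-zero subspace, followed
    by exact per-component recentring.
    """
    if tau_u <= 0:
        raise ValueError("tau_u must be positive")
    rng = np.random.default_rng(seed)
    q = icar_structure(graph)
    vals, vecs = np.linalg.eigh(q)
    keep = vals > 1e-9 * vals.max()
    z = rng.standard_normal(int(keep.sum()))
    u = vecs[:, keep] @ (z / np.sqrt(tau_u * vals[keep]))
    for comp in graph.components():
        u[comp] -= u[comp].mean()
    return u


def make_scenario(
    rows: int = 15,
    cols: int = 15,
    beta: tuple = (0.5, 1.0),
    smooth_menu: tuple = ("sinusoid",),
    tau_u: float = 1.0,
    tau_v: float = 10.0,
    sigma_eps: float = 0.5,
    observation_model: str = "gaussian",
    n_trials: int = 1000,
    seed=None,
    contiguity: str = "rook",
) -> SyntheticScenario:
    """Generate one lattice scenario from the geo-additive model.

    Parameters
    ----------
    rows, cols : lattice dimensions (rows * cols >= 16 units)
    beta : (intercept, slope_1, slope_2, ...) — one linear covariate per
        slope, each drawn Uniform(0, 1) per unit
    smooth_menu : names from :data:`SMOOTH_LIBRARY`; one smooth covariate
        (Uniform(0, 1)) per entry
    tau_u, tau_v : precisions of the structured (iCAR) and unstructured
        (i.i.d.) spatial effects
    sigma_eps : observation noise sd (Gaussian model)
    observation_model : "gaussian" (y = eta + eps) or "binomial"
        (events ~ Binomial(n_trials, logistic(eta)); the table then
        carries counts that mimic survey-style prevalence data)
    seed : RNG seed; a fixed seed makes the scenario bit-reproducible

    Returns
    -------
    SyntheticScenario
        ``table`` has ``unit_id``, covariate columns ``x1..`` (linear)
        and ``s1..`` (smooth), plus ``y`` or ``events``/``sample``;
        ``truth`` stores beta, the smooth curves on a grid, the u and v
        fields and all variance parameters.
    """
    if rows * cols < 16:
        raise ValueError("lattice must have at least 16 units")
    unknown = [name for name in smooth_menu if name not in SMOOTH_LIBRARY]
    if unknown:
        raise ValueError(
            f"unknown smooth shape(s) {unknown}; library: {sorted(SMOOTH_LIBRARY)}"
        )
    if observation_model not in ("gaussian", "binomial"):
        raise ValueError("observation_model must be 'gaussian' or 'binomial'")

    rng = np.random.default_rng(seed)
    graph = lattice_graph(rows, cols, contiguity=contiguity)
    n = graph.n
    beta = np.asarray(beta, dtype=float)
    intercept, slopes = beta[0], beta[1:]

    eta = np.full(n, intercept)
    df = pd.DataFrame({"unit_id": graph.node_ids})
    for i, b in enumerate(slopes, start=1):
        x = rng.uniform(size=n)
        df[f"x{i}"] = x
        eta = eta + b * (x - 0.5)  # centred so the intercept is the mean level

    grid = np.linspace(0.0, 1.0, 101)
    smooth_truth = {}
    for i, name in enumerate(smooth_menu, start=1):
        x = rng.uniform(size=n)
        fn = SMOOTH_LIBRARY[name]
        df[f"s{i}"] = x
        eta = eta + fn(x)
        smooth_truth[f"s{i}"] = {"shape": name, "grid": grid, "curve": fn(grid)}

    u = sample_icar_field(graph, tau_u, seed=rng) if tau_u else np.zeros(n)
    v = rng.normal(scale=1.0 / np.sqrt(tau_v), size=n) if tau_v else np.zeros(n)
    eta = eta + u + v

    if observation_model == "gaussian":
        yv = eta + rng.normal(scale=sigma_eps, size=n)
        df["y"] = yv
        # counts kept for container validity; the Gaussian response is `y`
        df["sample"] = 1
        df["events"] = 0
    else:
        prob = 1.0 / (1.0 + np.exp(-eta))
        df["sample"] = n_trials
        df["events"] = rng.binomial(n_trials, prob)

    table = RegionTable(df)
    truth = {
        "beta": beta,
        "smooths": smooth_truth,
        "u": u,
        "v": v,
        "tau_u": tau_u,
        "tau_v": tau_v,
        "sigma_eps": sigma_eps,
        "eta": eta,
    }
    return SyntheticScenario(
        graph=graph, table=table, truth=truth, seed=seed,
        observation_model=observation_model,
    )


def make_table_like(n_countries: int = 34, seed=None) -> RegionTable:
    """Pseudo country-level survey table with realistic heterogeneity.

    Mimics the structure of a multi-country DHS prevalence summary:
    sample sizes between 1,000 and 20,000 women, survey years spanning
    2010-2023, and event probabilities spanning 0.002-0.8 (log-uniform,
    matching the wide spread of observed country proportions).
    """
    if n_countries < 2:
        raise ValueError("need at least 2 countries")
    rng = np.random.default_rng(seed)
    sample = rng.integers(1_000, 20_001, size=n_countries)
    years = rng.integers(2010, 2024, size=n_countries)
    prob = np.exp(rng.uniform(np.log(0.002), np.log(0.8), size=n_countries))
    events = rng.binomial(sample, prob)
    df = pd.DataFrame(
        {
            "unit_id": [f"country{i:02d}" for i in range(n_countries)],
            "country": [f"country{i:02d}" for i in range(n_countries)],
            "survey_year": years,
            "sample": sample,
            "events": events,
        }
    )
    table = RegionTable(df)
    table.extra["true_prob"] = prob
    return table


def lattice_polygons(graph: SpatialGraph) -> dict:
    """Unit-square polygons for a lattice graph (GeoJSON-ready geometry)."""
    from shapely.geometry import box

    rows = graph.meta.get("rows")
    cols = graph.meta.get("cols")
    if rows is None or cols is None:
        raise ValueError("graph does not carry lattice metadata")
    out = {}
    for i in range(rows):
        for j in range(cols):
            out[f"r{i}c{j}"] = box(j, -i - 1, j + 1, -i)
    return out
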