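import numpy as np
import pandas as pd
import pytest

from ancspatial import RegionTable, lattice_graph
from ancspatial.model import (
    LATENT_RIDGE,
    ModelSpec,
    build_designs,
    gibbs_fit,
    icar_full_conditional_check,
    icar_structure,
    predict,
    rw2_structure,
    summarize,
)
from ancspatial.simulate import make_scenario


def _gaussian_table(y, covs=None):
    n = len(y)
    df = pd.DataFrame({"unit_id": [f"u{i}" for i in range(n)], "sample": 1, "events": 0, "y": y})
    for name, x in (covs or {}).items():
        df[name] = x
    return RegionTable(df)


class TestModelSpec:
    def test_bym_requires_graph(self):
        with pytest.raises(ValueError, match="graph"):
            ModelSpec("bym")

    def test_covariate_in_both_roles_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ModelSpec("additive_fixed", linear_terms=["x"], smooth_terms={"x": 10})

    def test_smooth_list_defaults_to_20_bins(self):
        spec = ModelSpec("additive_fixed", smooth_terms=["a", "b"])
        assert spec.smooth_terms == {"a": 20, "b": 20}


class TestDesigns:
    def test_incidence_one_hot_and_structure_ranks(self):
        rng = np.random.default_rng(0)
        n = 120
        covs = {f"s{j}": rng.uniform(size=n) * 100 for j in range(1, 4)}
        table = _gaussian_table(rng.normal(size=n), covs)
        spec = ModelSpec("additive_fixed", smooth_terms={k: 20 for k in covs})
        d = build_designs(table, spec)
        assert len(d.A) == 3
        for a in d.A.values():
            assert a.shape[0] == n
            assert np.all(a.sum(axis=1) == 1)  # exactly one bin per row
        for k in d.K.values():
            b = k.shape[0]
            assert np.linalg.matrix_rank(k) == b - 2

    def test_icar_rank_connected(self):
        g = lattice_graph(5, 5)
        q = icar_structure(g)
        assert np.linalg.matrix_rank(q) == 24
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_rw2_null_space(self):
        k = rw2_structure(20)
        b = np.arange(20.0)
        assert np.allclose(k @ np.ones(20), 0.0)
        assert np.allclose(k @ b, 0.0)

    def test_zero_variance_covariate_named(self):
        table = _gaussian_table(np.random.default_rng(1).normal(size=20),
                                {"flatcov": np.full(20, 7.0)})
        with pytest.raises(ValueError, match="flatcov"):
            build_designs(table, ModelSpec("linear_fixed", linear_terms=["flatcov"]))

    def test_graph_table_mismatch_listed(self):
        rng = np.random.default_rng(2)
        table = _gaussian_table(rng.normal(size=9))
        g = lattice_graph(3, 3)  # node labels r0c0... != u0...
        with pytest.raises(ValueError, match="mismatch"):
            build_designs(table, ModelSpec("bym", graph=g))

    def test_linear_covariates_standardized(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(10, 90, size=50)
        table = _gaussian_table(rng.normal(size=50), {"x1": x})
        d = build_designs(table, ModelSpec("linear_fixed", linear_terms=["x1"]))
        assert d.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert d.X[:, 1].std() == pytest.approx(1.0)


class TestSamplerCorrectness:
    def test_conjugate_posterior_closed_form(self):
        """With fixed noise precision and no random effects the posterior
        of beta is exactly N((tau X'X + lam I)^{-1} tau X'y, ...)."""
        rng = np.random.default_rng(10)
        n, tau = 50, 4.0
        x = rng.uniform(size=n) * 100
        y = 0.3 + 0.8 * rng.standard_normal(n)
        table = _gaussian_table(y, {"x1": x})
        spec = ModelSpec("linear_fixed", linear_terms=["x1"])
        fit = gibbs_fit(table, spec, n_iter=6000, n_burn=1000, thin=1, seed=1,
                        y=y, fixed_precisions={"tau_eps": tau})
        X = fit.designs.X
        P = tau * X.T @ X + spec.beta_precision * np.eye(2)
        mean = np.linalg.solve(P, tau * X.T @ y)
        sd = np.sqrt(np.diag(np.linalg.inv(P)))
        s = fit.n_draws
        emp_mean = fit.draws["beta"].mean(axis=0)
        emp_sd = fit.draws["beta"].std(axis=0, ddof=1)
        assert np.all(np.abs(emp_mean - mean) < 3 * sd / np.sqrt(s))
        assert np.all(np.abs(emp_sd - sd) < 3 * sd / np.sqrt(2 * s))

    def test_noiseless_limit_recovers_least_squares(self):
        rng = np.random.default_rng(11)
        n = 40
        x = rng.uniform(size=n)
        y = 1.5 + 2.0 * (x - x.mean()) / x.std()
        table = _gaussian_table(y, {"x1": x})
        spec = ModelSpec("linear_fixed", linear_terms=["x1"])
        fit = gibbs_fit(table, spec, n_iter=600, n_burn=100, thin=1, seed=2,
                        y=y, fixed_precisions={"tau_eps": 1e12})
        X = fit.designs.X
        ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.draws["beta"].mean(axis=0) == pytest.approx(ls, abs=1e-4)

    def test_joint_block_matches_dense_oracle(self):
        """Fixed-precision Gibbs draws of (beta, f, u) must match an
        independent dense construction of the joint Gaussian posterior
        (v collapsed into the noise), after identical recentring."""
        rng = np.random.default_rng(12)
        rows, cols = 5, 5
        scen = make_scenario(rows, cols, beta=(0.2, 0.7), smooth_menu=("quadratic",),
                             tau_u=1.0, tau_v=8.0, sigma_eps=0.6, seed=77)
        taus = {"tau_eps": 1 / 0.36, "tau_u": 1.0, "tau_v": 8.0, "tau_f": {"s1": 5.0}}
        spec = ModelSpec("bym", linear_terms=["x1"], smooth_terms={"s1": 8},
                         graph=scen.graph)
        n_draws = 20_000
        fit = gibbs_fit(scen.table, spec, n_iter=n_draws + 50, n_burn=50, thin=1,
                        seed=3, y=scen.y, fixed_precisions=taus)
        d = fit.designs
        n = rows * cols
        b_s1 = d.A["s1"].shape[1]
        # independent dense posterior: M = [X | A | I], prior blockdiag
        M = np.hstack([d.X, d.A["s1"], np.eye(n)])
        tau_c = taus["tau_eps"] * taus["tau_v"] / (taus["tau_eps"] + taus["tau_v"])
        prior = np.zeros((M.shape[1], M.shape[1]))
        p = d.X.shape[1]
        prior[:p, :p] = spec.beta_precision * np.eye(p)
        prior[p:p + b_s1, p:p + b_s1] = taus["tau_f"]["s1"] * d.K["s1"] + LATENT_RIDGE * np.eye(b_s1)
        prior[p + b_s1:, p + b_s1:] = taus["tau_u"] * d.Q + LATENT_RIDGE * np.eye(n)
        P = tau_c * M.T @ M + prior
        mean = np.linalg.solve(P, tau_c * M.T @ fit.y)
        cov = np.linalg.inv(P)
        # the recentring (f/u means absorbed into the intercept) is a
        # linear map T; compare against the exact N(T mean, T cov T')
        T = np.eye(M.shape[1])
        T[0, p:p + b_s1] += 1.0 / b_s1
        T[0, p + b_s1:] += 1.0 / n
        T[p:p + b_s1, p:p + b_s1] -= 1.0 / b_s1
        T[p + b_s1:, p + b_s1:] -= 1.0 / n
        exact_mean = T @ mean
        exact_sd = np.sqrt(np.diag(T @ cov @ T.T))
        gibbs = np.hstack([fit.draws["beta"], fit.draws["f"]["s1"], fit.draws["u"]])
        assert np.all(np.abs(gibbs.mean(0) - exact_mean) < 4 * exact_sd / np.sqrt(n_draws))
        assert np.all(
            np.abs(gibbs.std(0, ddof=1) - exact_sd) < 4 * exact_sd / np.sqrt(2 * n_draws)
        )

    def test_constrained_blocks_have_zero_mean(self):
        scen = make_scenario(6, 6, beta=(0.0, 0.5), smooth_menu=("sinusoid",),
                             tau_u=1.0, tau_v=10.0, sigma_eps=0.5, seed=5)
        spec = ModelSpec("bym", linear_terms=["x1"], smooth_terms={"s1": 8},
                         graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=400, n_burn=100, thin=1, seed=6, y=scen.y)
        assert np.abs(fit.draws["u"].mean(axis=1)).max() < 1e-10
        assert np.abs(fit.draws["f"]["s1"].mean(axis=1)).max() < 1e-10

    def test_precisions_positive_in_every_draw(self):
        scen = make_scenario(5, 5, beta=(0.0, 0.5), smooth_menu=(),
                             tau_u=1.0, tau_v=10.0, sigma_eps=0.5, seed=7)
        spec = ModelSpec("bym", linear_terms=["x1"], graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=500, n_burn=100, thin=1, seed=8, y=scen.y)
        for key in ("tau_eps", "tau_u", "tau_v"):
            assert np.all(fit.draws[key] > 0)


class TestVariantNesting:
    def test_iid_with_huge_tau_v_matches_fixed(self):
        rng = np.random.default_rng(20)
        n = 60
        x = rng.uniform(size=n)
        y = 0.5 + x + rng.normal(scale=0.4, size=n)
        table = _gaussian_table(y, {"x1": x})
        fit_fixed = gibbs_fit(table, ModelSpec("linear_fixed", linear_terms=["x1"]),
                              n_iter=2500, n_burn=500, thin=1, seed=9, y=y)
        fit_iid = gibbs_fit(table, ModelSpec("additive_iid", linear_terms=["x1"]),
                            n_iter=2500, n_burn=500, thin=1, seed=10, y=y,
                            fixed_precisions={"tau_v": 1e12})
        mf = fit_fixed.draws["beta"].mean(axis=0)
        mi = fit_iid.draws["beta"].mean(axis=0)
        sd = fit_fixed.draws["beta"].std(axis=0, ddof=1)
        assert np.all(np.abs(mf - mi) < 4 * sd / np.sqrt(2000) * 3)

    def test_bym_with_edgeless_graph_matches_iid(self):
        """With no edges the structured field has no density; every u is
        pinned at zero and the fit must coincide with additive_iid."""
        from ancspatial.graphs import SpatialGraph

        rng = np.random.default_rng(21)
        n = 40
        x = rng.uniform(size=n)
        y = 0.5 + x + rng.normal(scale=0.4, size=n)
        table = _gaussian_table(y, {"x1": x})
        g = SpatialGraph([f"u{i}" for i in range(n)], set())
        fit_bym = gibbs_fit(table, ModelSpec("bym", linear_terms=["x1"], graph=g),
                            n_iter=2000, n_burn=500, thin=1, seed=11, y=y)
        fit_iid = gibbs_fit(table, ModelSpec("additive_iid", linear_terms=["x1"]),
                            n_iter=2000, n_burn=500, thin=1, seed=11, y=y)
        assert np.abs(fit_bym.draws["u"]).max() < 1e-3
        mb = fit_bym.draws["beta"].mean(axis=0)
        mi = fit_iid.draws["beta"].mean(axis=0)
        sd = fit_iid.draws["beta"].std(axis=0, ddof=1)
        assert np.all(np.abs(mb - mi) < 4 * sd / np.sqrt(1500) * 3)


class TestSummaries:
    def test_summary_schema_and_ordering(self):
        scen = make_scenario(5, 5, beta=(0.1, 0.5), smooth_menu=("sinusoid",),
                             tau_u=1.0, tau_v=10.0, sigma_eps=0.5, seed=30)
        spec = ModelSpec("bym", linear_terms=["x1"], smooth_terms={"s1": 8},
                         graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=500, n_burn=200, thin=1, seed=31, y=scen.y)
        s = summarize(fit)
        assert list(s.fixed.columns[:6]) == ["term", "mean", "sd", "q2.5", "q50", "q97.5"]
        for frame in (s.fixed, s.precisions):
            assert (frame["q2.5"] <= frame["q50"]).all()
            assert (frame["q50"] <= frame["q97.5"]).all()
        assert set(s.smooths) == {"s1"}

    def test_normal_draw_quantiles(self):
        """Posterior quantile machinery against the normal quantile oracle."""
        rng = np.random.default_rng(32)
        scen = make_scenario(5, 5, beta=(0.0,), smooth_menu=(),
                             tau_u=0, tau_v=0, sigma_eps=1.0, seed=33)
        spec = ModelSpec("linear_fixed")
        fit = gibbs_fit(scen.table, spec, n_iter=200, n_burn=100, thin=1, seed=34, y=scen.y)
        fit.draws["beta"] = rng.standard_normal((40_000, 1))
        s = summarize(fit)
        row = s.fixed.iloc[0]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q50"] == pytest.approx(0.0, abs=0.03)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)

    def test_intercept_only_fitted_constant(self):
        rng = np.random.default_rng(35)
        y = rng.normal(size=30)
        table = _gaussian_table(y)
        fit = gibbs_fit(table, ModelSpec("linear_fixed"), n_iter=400, n_burn=100,
                        thin=1, seed=36, y=y)
        fitted = predict(fit)["fitted"]
        assert fitted.nunique() == 1
        assert fitted.iloc[0] == pytest.approx(fit.draws["beta"].mean())

    def test_residual_variance_not_above_observed(self):
        scen = make_scenario(6, 6, beta=(0.3, 1.0), smooth_menu=("quadratic",),
                             tau_u=1.0, tau_v=10.0, sigma_eps=0.5, seed=37)
        spec = ModelSpec("bym", linear_terms=["x1"], smooth_terms={"s1": 8},
                         graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=600, n_burn=200, thin=1, seed=38, y=scen.y)
        out = predict(fit)
        assert out["residual"].var() <= np.var(fit.y) * (1 + 1e-9)


class TestIcarDiagnostic:
    def test_slope_near_one_with_strong_field(self):
        scen = make_scenario(10, 10, beta=(0.0,), smooth_menu=(),
                             tau_u=0.25, tau_v=100.0, sigma_eps=0.1, seed=40)
        spec = ModelSpec("bym", graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=1500, n_burn=500, thin=2, seed=41, y=scen.y)
        report = icar_full_conditional_check(fit)
        assert 0.9 <= report["slope"] <= 1.1

    def test_shuffled_graph_negative_control(self):
        """Regressing u on the neighbor means of a *wrong* graph should
        show little association."""
        rng = np.random.default_rng(42)
        scen = make_scenario(10, 10, beta=(0.0,), smooth_menu=(),
                             tau_u=0.25, tau_v=100.0, sigma_eps=0.1, seed=43)
        spec = ModelSpec("bym", graph=scen.graph)
        fit = gibbs_fit(scen.table, spec, n_iter=800, n_burn=300, thin=2, seed=44, y=scen.y)
        ids = list(scen.graph.node_ids)
        from ancspatial.graphs import SpatialGraph

        slopes = []
        for _ in range(10):
            perm = rng.permutation(len(ids))
            relabel = {ids[i]: ids[perm[i]] for i in range(len(ids))}
            shuffled = SpatialGraph(
                ids,
                {frozenset((relabel[a], relabel[b])) for a, b in map(tuple, scen.graph.edges)},
            )
            slopes.append(icar_full_conditional_check(fit, graph=shuffled)["slope"])
        good = icar_full_conditional_check(fit)["slope"]
        assert abs(np.mean(slopes)) < 0.2
        # the true-graph slope stands far above every shuffled one
        assert good > max(np.abs(slopes)) and good > 0.6

    def test_skipped_without_structured_effect(self):
        rng = np.random.default_rng(45)
        y = rng.normal(size=20)
        fit = gibbs_fit(_gaussian_table(y), ModelSpec("linear_fixed"),
                        n_iter=300, n_burn=100, thin=1, seed=46, y=y)
        assert icar_full_conditional_check(fit)["skipped"] is not None
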