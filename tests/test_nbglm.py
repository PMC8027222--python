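import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sipflow.ingest import make_sample_table
from sipflow.nbglm import (DesignMatrix, RankError, build_design,
                           estimate_dispersions, fit_glm, fit_gene,
                           nb_deviance)
from sipflow.simulate import SimConfig, simulate_experiment


def _design(X, offsets=None, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"b{j}" for j in range(X.shape[1])]
    offsets = offsets if offsets is not None else np.zeros(X.shape[0])
    return DesignMatrix(colnames=names, X=X, offsets=offsets)


def _mtplus_samples():
    rows = []
    for r in (1, 2, 3):
        rows.append({"sample_id": f"t0_control_r{r}", "dataset": "d",
                     "mating_type": "MTplus", "timepoint": "0h",
                     "condition": "control", "replicate": r})
    for t in ("15min", "1h", "3h", "6h", "9h"):
        for cond in ("control", "treated"):
            for r in (1, 2, 3):
                rows.append({"sample_id": f"t{t}_{cond}_r{r}", "dataset": "d",
                             "mating_type": "MTplus", "timepoint": t,
                             "condition": cond, "replicate": r})
    return make_sample_table(pd.DataFrame(rows))


class TestBuildDesign:
    def test_study_layout_has_11_cells(self):
        d = build_design(_mtplus_samples())
        assert d.n_params == 11
        assert "t0_control" in d.colnames
        assert "t0_treated" not in d.colnames

    def test_one_timepoint_two_conditions(self):
        rows = pd.DataFrame([
            {"sample_id": f"s{i}", "dataset": "d", "mating_type": "MTminus",
             "timepoint": "1h", "condition": c, "replicate": i}
            for i, c in enumerate(["control"] * 3 + ["treated"] * 3)])
        d = build_design(make_sample_table(rows))
        assert d.colnames == ["t60_control", "t60_treated"]

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(RankError, match="aliased"):
            _design(X, names=["a", "a_copy"])

    def test_reduced_design_nested(self):
        st = _mtplus_samples()
        full = build_design(st)
        red = build_design(st, "timepoint_only")
        assert red.n_params == 6
        # every reduced column is a sum of full columns
        for j in range(red.n_params):
            assert np.allclose(red.X[:, j],
                               full.X[:, np.abs(
                                   full.X.T @ red.X[:, j]) > 0].sum(axis=1))


class TestFitGLM:
    def test_intercept_only_fitted_mean_is_sample_mean(self):
        d = _design(np.ones((3, 1)))
        for phi in (1e-8, 0.1, 1.0):
            fit = fit_gene(np.array([3, 5, 7]), d, phi)
            assert np.exp(fit.beta[0, 0]) == pytest.approx(5.0, rel=1e-7)

    def test_saturated_design_zero_deviance(self):
        d = _design(np.eye(4))
        fit = fit_gene(np.array([2, 9, 4, 7]), d, 0.2)
        assert fit.deviance[0] == pytest.approx(0.0, abs=1e-6)

    def test_poisson_limit_matches_statsmodels_oracle(self):
        """At dispersion 1e-8 the NB IRLS coincides with a Poisson GLM."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 15))
            p = int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n)]
                                + [rng.normal(size=n) for _ in range(p - 1)])
            off = np.log(rng.uniform(0.5e6, 2e6, n))
            beta = rng.normal(0, 0.5, p)
            beta[0] = rng.normal(np.log(50) - 14, 0.5)
            y = rng.poisson(np.exp(X @ beta + off))
            d = _design(X, offsets=off)
            fit = fit_glm(y[None, :], d, 1e-8)
            ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
            assert np.max(np.abs(fit.beta[0] - ref.params)) < 1e-6

    def test_matches_statsmodels_negative_binomial(self):
        """Cross-check a proper NB fit (phi = 0.3) against statsmodels."""
        rng = np.random.default_rng(11)
        n, phi = 12, 0.3
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        off = np.full(n, np.log(1e6))
        mu = np.exp(np.log(40) - 13.8 + 0.8 * X[:, 1] + off)
        y = rng.poisson(rng.gamma(1 / phi, phi * mu))
        d = _design(X, offsets=off)
        fit = fit_glm(y[None, :], d, phi)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                     offset=off).fit()
        assert np.allclose(fit.beta[0], ref.params, atol=1e-5)
        assert np.allclose(fit.se[0], ref.bse, rtol=1e-3)

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(5)
        n = 9
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = rng.poisson(30, (4, n))
        d = _design(X)
        fit1 = fit_glm(y, d, 0.1)
        perm = rng.permutation(n)
        d2 = _design(X[perm])
        fit2 = fit_glm(y[:, perm], d2, 0.1)
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-7)

    def test_added_column_never_increases_deviance(self):
        rng = np.random.default_rng(6)
        n = 10
        X1 = np.ones((n, 1))
        X2 = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(25, (20, n))
        d1, d2 = _design(X1), _design(X2)
        dev1 = fit_glm(y, d1, 0.1).deviance
        dev2 = fit_glm(y, d2, 0.1).deviance
        assert (dev2 <= dev1 + 1e-6).all()

    def test_all_zero_gene_flagged_low(self):
        d = _design(np.ones((4, 1)), offsets=np.full(4, np.log(1e6)))
        fit = fit_gene(np.zeros(4, dtype=int), d, 0.1)
        assert fit.low_cell[0, 0]


class TestNBDeviance:
    def test_zero_at_perfect_fit(self):
        y = np.array([[1.0, 5.0, 9.0]])
        assert nb_deviance(y, y, 0.3)[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_limit_closed_form(self):
        y = np.array([[2.0, 4.0]])
        mu = np.array([[3.0, 3.0]])
        expected = 2 * np.sum(y * np.log(y / mu) - (y - mu))
        assert nb_deviance(y, mu, 1e-8)[0] == pytest.approx(expected, abs=1e-6)

    def test_additive_over_samples(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(10, (1, 6)).astype(float)
        mu = rng.uniform(5, 15, (1, 6))
        total = nb_deviance(y, mu, 0.2)[0]
        parts = sum(nb_deviance(y[:, [i]], mu[:, [i]], 0.2)[0]
                    for i in range(6))
        assert total == pytest.approx(parts, rel=1e-10)


class TestDispersionEstimation:
    def _design6(self):
        X = np.zeros((6, 2))
        X[:3, 0] = 1
        X[3:, 1] = 1
        return _design(X, offsets=np.full(6, np.log(1e6)))

    def test_poisson_data_yields_small_dispersion(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(np.log(100), 1.2, 2000))
        y = rng.poisson(mu[:, None] * np.ones(6))
        d = estimate_dispersions(y, self._design6())
        assert np.median(d.tagwise) <= 0.05

    def test_constant_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(np.log(100), 1.2, 2000))
        lam = rng.gamma(1 / 0.1, 0.1 * mu[:, None] * np.ones(6))
        y = rng.poisson(lam)
        d = estimate_dispersions(y, self._design6())
        assert 0.07 <= np.median(d.tagwise) <= 0.14

    def test_infinite_prior_recovers_trend(self):
        rng = np.random.default_rng(2)
        mu = np.exp(rng.normal(np.log(50), 1.0, 400))
        y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * mu[:, None] * np.ones(6)))
        d = estimate_dispersions(y, self._design6(), prior_df=1e9)
        assert np.allclose(d.tagwise, d.trended, rtol=1e-6)

    def test_zero_residual_df_rejected(self):
        d = _design(np.eye(4))
        with pytest.raises(ValueError, match="residual"):
            estimate_dispersions(np.ones((5, 4)), d)
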