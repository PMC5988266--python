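"""Penalized additive model engine against independent GLM oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hydrurga.pam import (PenalizedAdditiveModel, RandomEffectSpec, SmoothSpec,
                          build_basis, compare, crs_basis, cyclic_crs_basis)


class TestBases:
    def test_cyclic_periodicity(self):
        knots = np.linspace(0, 24, 11)
        X, _ = cyclic_crs_basis(np.array([0.0, 24.0, 6.5, 30.5]), knots, 24.0)
        assert np.allclose(X[0], X[1])
        assert np.allclose(X[2], X[3])

    def test_cyclic_derivative_continuity(self):
        """Value and slope of every basis function match across the seam."""
        knots = np.linspace(0, 24, 9)
        eps = 1e-5
        Xa, _ = cyclic_crs_basis(np.array([24.0 - eps]), knots, 24.0)
        Xb, _ = cyclic_crs_basis(np.array([eps]), knots, 24.0)
        assert np.allclose(Xa, Xb, atol=1e-3)

    def test_straight_line_in_penalty_null_space(self):
        spec = SmoothSpec("x", basis_dim=8, shrinkage=False)
        x = np.linspace(0, 10, 200)
        _, S, knots = build_basis(x, spec)
        line = 2.0 * knots + 1.0
        assert abs(line @ S @ line) < 1e-8

    def test_interpolation_property(self):
        """The CRS design evaluated at the knots returns the knot values."""
        knots = np.linspace(0, 5, 7)
        X, _ = crs_basis(knots, knots)
        assert np.allclose(X, np.eye(7), atol=1e-10)

    def test_too_few_distinct_values_rejected(self):
        spec = SmoothSpec("x", basis_dim=10)
        with pytest.raises(ValueError, match="distinct"):
            build_basis(np.repeat([1.0, 2.0, 3.0], 10), spec)

    def test_cyclic_requires_period(self):
        with pytest.raises(ValueError, match="period"):
            SmoothSpec("x", cyclic=True)


class TestFit:
    def test_intercept_only_matches_event_rate(self, rng):
        y = (rng.uniform(size=400) < 0.27).astype(float)
        r = PenalizedAdditiveModel(y, data=pd.DataFrame(index=range(400))).fit()
        assert r.fittedvalues[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_linear_logit_matches_glm_oracle(self, rng):
        x = rng.normal(size=800)
        z = rng.normal(size=800)
        eta = -0.5 + 0.8 * x - 0.4 * z
        y = (rng.uniform(size=800) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        r = PenalizedAdditiveModel("y", df, linear=["x", "z"]).fit()
        g = sm.GLM(y, sm.add_constant(np.column_stack([x, z])),
                   family=sm.families.Binomial()).fit()
        assert np.abs(r.params - g.params).max() < 1e-6
        assert r.llf == pytest.approx(g.llf, abs=1e-6)

    def test_infinite_penalty_collapses_to_linear_glm(self, rng):
        """lambda -> inf leaves only the smooth's null space (a line)."""
        x = rng.normal(size=600)
        z = rng.normal(size=600)
        eta = 0.3 + 0.5 * x - 0.7 * z
        y = (rng.uniform(size=600) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        r = PenalizedAdditiveModel(
            "y", df, linear=["x"],
            smooths=[SmoothSpec("z", basis_dim=8, shrinkage=False)],
        ).fit(penalty_selection="fixed", lambdas=[1e8])
        g = sm.GLM(y, sm.add_constant(np.column_stack([x, z])),
                   family=sm.families.Binomial()).fit()
        assert np.abs(r.fittedvalues - g.fittedvalues).max() < 1e-5

    def test_cloglog_parameter_recovery(self, rng):
        """Known-coefficient cloglog data, n=20000: bias < 5%."""
        x = rng.normal(size=20_000)
        eta = -1.5 + 0.7 * x
        mu = -np.expm1(-np.exp(eta))
        y = (rng.uniform(size=20_000) < mu).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        r = PenalizedAdditiveModel("y", df, linear=["x"], link="cloglog").fit()
        assert r.params[0] == pytest.approx(-1.5, rel=0.05)
        assert r.params[1] == pytest.approx(0.7, rel=0.05)

    def test_shrinkage_smooth_on_line_is_effectively_linear(self, rng):
        """On pure-line data the selected smooth is a near-line of modest edf
        (the reference GAM engine behaves the same way)."""
        x = rng.uniform(0, 10, 2000)
        eta = -1.0 + 0.4 * x
        y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        r = PenalizedAdditiveModel("y", df, smooths=[SmoothSpec("x", basis_dim=10)]).fit()
        edf = r.edf_by_term()["s(x)"]
        assert edf < 5.0
        grid = np.linspace(0.5, 9.5, 100)
        pe = r.partial_effect("s(x)", grid)
        resid = pe - np.polyval(np.polyfit(grid, pe, 1), grid)
        assert np.abs(resid).max() < 0.15 * (pe.max() - pe.min())

    def test_nonlinear_signal_is_found(self, rng):
        x = rng.uniform(0, 2 * np.pi, 3000)
        eta = -0.5 + 1.2 * np.sin(x)
        y = (rng.uniform(size=3000) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        r = PenalizedAdditiveModel("y", df, smooths=[SmoothSpec("x", basis_dim=10)]).fit()
        assert r.edf_by_term()["s(x)"] > 2.0
        grid = np.linspace(0.2, 2 * np.pi - 0.2, 60)
        pe = r.partial_effect("s(x)", grid)
        assert np.corrcoef(pe, np.sin(grid))[0, 1] > 0.97

    def test_rare_event_links_agree(self, rng):
        """Logit and cloglog slopes converge in the rare-event limit."""
        x = rng.normal(size=50_000)
        eta = -5.0 + 0.5 * x
        mu = np.exp(eta)  # rare-event intensity, ~0.008
        y = (rng.uniform(size=50_000) < mu).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        r_logit = PenalizedAdditiveModel("y", df, linear=["x"], link="logit").fit()
        r_clog = PenalizedAdditiveModel("y", df, linear=["x"], link="cloglog").fit()
        assert r_logit.params[1] == pytest.approx(r_clog.params[1], rel=0.05)

    def test_random_effect_shrinks_group_intercepts(self, rng):
        g = np.repeat(np.arange(8), 150)
        re_true = rng.normal(0, 0.8, 8)
        eta = -0.5 + re_true[g]
        y = (rng.uniform(size=1200) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "tag": g.astype(str), "trip": "t1"})
        r = PenalizedAdditiveModel("y", df,
                                   random_effect=RandomEffectSpec(("tag", "trip"))).fit()
        re_block = [tb for tb in r.model.blocks if tb.kind == "random"][0]
        est = r.params[re_block.sl]
        assert np.corrcoef(est, re_true)[0, 1] > 0.8
        assert est.std() < re_true.std() + 0.3

    def test_aic_identity(self, rng):
        y = (rng.uniform(size=300) < 0.4).astype(float)
        x = rng.normal(size=300)
        df = pd.DataFrame({"y": y, "x": x})
        r = PenalizedAdditiveModel("y", df, linear=["x"]).fit()
        assert r.aic == pytest.approx(-2 * r.llf + 2 * r.edf_total)

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            PenalizedAdditiveModel(np.array([0.0, 0.5, 1.0]),
                                   data=pd.DataFrame(index=range(3)))


class TestCompare:
    def _fits(self, rng):
        x = rng.normal(size=500)
        eta = -0.2 + 1.0 * x
        y = (rng.uniform(size=500) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "junk": rng.normal(size=500)})
        f0 = PenalizedAdditiveModel("y", df).fit()
        f1 = PenalizedAdditiveModel("y", df, linear=["x"]).fit()
        f2 = PenalizedAdditiveModel("y", df, linear=["x", "junk"]).fit()
        return f0, f1, f2

    def test_generating_covariate_improves_loglik(self, rng):
        f0, f1, _ = self._fits(rng)
        assert f1.llf > f0.llf

    def test_aic_ordering_matches_manual_computation(self, rng):
        f0, f1, f2 = self._fits(rng)
        tbl = compare([f0, f1, f2], criterion="aic", names=["0", "x", "x+junk"])
        manual = sorted([f0, f1, f2], key=lambda f: (-2 * f.llf + 2 * f.edf_total,
                                                     f.edf_total))
        assert tbl["aic"].tolist() == [(-2 * f.llf + 2 * f.edf_total) for f in manual]

    def test_duplicate_fit_tie_broken_by_edf(self, rng):
        f0, f1, _ = self._fits(rng)
        tbl = compare([f1, f1, f0], criterion="loglik", names=["a", "b", "c"])
        assert tbl["model"].tolist()[:2] == ["a", "b"]  # stable

    def test_mismatched_responses_rejected(self, rng):
        f0, _, _ = self._fits(rng)
        y2 = (rng.uniform(size=500) < 0.5).astype(float)
        other = PenalizedAdditiveModel(y2, data=pd.DataFrame(index=range(500))).fit()
        with pytest.raises(ValueError, match="identical response"):
            compare([f0, other])
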