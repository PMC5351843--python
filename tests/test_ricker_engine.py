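import numpy as np
import pandas as pd
import pytest

import prodshift as ps
from prodshift.errors import (
    DegenerateLikelihoodError,
    InsufficientDataError,
    SingularDesignError,
)
from .conftest import ols_oracle


def make_frame(log_rs, spawners=None, x=None, start=1981):
    data = {"log_rs": np.asarray(log_rs, dtype=float)}
    if spawners is not None:
        data["spawners"] = np.asarray(spawners, dtype=float)
    if x is not None:
        data["x"] = np.asarray(x, dtype=float)
    years = pd.Index(range(start, start + len(log_rs)), name="brood_year")
    return pd.DataFrame(data, index=years)


class TestFitNull:
    def test_mean_and_ml_sigma(self):
        fit = ps.fit_null(make_frame([0.5, 1.0, 1.5]))
        assert fit.a["pop"] == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma == pytest.approx(np.sqrt(1 / 6), abs=1e-12)
        assert fit.k_params == 2

    def test_constant_series_degenerate(self):
        fit = ps.fit_null(make_frame([0.7, 0.7, 0.7]))
        assert fit.a["pop"] == pytest.approx(0.7)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)
        assert fit.degenerate

    def test_intercept_equals_mean_on_random_data(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        fit = ps.fit_null(make_frame(y))
        assert fit.a["pop"] == pytest.approx(np.mean(y), abs=1e-12)

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            ps.fit_null(make_frame([1.0, 2.0]))


class TestFitRicker:
    def test_noise_free_exact_interpolation(self):
        S = np.array([1.0, 2.0, 3.0, 4.0])
        frame = make_frame(2.0 - 1.0 * S, spawners=S)
        fit = ps.fit_ricker(frame, ps.ModelSpec(["pop"], "shared"))
        assert fit.a["pop"] == pytest.approx(2.0, abs=1e-9)
        assert fit.b["pop"] == pytest.approx(-1.0, abs=1e-9)
        assert np.allclose(fit.residuals.to_numpy(), 0.0, atol=1e-10)
        assert fit.degenerate

    def test_matches_normal_equations_oracle(self, random_frame_factory):
        rng = np.random.default_rng(42)
        for _ in range(25):
            frame = random_frame_factory(rng)
            fit = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))
            beta, sigma, ll = ols_oracle(frame, ["spawners", "x"])
            assert fit.a["p"] == pytest.approx(beta[0], abs=1e-8)
            assert fit.b["p"] == pytest.approx(beta[1], abs=1e-8)
            assert fit.c == pytest.approx(beta[2], abs=1e-8)
            assert fit.sigma == pytest.approx(sigma, abs=1e-8)
            assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_matches_statsmodels(self, random_frame_factory):
        """Cross-check against an independent library implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        frame = random_frame_factory(rng)
        fit = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))
        X = sm.add_constant(frame[["spawners", "x"]])
        res = sm.OLS(frame["log_rs"], X).fit()
        assert fit.a["p"] == pytest.approx(res.params["const"], abs=1e-8)
        assert fit.b["p"] == pytest.approx(res.params["spawners"], abs=1e-8)
        assert fit.c == pytest.approx(res.params["x"], abs=1e-8)
        assert fit.se["b"] == pytest.approx(res.bse["spawners"], abs=1e-8)

    def test_estimates_near_truth_at_large_n(self):
        rng = np.random.default_rng(99)
        n = 1000
        S = rng.uniform(500, 5000, size=n)
        x = rng.normal(size=n)
        a, b, c, sigma = 1.5, -2e-4, -0.5, 0.4
        y = a + b * S + c * x + rng.normal(0, sigma, size=n)
        fit = ps.fit_ricker(make_frame(y, S, x, start=0), ps.ModelSpec(["p"], "shared", covariate="x"))
        for name, truth in [("a:p", a), ("b:p", b), ("c", c)]:
            est = fit.estimate(name)
            assert abs(est - truth) < 3 * fit.se[name]

    def test_collinear_design_rejected(self):
        S = np.linspace(100, 1000, 10)
        frame = make_frame(np.log(S), spawners=S, x=2.0 * S)
        with pytest.raises(SingularDesignError):
            ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))

    def test_insufficient_observations(self):
        frame = make_frame([1.0, 2.0, 3.0], spawners=[1, 2, 3], x=[0.1, 0.3, -0.2])
        with pytest.raises(InsufficientDataError):
            ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))

    def test_residual_mean_zero_with_intercept(self, random_frame_factory):
        rng = np.random.default_rng(8)
        frame = random_frame_factory(rng)
        fit = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared"))
        assert abs(fit.residuals.mean()) < 1e-8


class TestNestingAndInvariance:
    def test_adding_covariate_never_decreases_loglik(self, random_frame_factory):
        rng = np.random.default_rng(21)
        for _ in range(10):
            frame = random_frame_factory(rng)
            base = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared"))
            full = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))
            assert full.loglik >= base.loglik - 1e-8

    def test_affine_rescaling_leaves_fit_invariant(self, random_frame_factory):
        rng = np.random.default_rng(22)
        frame = random_frame_factory(rng)
        fit = ps.fit_ricker(frame, ps.ModelSpec(["p"], "shared", covariate="x"))
        scaled = frame.copy()
        scaled["x"] = 3.5 * scaled["x"] - 2.0
        fit2 = ps.fit_ricker(scaled, ps.ModelSpec(["p"], "shared", covariate="x"))
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)
        np.testing.assert_allclose(
            fit2.residuals.to_numpy(), fit.residuals.to_numpy(), atol=1e-8
        )
        assert fit2.c == pytest.approx(fit.c / 3.5, abs=1e-10)


class TestMultipopulation:
    def _two_pop_frames(self, rng, identical=False):
        f1 = pd.DataFrame(
            {"log_rs": rng.normal(1.0, 0.4, 20),
             "spawners": rng.uniform(500, 3000, 20)},
            index=pd.Index(range(1981, 2001), name="brood_year"),
        )
        f2 = f1.copy() if identical else pd.DataFrame(
            {"log_rs": rng.normal(1.4, 0.4, 20),
             "spawners": rng.uniform(200, 1500, 20)},
            index=pd.Index(range(1981, 2001), name="brood_year"),
        )
        return {"p1": f1, "p2": f2}

    def test_identical_populations_match_single_fit(self):
        rng = np.random.default_rng(31)
        frames = self._two_pop_frames(rng, identical=True)
        joint = ps.fit_multipopulation(frames, ps.ModelSpec(["p1", "p2"], "shared"))
        single = ps.fit_ricker(frames["p1"], ps.ModelSpec(["p1"], "shared"))
        assert joint.a["p1"] == pytest.approx(single.a["p1"], abs=1e-8)
        assert joint.a["p2"] == pytest.approx(single.a["p1"], abs=1e-8)
        assert joint.b["p1"] == pytest.approx(single.b["p1"], abs=1e-8)
        assert joint.sigma == pytest.approx(single.sigma, abs=1e-8)

    def test_per_population_b_matches_independent_fits(self):
        """With b_i free and per-population sigma, the joint fit decouples."""
        rng = np.random.default_rng(32)
        frames = self._two_pop_frames(rng)
        joint = ps.fit_multipopulation(
            frames,
            ps.ModelSpec(["p1", "p2"], "per_population", sigma_structure="per_population"),
        )
        for p in ("p1", "p2"):
            solo = ps.fit_ricker(frames[p], ps.ModelSpec([p], "shared"))
            assert joint.a[p] == pytest.approx(solo.a[p], abs=1e-6)
            assert joint.b[p] == pytest.approx(solo.b[p], abs=1e-6)
            assert joint.sigma[p] == pytest.approx(solo.sigma, abs=1e-6)

    def test_noise_free_joint_recovery(self):
        years = pd.Index(range(1981, 2001), name="brood_year")
        S1 = np.linspace(500, 2500, 20)
        S2 = np.linspace(200, 1800, 20)
        truth = {"p1": (1.2, -3e-4), "p2": (1.8, -6e-4)}
        frames = {
            "p1": pd.DataFrame({"log_rs": truth["p1"][0] + truth["p1"][1] * S1, "spawners": S1}, index=years),
            "p2": pd.DataFrame({"log_rs": truth["p2"][0] + truth["p2"][1] * S2, "spawners": S2}, index=years),
        }
        joint = ps.fit_multipopulation(frames, ps.ModelSpec(["p1", "p2"], "per_population"))
        for p, (a, b) in truth.items():
            assert joint.a[p] == pytest.approx(a, abs=1e-9)
            assert joint.b[p] == pytest.approx(b, abs=1e-9)
        assert joint.degenerate

    def test_unbalanced_years_allowed(self):
        rng = np.random.default_rng(33)
        frames = self._two_pop_frames(rng)
        frames["p2"] = frames["p2"].iloc[:12]
        joint = ps.fit_multipopulation(frames, ps.ModelSpec(["p1", "p2"], "shared"))
        assert joint.n_obs == 32

    def test_freeing_b_never_decreases_loglik(self):
        rng = np.random.default_rng(34)
        frames = self._two_pop_frames(rng)
        shared = ps.fit_multipopulation(frames, ps.ModelSpec(["p1", "p2"], "shared"))
        free = ps.fit_multipopulation(frames, ps.ModelSpec(["p1", "p2"], "per_population"))
        assert free.loglik >= shared.loglik - 1e-8


class TestLoglik:
    def test_single_observation_residual_zero(self):
        fit = ps.FitResult(
            a={"p": 0.0}, b=None, c=None, sigma=1.0, loglik=np.nan, n_obs=1,
            k_params=2,
            residuals=pd.Series([0.0], index=pd.MultiIndex.from_tuples([("p", 1981)], names=["population", "brood_year"])),
            fitted=pd.Series([0.0]),
        )
        assert ps.loglik(fit) == pytest.approx(-0.918939, abs=1e-6)

    def test_location_scale_identity(self):
        rng = np.random.default_rng(4)
        resid = rng.normal(size=12)
        idx = pd.MultiIndex.from_product([["p"], range(12)], names=["population", "brood_year"])
        base = ps.FitResult(a={"p": 0.0}, b=None, c=None, sigma=0.7, loglik=np.nan,
                            n_obs=12, k_params=2, residuals=pd.Series(resid, index=idx),
                            fitted=pd.Series(np.zeros(12), index=idx))
        scaled = ps.FitResult(a={"p": 0.0}, b=None, c=None, sigma=0.7 * 3, loglik=np.nan,
                              n_obs=12, k_params=2, residuals=pd.Series(resid * 3, index=idx),
                              fitted=pd.Series(np.zeros(12), index=idx))
        assert ps.loglik(scaled) == pytest.approx(ps.loglik(base) - 12 * np.log(3), abs=1e-10)

    def test_matches_density_summation_oracle(self):
        from scipy.stats import norm

        rng = np.random.default_rng(5)
        for _ in range(10):
            resid = rng.normal(0, 0.5, size=20)
            sigma = rng.uniform(0.2, 1.0)
            idx = pd.MultiIndex.from_product([["p"], range(20)], names=["population", "brood_year"])
            fit = ps.FitResult(a={"p": 0.0}, b=None, c=None, sigma=sigma, loglik=np.nan,
                               n_obs=20, k_params=2, residuals=pd.Series(resid, index=idx),
                               fitted=pd.Series(np.zeros(20), index=idx))
            oracle = norm.logpdf(resid, scale=sigma).sum()
            assert ps.loglik(fit) == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_sigma_raises(self):
        idx = pd.MultiIndex.from_product([["p"], range(3)], names=["population", "brood_year"])
        fit = ps.FitResult(a={"p": 0.0}, b=None, c=None, sigma=0.0, loglik=np.nan,
                           n_obs=3, k_params=2, residuals=pd.Series(np.zeros(3), index=idx),
                           fitted=pd.Series(np.zeros(3), index=idx), degenerate=True)
        with pytest.raises(DegenerateLikelihoodError):
            ps.loglik(fit)
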