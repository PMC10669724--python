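import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from gxecross.regression import OlsFit, fit_ols
from gxecross.ros import (UndefinedCrossoverError, crossover_point, holm_correction,
                          jn_boundaries, nonlinearity_probe, pa_index, poi_index)


def make_fit(b_z, b_xz, v_zz=0.0, v_zp=0.0, v_pp=0.0, df2=100):
    """Hand-built interaction fit with the given moderator/product
    coefficients and covariance entries."""
    terms = ["(Intercept)", "x", "z", "x*z"]
    coef = np.array([0.0, 0.5, b_z, b_xz])
    cov = np.zeros((4, 4))
    cov[2, 2], cov[3, 3] = v_zz, v_pp
    cov[2, 3] = cov[3, 2] = v_zp
    k = len(terms)
    return OlsFit(terms=terms, coef=coef, beta_std=np.full(k, np.nan),
                  se=np.sqrt(np.diag(cov)), t=np.zeros(k), p=np.ones(k),
                  cov=cov, r2=0.5, sse=50.0, sst=100.0, f=10.0, df1=3,
                  df2=df2, f_p=0.001, n=df2 + k)


def simulated_interaction_fit(rng, n=400, b_z=-0.3, b_xz=0.25, noise=1.0):
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = 0.4 * x + b_z * z + b_xz * x * z + noise * rng.normal(size=n)
    df = pd.DataFrame({"x": x, "z": z, "y": y})
    return fit_ols("y", ["x", "z", "x*z"], df)


class TestJnBoundaries:
    def test_zero_variance_limit_single_crossing(self):
        res = jn_boundaries(make_fit(b_z=-1.0, b_xz=2.0), "x", "z")
        assert res.lower == pytest.approx(0.5, abs=1e-12)
        assert res.upper is None

    def test_roots_reproduce_critical_ratio(self, rng):
        fit = simulated_interaction_fit(rng)
        res = jn_boundaries(fit, "x", "z", alpha=0.05)
        v_zz = fit.cov_of("z", "z")
        v_zp = fit.cov_of("z", "x*z")
        v_pp = fit.cov_of("x*z", "x*z")
        for b in res.boundaries:
            theta = fit.coef_of("z") + fit.coef_of("x*z") * b
            se = np.sqrt(v_zz + 2 * b * v_zp + b * b * v_pp)
            assert abs(theta) / se == pytest.approx(res.t_crit, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        # brute-force |theta(X)|/SE over a 1e-4 grid as independent oracle
        grid = np.arange(-6.0, 6.0, 1e-4)
        for _ in range(8):
            fit = simulated_interaction_fit(rng)
            res = jn_boundaries(fit, "x", "z")
            theta = fit.coef_of("z") + fit.coef_of("x*z") * grid
            var = (fit.cov_of("z", "z") + 2 * grid * fit.cov_of("z", "x*z")
                   + grid ** 2 * fit.cov_of("x*z", "x*z"))
            gfun = np.abs(theta) / np.sqrt(var) - res.t_crit
            crossings = grid[np.nonzero(np.diff(np.sign(gfun)))[0]]
            analytic = [b for b in res.boundaries if -6 < b < 6]
            assert len(crossings) == len(analytic)
            for c, a in zip(sorted(crossings), sorted(analytic)):
                assert abs(c - a) < 1e-3

    def test_no_moderation_flag(self):
        res = jn_boundaries(make_fit(b_z=0.0, b_xz=0.0, v_zz=0.1, v_pp=0.1),
                            "x", "z")
        assert res.classification == "no moderation"
        assert res.boundaries == []

    def test_observed_range_reported(self, rng):
        fit = simulated_interaction_fit(rng)
        xobs = rng.normal(size=500)
        res = jn_boundaries(fit, "x", "z", x_observed=xobs)
        lo, hi = res.eval_range_observed
        assert lo == xobs.min() and hi == xobs.max()


class TestCrossoverPoint:
    def test_zero_moderator_effect_crosses_at_center(self):
        assert crossover_point(make_fit(0.0, 0.7), "x", "z") == 0.0

    def test_study_coefficients_ratio(self):
        # moderator -0.05, interaction 0.09 -> crossover 0.5556
        fit = make_fit(b_z=-0.05, b_xz=0.09)
        assert crossover_point(fit, "x", "z") == pytest.approx(0.5556, abs=5e-5)

    def test_scale_invariance(self):
        a = crossover_point(make_fit(-0.4, 0.3), "x", "z")
        b = crossover_point(make_fit(-0.8, 0.6), "x", "z")
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_interaction_undefined(self):
        with pytest.raises(UndefinedCrossoverError):
            crossover_point(make_fit(0.5, 0.0), "x", "z")


class TestPoiIndex:
    def test_midpoint_gives_half(self):
        assert poi_index(0.0, (-2.0, 2.0)).poi == pytest.approx(0.5)

    def test_matches_quadrature_oracle(self, rng):
        # integrate the between-line area on each side of the crossover
        for _ in range(10):
            s1, s2 = rng.normal(size=2)
            xc = rng.uniform(-1, 1)
            lo, hi = -3.0, 2.5
            diff = lambda x: abs((s1 - s2) * (x - xc))
            bad = integrate.quad(diff, lo, xc)[0]
            good = integrate.quad(diff, xc, hi)[0]
            expected = good / (good + bad)
            assert poi_index(xc, (lo, hi)).poi == pytest.approx(expected, abs=1e-8)

    def test_mirror_symmetry(self, rng):
        lo, hi = -4.31, 1.85
        for xc in rng.uniform(lo, hi, size=5):
            p1 = poi_index(xc, (lo, hi)).poi
            p2 = poi_index(lo + hi - xc, (lo, hi)).poi
            assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_negative_orientation_flips(self):
        p_pos = poi_index(1.0, (-2.0, 2.0), orientation=1).poi
        p_neg = poi_index(1.0, (-2.0, 2.0), orientation=-1).poi
        assert p_pos + p_neg == pytest.approx(1.0)

    def test_crossover_outside_range_clamped(self):
        assert poi_index(5.0, (-2.0, 2.0)).poi == 0.0
        assert poi_index(-5.0, (-2.0, 2.0)).poi == 1.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            poi_index(0.0, (1.0, 1.0))


class TestPaIndex:
    def test_all_above_crossover(self):
        assert pa_index(0.0, np.full(10, 2.0)).pa == 1.0

    def test_empirical_converges_to_normal_tail(self, rng):
        xc = 0.49
        draws = rng.standard_normal(1_000_000)
        emp = pa_index(xc, draws, mode="empirical").pa
        ana = pa_index(xc, mode="normal").pa
        p = stats.norm.sf(xc)
        assert ana == pytest.approx(p, abs=1e-12)
        assert abs(emp - ana) < 3 * np.sqrt(p * (1 - p) / 1e6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pa_index(0.0, np.array([]))


class TestNonlinearityProbe:
    def test_true_quadratic_detected(self, rng):
        hits = 0
        for _ in range(10):
            n = 745
            x, z = rng.normal(size=n), rng.integers(0, 2, n).astype(float)
            y = 0.3 * x + 0.15 * x ** 2 + rng.normal(size=n)
            df = pd.DataFrame({"x": x, "z": z, "y": y})
            chk = nonlinearity_probe("y", "x", "z", df)
            hits += chk.p_x2 < 0.001
        assert hits >= 8

    def test_linear_truth_calibrated(self, rng):
        rejections = 0
        reps = 150
        for _ in range(reps):
            n = 300
            x, z = rng.normal(size=n), rng.integers(0, 2, n).astype(float)
            y = 0.3 * x - 0.2 * z + rng.normal(size=n)
            df = pd.DataFrame({"x": x, "z": z, "y": y})
            chk = nonlinearity_probe("y", "x", "z", df)
            rejections += chk.p_x2 < 0.05
        assert 0.005 <= rejections / reps <= 0.12


class TestHolmCorrection:
    def test_worked_example(self):
        res = holm_correction([0.005, 0.5, 0.9], alpha=0.05)
        assert res.critical[0] == pytest.approx(0.05 / 3, abs=1e-12)
        assert round(res.critical[0], 2) == 0.02
        assert res.reject.tolist() == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert not holm_correction([1.0, 1.0, 1.0]).reject.any()

    def test_single_pvalue_uses_alpha(self):
        res = holm_correction([0.04], alpha=0.05)
        assert res.critical[0] == 0.05 and res.reject[0]

    def test_step_down_stops_at_first_failure(self):
        res = holm_correction([0.001, 0.04, 0.012], alpha=0.05)
        # sorted: 0.001 (crit .0167, reject), 0.012 (crit .025, reject),
        # 0.04 (crit .05, reject) -> all rejected
        assert res.reject.all()
        res2 = holm_correction([0.001, 0.03, 0.9], alpha=0.05)
        # 0.03 > 0.025 stops the chain even though 0.03 < alpha
        assert res2.reject.tolist() == [True, False, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_between_bonferroni_and_uncorrected(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=8)
        m = len(p)
        holm = holm_correction(p, alpha=0.05).reject
        bonf = p <= 0.05 / m
        raw = p <= 0.05
        assert (holm | ~bonf).all()   # Holm rejects every Bonferroni rejection
        assert (~holm | raw).all()    # and only uncorrected-significant ones
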