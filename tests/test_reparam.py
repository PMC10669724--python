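import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import gxecross as g
from gxecross.regression import fit_ols
from gxecross.reparam import (EstimationError, ReparamSpec, fit_reparam,
                              information_criteria, nested_f_vs_full,
                              select_model)
from tests.conftest import COVARIATES, standardized_cohort


def random_gxe_dataset(rng, n=200):
    """Unstructured dataset with two groups, environment and covariates."""
    d2 = (rng.random(n) < 0.3).astype(float)
    x = rng.normal(size=n)
    Z = rng.normal(size=(n, 2))
    y = (0.2 + 0.1 * x + 0.25 * d2 * x - 0.3 * d2
         + Z @ [0.3, -0.2] + rng.normal(size=n))
    df = pd.DataFrame({"reading": y, "home_supervision": x, "risk": d2,
                       "c1": Z[:, 0], "c2": Z[:, 1]})
    return df


def spec_for(df_or_model, model=None):
    if model is None:
        return ReparamSpec(df_or_model)
    return ReparamSpec(model, covariates=("c1", "c2"))


class TestFitReparam:
    def test_noiseless_weak_diathesis_stress_inverted_exactly(self):
        _, view, truth = standardized_cohort(seed=42, residual_sd=0.0)
        fit = fit_reparam(view, ReparamSpec("d"))
        for name, val in (("B0", 5.14), ("B1", 0.10), ("B3", 0.21), ("B4", 0.08),
                          ("B5", -0.52), ("B6", 0.10), ("B7", 0.14), ("B8", 0.01)):
            assert fit.params[name] == pytest.approx(val, abs=1e-8)
        assert fit.params["C"] == pytest.approx(truth["crossover_realized"], abs=1e-12)

    def test_model_b_sse_equals_unconstrained_ols(self, rng):
        for _ in range(5):
            df = random_gxe_dataset(rng)
            fit_b = fit_reparam(df, spec_for(df, "b"))
            lin = fit_ols("reading",
                          ["risk", "home_supervision", "risk*home_supervision",
                           "c1", "c2"], df)
            assert fit_b.sse == pytest.approx(lin.sse, rel=1e-10)

    def test_model_a_closed_form_attains_nls_optimum(self, rng):
        # independent oracle: direct nonlinear least squares over
        # (B0, B3, covs, C) cannot beat the closed-form fit
        df = random_gxe_dataset(rng)
        fit_a = fit_reparam(df, spec_for(df, "a"))
        y = df["reading"].to_numpy()
        x = df["home_supervision"].to_numpy()
        d2 = df["risk"].to_numpy()
        Z = df[["c1", "c2"]].to_numpy()

        def resid(theta):
            b0, b3, z1, z2, c = theta
            return y - (b0 + b3 * d2 * (x - c) + Z @ [z1, z2])

        sol = optimize.least_squares(resid, x0=[0, 0.1, 0, 0, 0.0], method="lm")
        assert fit_a.sse <= 2 * sol.cost + 1e-8
        assert fit_a.sse == pytest.approx(2 * sol.cost, rel=1e-6)

    def test_fixed_crossover_uses_sample_extremes(self, rng):
        df = random_gxe_dataset(rng)
        fit_d = fit_reparam(df, spec_for(df, "d"))
        fit_f = fit_reparam(df, spec_for(df, "f"))
        assert fit_d.params["C"] == df["home_supervision"].max()
        assert fit_f.params["C"] == df["home_supervision"].min()
        assert fit_d.c_ci is None and fit_d.se.get("C") is None

    def test_strong_constraint_binds_when_slopes_equal(self, rng):
        n = 300
        x = rng.normal(size=n)
        d2 = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({"reading": 0.4 * x + 0.1 * rng.normal(size=n),
                           "home_supervision": x, "risk": d2,
                           "c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        fit_a = fit_reparam(df, spec_for(df, "a"))
        fit_b = fit_reparam(df, spec_for(df, "b"))
        assert fit_a.params["B1"] == 0.0
        assert fit_a.sse > fit_b.sse
        assert fit_b.params["B1"] == pytest.approx(0.4, abs=0.05)

    def test_unidentified_crossover_raises(self, rng):
        n = 100
        x = rng.normal(size=n)
        d2 = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({"reading": 0.5 * x, "home_supervision": x,
                           "risk": d2, "c1": np.zeros(n) + rng.normal(size=n),
                           "c2": rng.normal(size=n)})
        with pytest.raises(EstimationError):
            fit_reparam(df, spec_for(df, "b"))

    def test_nesting_r2_inequalities(self, cohort_d):
        _, view, _ = cohort_d
        fits = {m: fit_reparam(view, ReparamSpec(m)) for m in "abcdef"}
        eps = 1e-10
        assert fits["a"].r2 <= fits["b"].r2 + eps
        assert fits["c"].r2 <= min(fits["a"].r2, fits["d"].r2) + eps
        assert fits["e"].r2 <= min(fits["a"].r2, fits["f"].r2) + eps
        assert fits["d"].r2 <= fits["b"].r2 + eps
        assert fits["f"].r2 <= fits["b"].r2 + eps

    def test_crossover_ci_coverage_under_free_crossover_truth(self):
        hits = 0
        n_seeds = 150
        for s in range(n_seeds):
            _, view, _ = standardized_cohort(seed=9000 + s, model="b",
                                             b1=0.07, b3=0.31, crossover=0.49)
            fit = fit_reparam(view, ReparamSpec("b"))
            lo, hi = fit.c_ci
            hits += lo <= 0.49 <= hi
        # binomial 3-SE band around the nominal 0.95 at 150 replicates
        assert 0.90 <= hits / n_seeds <= 1.0

    def test_delta_method_se_matches_parametric_bootstrap(self):
        # well-identified crossover (large slope contrast); under weak
        # identification the bootstrap distribution of the ratio C is
        # heavy-tailed and no SE comparison is meaningful
        _, view, _ = standardized_cohort(seed=77, model="b", b1=0.07, b3=0.55,
                                         crossover=0.49)
        fit = fit_reparam(view, ReparamSpec("b"))
        w = view.data
        p = fit.params
        x = w["home_supervision"].to_numpy()
        d2 = w["risk"].to_numpy()
        Z = w[list(COVARIATES)].to_numpy()
        mean = (p["B0"] + np.where(d2 == 1, p["B3"], p["B1"]) * (x - p["C"])
                + Z @ [p["B4"], p["B5"], p["B6"], p["B7"], p["B8"]])
        sigma = np.sqrt(fit.sse / (fit.n - fit.n_free))
        rng = np.random.default_rng(5)
        draws = []
        boot = view.data.copy()
        for _ in range(300):
            boot["reading"] = mean + sigma * rng.standard_normal(len(mean))
            draws.append(fit_reparam(boot, ReparamSpec("b")).params["C"])
        ratio = fit.se["C"] / np.std(draws, ddof=1)
        assert 0.85 <= ratio <= 1.15


class TestNestedF:
    def test_identical_fits_give_zero(self, cohort_d):
        _, view, _ = cohort_d
        fit = fit_reparam(view, ReparamSpec("b"))
        F, dfs, p, dr2 = nested_f_vs_full(fit, fit)
        assert F == 0.0 and p == 1.0 and dr2 == 0.0

    def test_single_constraint_f_equals_t_squared(self, cohort_d):
        # model a releases exactly the environment main effect relative to b
        _, view, _ = cohort_d
        fa = fit_reparam(view, ReparamSpec("a"))
        fb = fit_reparam(view, ReparamSpec("b"))
        F, dfs, p, _ = nested_f_vs_full(fa, fb)
        w = view.data.dropna(subset=["reading", "home_supervision", "risk"])
        lin = fit_ols("reading",
                      ["risk", "home_supervision", "risk*home_supervision",
                       *COVARIATES], w)
        assert dfs == (1, fb.n - fb.n_free)
        assert F == pytest.approx(lin.t[lin["home_supervision"]] ** 2, abs=1e-6)

    def test_degrees_of_freedom_follow_released_constraints(self, cohort_d):
        _, view, _ = cohort_d
        fits = {m: fit_reparam(view, ReparamSpec(m)) for m in "abcde"}
        assert nested_f_vs_full(fits["c"], fits["b"])[1][0] == 2  # B1 and C
        assert nested_f_vs_full(fits["d"], fits["b"])[1][0] == 1  # C only
        assert nested_f_vs_full(fits["c"], fits["d"])[1][0] == 1  # B1 only

    def test_non_nested_pair_rejected(self, cohort_d):
        _, view, _ = cohort_d
        fd = fit_reparam(view, ReparamSpec("d"))
        ff = fit_reparam(view, ReparamSpec("f"))
        with pytest.raises(Exception):
            nested_f_vs_full(fd, ff)

    def test_under_true_model_f_vs_b_is_calibrated(self):
        # model d truth: F(d vs b) should reject at ~alpha
        rej = 0
        n_seeds = 120
        for s in range(n_seeds):
            _, view, _ = standardized_cohort(seed=11000 + s)
            fd = fit_reparam(view, ReparamSpec("d"))
            fb = fit_reparam(view, ReparamSpec("b"))
            rej += nested_f_vs_full(fd, fb)[2] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rej / n_seeds - 0.05) <= 3 * se


class TestInformationCriteria:
    def test_crossover_penalty_arithmetic(self, cohort_d):
        _, view, _ = cohort_d
        fit = fit_reparam(view, ReparamSpec("b"))
        aic0, bic0 = information_criteria(fit, count_crossover=False)
        aic1, bic1 = information_criteria(fit, count_crossover=True)
        assert aic1 - aic0 == pytest.approx(2.0, abs=1e-12)
        assert bic1 - bic0 == pytest.approx(np.log(fit.n), abs=1e-12)

    def test_equal_k_ordering_follows_sse(self, cohort_d):
        _, view, _ = cohort_d
        fc = fit_reparam(view, ReparamSpec("c"))
        fe = fit_reparam(view, ReparamSpec("e"))
        assert fc.n_free == fe.n_free
        assert (fc.aic < fe.aic) == (fc.sse < fe.sse)

    def test_true_model_beats_wrong_fixed_crossover_on_average(self):
        wins = 0
        n_seeds = 40
        for s in range(n_seeds):
            _, view, _ = standardized_cohort(seed=12000 + s)
            fd = fit_reparam(view, ReparamSpec("d"))
            ff = fit_reparam(view, ReparamSpec("f"))
            wins += fd.aic < ff.aic
        assert wins / n_seeds >= 0.8


class TestSelectModel:
    def test_comparison_table_has_all_six_models(self, cohort_d):
        _, view, _ = cohort_d
        comp = select_model(view)
        assert sorted(comp.fits) == list("abcdef")
        frame = comp.to_frame()
        assert list(frame.columns) == list("abcdef")
        assert comp.selected in comp.fits
        assert "model" in comp.rationale

    def test_full_model_rarely_wins_when_no_interaction(self):
        # equal slopes truth: some constrained alternative should survive
        picks_b = 0
        n_seeds = 40
        for s in range(n_seeds):
            _, view, _ = standardized_cohort(seed=13000 + s, model="null",
                                             b1=0.15, b3=0.15)
            comp = select_model(view)
            picks_b += comp.selected == "b"
        assert picks_b / n_seeds <= 0.15

    def test_strong_vantage_truth_recovered_at_large_n(self):
        hits = 0
        for s in range(8):
            _, view, _ = standardized_cohort(seed=14000 + s, n=4000, model="e",
                                             b3=0.25)
            comp = select_model(view)
            hits += comp.selected == "e"
        assert hits >= 5

    def test_parsimony_rule_available(self, cohort_d):
        _, view, _ = cohort_d
        comp = select_model(view, rule="parsimony")
        assert comp.selected in "abcdef"
        with pytest.raises(ValueError):
            select_model(view, rule="nonsense")
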