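"""Re-parameterized gene-by-environment crossover regression.

The two genotype groups share an intercept B0 and covariate effects B4..B8
but have their own environment slopes pivoting about a common crossover
point C:

    non-risk group (D1):  Y = B0 + B1 (X - C) + B4 X4 + ... + B8 X8 + e
    risk group     (D2):  Y = B0 + B3 (X - C) + B4 X4 + ... + B8 X8 + e

Six nested variants distinguish the competing interaction theories by where
C sits and whether the non-risk slope B1 is freed:

    a  strong differential susceptibility   B1 = 0, C free
    b  weak differential susceptibility     B1 free, C free (full model)
    c  strong diathesis-stress              B1 = 0, C = max(X)
    d  weak diathesis-stress                B1 free, C = max(X)
    e  strong vantage sensitivity           B1 = 0, C = min(X)
    f  weak vantage sensitivity             B1 free, C = min(X)

Every variant is an exact linear re-parameterization, so all six are solved
in closed form.  With C free, model b maps one-to-one onto the unconstrained
OLS interaction model (same SSE) via C = -g_D2/g_D2X, B1 = g_X,
B3 = g_X + g_D2X, B0 = g_0 + B1 C; model a (B1 = 0) maps onto the model
without the environment main effect via B0 = g_0, B3 = g_D2X,
C = -g_D2/g_D2X.  Standard errors of the nonlinear parameters (C, and B0 in
model b) come from the delta method on the OLS coefficient covariance.  All
variants nest in model b, so each is screened by an F test against b;
AIC/BIC round out the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import fit_ols, SpecificationError

__all__ = [
    "ReparamSpec", "ReparamFit", "ComparisonTable", "EstimationError",
    "MODEL_LABELS", "fit_reparam", "nested_f_vs_full", "information_criteria",
    "select_model",
]

MODEL_LABELS = {
    "a": "strong differential susceptibility",
    "b": "weak differential susceptibility",
    "c": "strong diathesis-stress",
    "d": "weak diathesis-stress",
    "e": "strong vantage sensitivity",
    "f": "weak vantage sensitivity",
}

COVARIATE_PARAMS = ("B4", "B5", "B6", "B7", "B8")


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReparamSpec:
    """One variant of the crossover regression on named table columns.

    ``risk_indicator`` is a 0/1 column: 1 = risk/plastic genotype (slope B3),
    0 = non-risk (slope B1).  For the study's focal SNP rs11629841 the GT
    genotype is the risk group, TT the non-risk group.
    """

    model: str
    outcome: str = "reading"
    environment: str = "home_supervision"
    risk_indicator: str = "risk"
    covariates: tuple[str, ...] = (
        "gender", "age", "parental_education", "parental_occupation", "monthly_income",
    )

    def __post_init__(self):
        if self.model not in MODEL_LABELS:
            raise ValueError(f"model must be one of {sorted(MODEL_LABELS)}")

    @property
    def strong(self) -> bool:
        """B1 constrained to 0."""
        return self.model in ("a", "c", "e")

    @property
    def crossover_mode(self) -> str:
        return {"a": "free", "b": "free", "c": "max", "d": "max",
                "e": "min", "f": "min"}[self.model]

    @property
    def constraints(self) -> frozenset[str]:
        out = set()
        if self.strong:
            out.add("B1=0")
        if self.crossover_mode != "free":
            out.add(f"C={self.crossover_mode}")
        return frozenset(out)


@dataclass
class ReparamFit:
    spec: ReparamSpec
    params: dict[str, float]      # B0, B1, B3, covariate Bs, C
    se: dict[str, float]          # absent/NaN for constrained parameters
    c_ci: tuple[float, float] | None
    sse: float
    sst: float
    r2: float
    f: float
    df1: int
    df2: int
    f_p: float
    n: int
    n_free: int                   # free mean parameters incl. C when free
    aic: float = np.nan
    bic: float = np.nan
    converged: bool = True
    n_restarts_used: int = 0

    @property
    def model(self) -> str:
        return self.spec.model

    def param_p(self, name: str) -> float:
        se = self.se.get(name, np.nan)
        if not np.isfinite(se) or se <= 0:
            return np.nan
        t = self.params[name] / se
        return float(2 * stats.t.sf(abs(t), self.n - self.n_free))


@dataclass
class ComparisonTable:
    fits: dict[str, ReparamFit]
    f_vs_b: dict[str, tuple[float, tuple[int, int], float, float]]  # F, dfs, p, dR2
    rejected: dict[str, bool]
    selected: str
    rationale: str
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        order = ["B0", "C", "B1", "B3", *COVARIATE_PARAMS,
                 "R2", "F", "df", "F_vs_b", "F_vs_b_p", "AIC", "BIC"]
        for m, fit in self.fits.items():
            col = {}
            for p in ("B0", "C", "B1", "B3", *COVARIATE_PARAMS):
                v = fit.params.get(p, np.nan)
                s = fit.se.get(p, np.nan)
                col[p] = f"{v:.2f} ({s:.2f})" if np.isfinite(s) else f"{v:.2f} (-)"
            col["R2"] = f"{fit.r2:.3f}"
            col["F"] = f"{fit.f:.2f}"
            col["df"] = f"({fit.df1}, {fit.df2})"
            if m in self.f_vs_b:
                F, dfs, p, dr2 = self.f_vs_b[m]
                col["F_vs_b"] = f"{F:.2f} {dfs}"
                col["F_vs_b_p"] = f"{p:.4f}"
            else:
                col["F_vs_b"] = "-"
                col["F_vs_b_p"] = "-"
            col["AIC"] = f"{fit.aic:.3f}"
            col["BIC"] = f"{fit.bic:.3f}"
            rows[m] = col
        return pd.DataFrame(rows).reindex(order)


def _extract(table, spec: ReparamSpec):
    df = table if isinstance(table, pd.DataFrame) else table.data
    cols = [spec.outcome, spec.environment, spec.risk_indicator, *spec.covariates]
    work = df[cols].astype(float).dropna()
    y = work[spec.outcome].to_numpy()
    x = work[spec.environment].to_numpy()
    d2 = work[spec.risk_indicator].to_numpy()
    if not set(np.unique(d2)) <= {0.0, 1.0}:
        raise ValueError(f"'{spec.risk_indicator}' must be a 0/1 indicator")
    if d2.sum() == 0 or d2.sum() == len(d2):
        raise ValueError("both genotype groups must be non-empty")
    Z = work[list(spec.covariates)].to_numpy()
    return y, x, d2, Z


def _param_names(spec: ReparamSpec, free_c: bool) -> list[str]:
    names = ["B0"]
    if not spec.strong:
        names.append("B1")
    names.append("B3")
    names += list(COVARIATE_PARAMS[: len(spec.covariates)])
    if free_c:
        names.append("C")
    return names


def _finish(spec, names, theta, cov, sse, y, n, free_c, restarts=0, converged=True):
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - sse / sst
    # printed-table df convention: slope terms only (no intercept, no C)
    df1 = len([nm for nm in names if nm not in ("B0", "C")])
    df2 = n - 1 - df1
    if 1 - r2 > 0:
        f = (r2 / df1) / ((1 - r2) / df2)
    else:
        f = np.inf  # perfect (noiseless) fit
    f_p = float(stats.f.sf(f, df1, df2))
    params = dict(zip(names, theta))
    if spec.strong:
        params["B1"] = 0.0
    se = {}
    if cov is not None:
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = dict(zip(names, sds))
    n_free = len(names)
    c_ci = None
    if free_c and "C" in se and np.isfinite(se["C"]):
        tcrit = stats.t.ppf(0.975, n - n_free)
        c_ci = (params["C"] - tcrit * se["C"], params["C"] + tcrit * se["C"])
    fit = ReparamFit(
        spec=spec, params=params, se=se, c_ci=c_ci, sse=float(sse), sst=sst,
        r2=float(r2), f=float(f), df1=df1, df2=df2, f_p=f_p, n=n,
        n_free=n_free, converged=converged, n_restarts_used=restarts,
    )
    if sse > 0:
        fit.aic, fit.bic = information_criteria(fit)
    return fit


def fit_reparam(table, spec: ReparamSpec, slope_tol: float = 1e-10) -> ReparamFit:
    """Fit one crossover-regression variant.

    Every variant is closed-form least squares (see module docstring); the
    free-C variants get delta-method standard errors for the nonlinearly
    mapped parameters.  Raises :class:`EstimationError` when the crossover is
    unidentified (group slopes indistinguishable with C free).
    """
    y, x, d2, Z = _extract(table, spec)
    n = len(y)
    d1 = 1.0 - d2
    free_c = spec.crossover_mode == "free"
    names = _param_names(spec, free_c)

    if not free_c:
        C = float(x.max()) if spec.crossover_mode == "max" else float(x.min())
        cols = [np.ones(n)]
        if not spec.strong:
            cols.append(d1 * (x - C))
        cols.append(d2 * (x - C))
        X = np.column_stack(cols + [Z])
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ theta
        sse = float(resid @ resid)
        cov = sse / (n - X.shape[1]) * np.linalg.inv(X.T @ X)
        fit = _finish(spec, names, theta, cov, sse, y, n, free_c=False)
        fit.params["C"] = C
        return fit

    # --- free crossover: exact linear re-parameterization ------------------
    zn = [f"z{i}" for i in range(Z.shape[1])]
    df_lin = pd.DataFrame({"y": y, "d2": d2, "x": x,
                           **{f"z{i}": Z[:, i] for i in range(Z.shape[1])}})
    lin_terms = (["d2", "x", "d2*x"] if spec.model == "b" else ["d2", "d2*x"]) + zn
    lin = fit_ols("y", lin_terms, df_lin)
    g_d2 = lin.coef_of("d2")
    g_d2x = lin.coef_of("d2*x")
    if abs(g_d2x) < slope_tol:
        raise EstimationError(
            "group slopes are indistinguishable; crossover point unidentified")
    C0 = -g_d2 / g_d2x
    covs0 = [lin.coef_of(z) for z in zn]
    gnames = ["(Intercept)", *lin_terms]
    V = lin.cov[np.ix_([lin[t] for t in gnames], [lin[t] for t in gnames])]
    dC_dd2 = -1.0 / g_d2x
    dC_dd2x = g_d2 / g_d2x ** 2
    iI, iD2 = gnames.index("(Intercept)"), gnames.index("d2")
    iD2X = gnames.index("d2*x")
    nz = Z.shape[1]

    if spec.model == "b":
        g0, g_x = lin.coef_of("(Intercept)"), lin.coef_of("x")
        iX = gnames.index("x")
        B1_0, B3_0 = g_x, g_x + g_d2x
        theta = np.array([g0 + B1_0 * C0, B1_0, B3_0, *covs0, C0])
        G = np.zeros((len(theta), len(gnames)))
        G[0, iI] = 1.0                   # B0 = g0 + g_x * C
        G[0, iD2] = g_x * dC_dd2
        G[0, iX] = C0
        G[0, iD2X] = g_x * dC_dd2x
        G[1, iX] = 1.0                   # B1 = g_x
        G[2, iX] = 1.0                   # B3 = g_x + g_d2x
        G[2, iD2X] = 1.0
    else:
        # model a: Y = B0 + B3 D2 (X - C) + covs is linear in
        # (B0, -B3 C, B3) over columns (1, D2, D2*X)
        theta = np.array([lin.coef_of("(Intercept)"), g_d2x, *covs0, C0])
        G = np.zeros((len(theta), len(gnames)))
        G[0, iI] = 1.0                   # B0 = g0
        G[1, iD2X] = 1.0                 # B3 = g_d2x
    for i in range(nz):
        G[-1 - nz + i, gnames.index(zn[i])] = 1.0
    G[-1, iD2] = dC_dd2                  # C = -g_d2 / g_d2x
    G[-1, iD2X] = dC_dd2x
    cov = G @ V @ G.T
    return _finish(spec, names, theta, cov, lin.sse, y, n, free_c=True)


def nested_f_vs_full(restricted: ReparamFit, full: ReparamFit):
    """F test of a constrained variant against a nesting one.

    F = ((SSE_r - SSE_f) / ddf) / (SSE_f / (n - k_f)) with ddf counting every
    released constraint including the crossover point.  Returns
    (F, (ddf, df_denom), p, delta_R2).
    """
    if not restricted.spec.constraints >= full.spec.constraints:
        raise SpecificationError(
            f"model {restricted.model} is not nested in {full.model}")
    if restricted.n != full.n:
        raise SpecificationError("fits use different data")
    if restricted.spec.constraints == full.spec.constraints:
        return 0.0, (0, full.n - full.n_free), 1.0, 0.0
    ddf = full.n_free - restricted.n_free
    df_den = full.n - full.n_free
    num = max(restricted.sse - full.sse, 0.0) / ddf
    den = full.sse / df_den
    F = num / den
    p = float(stats.f.sf(F, ddf, df_den))
    dr2 = full.r2 - restricted.r2
    return float(F), (ddf, df_den), p, float(dr2)


def information_criteria(fit: ReparamFit, count_crossover: bool = False) -> tuple[float, float]:
    """AIC = n ln(SSE/n) + 2k and BIC = n ln(SSE/n) + k ln(n).

    k counts the free mean parameters; by default the crossover point is not
    counted even when free (the convention consistent with the study's
    printed table), set ``count_crossover=True`` to include it.
    """
    if fit.sse <= 0:
        raise ValueError("information criteria need SSE > 0")
    k = fit.n_free
    if not count_crossover and fit.spec.crossover_mode == "free":
        k -= 1
    base = fit.n * np.log(fit.sse / fit.n)
    return float(base + 2 * k), float(base + k * np.log(fit.n))


def select_model(
    table,
    outcome: str = "reading",
    environment: str = "home_supervision",
    risk_indicator: str = "risk",
    covariates: tuple[str, ...] = (
        "gender", "age", "parental_education", "parental_occupation", "monthly_income"),
    alpha: float = 0.05,
    rule: str = "aic",
) -> ComparisonTable:
    """Fit all six variants, screen each against model b, and pick a winner.

    Every alternative whose F-vs-b is significant at ``alpha`` is rejected.
    If all alternatives fall, model b stands.  Among surviving alternatives
    the default rule picks the lowest AIC — computed with the free crossover
    counted as a fitted parameter, so a free-C variant is not rewarded for a
    parameter it did estimate — with ties broken by BIC, then fewest free
    parameters.  ``rule="parsimony"`` instead prefers the fewest free
    parameters (ties: BIC, then AIC).  Per-model estimation errors are
    reported without aborting the table.
    """
    mk = lambda m: ReparamSpec(m, outcome, environment, risk_indicator, tuple(covariates))
    fits: dict[str, ReparamFit] = {}
    errors: dict[str, str] = {}
    for m in "abcdef":
        try:
            fits[m] = fit_reparam(table, mk(m))
        except (EstimationError, ValueError, np.linalg.LinAlgError) as exc:
            errors[m] = str(exc)
    if "b" not in fits:
        raise EstimationError(f"full model b failed: {errors.get('b')}")
    full = fits["b"]
    f_vs_b, rejected = {}, {}
    lines = []
    for m in "acdef":
        if m not in fits:
            lines.append(f"model {m}: estimation failed ({errors[m]})")
            continue
        F, dfs, p, dr2 = nested_f_vs_full(fits[m], full)
        f_vs_b[m] = (F, dfs, p, dr2)
        rejected[m] = p < alpha
        verdict = "rejected" if rejected[m] else "retained"
        lines.append(
            f"model {m} ({MODEL_LABELS[m]}): F{dfs} = {F:.2f}, p = {p:.4f}, "
            f"dR2 = {dr2:.4f} -> {verdict}")
    survivors = [m for m in "acdef" if m in fits and not rejected.get(m, True)]
    if not survivors:
        selected = "b"
        lines.append("all constrained alternatives rejected -> model b "
                     f"({MODEL_LABELS['b']}) accepted")
    else:
        if rule == "parsimony":
            key = lambda m: (fits[m].n_free, fits[m].bic, fits[m].aic)
        elif rule == "aic":
            ic = {m: information_criteria(fits[m], count_crossover=True)
                  for m in survivors}
            key = lambda m: (ic[m][0], ic[m][1], fits[m].n_free)
        else:
            raise ValueError("rule must be 'aic' or 'parsimony'")
        selected = min(survivors, key=key)
        lines.append(
            f"surviving alternatives {survivors} -> model {selected} "
            f"({MODEL_LABELS[selected]}) accepted by {rule} rule")
    return ComparisonTable(fits=fits, f_vs_b=f_vs_b, rejected=rejected,
                           selected=selected, rationale="\n".join(lines),
                           errors=errors)
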