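"""Cohort table I/O, standardization, scale reliability, EM imputation and
descriptive correlations.

The single tabular currency of the pipeline is the :class:`CohortTable`: one
row per child carrying the outcome (reading achievement), the environmental
exposure (home supervision), demographic/SES covariates and string genotype
calls.  Missing entries are NaN (numeric columns) or None (genotype calls) —
never silently zero-filled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "StandardizedView",
    "CorrelationReport",
    "EmTrace",
    "SchemaError",
    "DegenerateVariableError",
    "EmConvergenceError",
    "DEFAULT_SCHEMA",
    "ORDINAL_RANGES",
    "read_cohort",
    "zscore",
    "cronbach_alpha",
    "em_impute",
    "correlation_report",
]


class SchemaError(ValueError):
    """A required column/role is absent or the file cannot serve the schema."""


class DegenerateVariableError(ValueError):
    """A variable has zero variance (or too few values) where spread is required."""


class EmConvergenceError(RuntimeError):
    """EM did not converge within ``max_iter``; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: "EmTrace"):
        super().__init__(message)
        self.trace = trace


#: role -> (low, high) inclusive range for coded/ordinal variables.  Age is a
#: measurement, not a code; it is only required to be positive.
ORDINAL_RANGES: dict[str, tuple[float, float]] = {
    "gender": (1, 2),
    "parental_education": (1, 6),
    "parental_occupation": (1, 10),
    "monthly_income": (1, 5),
}

HS_ITEM_COLUMNS = [f"hs{i}" for i in range(1, 6)]

#: identity schema: role names double as column names.
DEFAULT_SCHEMA: dict[str, str] = {
    role: role
    for role in (
        "child_id",
        "gender",
        "age",
        "parental_education",
        "parental_occupation",
        "monthly_income",
        "home_supervision",
        "reading",
    )
}

REQUIRED_ROLES = (
    "gender",
    "age",
    "parental_education",
    "parental_occupation",
    "monthly_income",
    "home_supervision",
    "reading",
)


@dataclass
class CohortTable:
    """Per-child phenotypes, covariates and genotype calls.

    ``data`` holds numeric columns (NaN = missing) plus one string column per
    SNP (None/NaN = no call).  ``snp_columns`` names the genotype-call
    columns; ``warnings`` counts out-of-range cells converted to missing at
    read time.
    """

    data: pd.DataFrame
    snp_columns: list[str] = field(default_factory=list)
    warnings: int = 0

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise SchemaError("cohort must contain at least 2 rows")

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.snp_columns), self.warnings)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class StandardizedView:
    """A cohort table with selected columns replaced by Z scores.

    ``scale`` records the (mean, sd) used per standardized column so raw
    values remain recoverable.  Sample SD (denominator n-1) throughout.
    """

    data: pd.DataFrame
    standardized: list[str]
    scale: dict[str, tuple[float, float]]
    snp_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class CorrelationReport:
    variables: list[str]
    mean: pd.Series
    sd: pd.Series
    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    mode: str  # "pairwise" | "listwise"

    def to_markdown(self) -> str:
        """Correlation matrix with significance stars (* p<0.05, ** p<0.01)."""
        lines = ["| Variable | M ± SD | " + " | ".join(self.variables) + " |"]
        lines.append("|" + "---|" * (len(self.variables) + 2))
        for i, v in enumerate(self.variables):
            cells = []
            for j, w in enumerate(self.variables):
                if j > i:
                    cells.append("")
                    continue
                rij = self.r.loc[v, w]
                if np.isnan(rij):
                    cells.append("—")
                    continue
                stars = ""
                pij = self.p.loc[v, w]
                if v != w and np.isfinite(pij):
                    stars = "**" if pij < 0.01 else ("*" if pij < 0.05 else "")
                cells.append(f"{rij:.2f} {stars}".strip())
            lines.append(
                f"| {v} | {self.mean[v]:.2f} ± {self.sd[v]:.2f} | " + " | ".join(cells) + " |"
            )
        return "\n".join(lines)


def _coerce_numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    snp_columns: Sequence[str] | None = None,
) -> CohortTable:
    """Read and validate a cohort CSV/TSV.

    Parameters
    ----------
    path:
        CSV (or TSV, by extension) with a header row; missing cells are empty
        strings or "NA".
    schema:
        role -> column-name mapping; defaults to identity names.  Every
        required role (gender, age, parental_education, parental_occupation,
        monthly_income, home_supervision, reading) must be resolvable, except
        home_supervision which may instead be derived from item columns
        hs1..hs5 (their row mean).
    snp_columns:
        genotype-call column names to carry along as strings; defaults to any
        column starting with "rs".

    Out-of-range ordinal codes and non-positive ages become missing; each such
    cell increments ``warnings``.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, na_values=["", "NA"], keep_default_na=True,
                      dtype=str, skipinitialspace=True)
    if raw.empty:
        raise SchemaError(f"empty cohort file: {path}")

    df = pd.DataFrame(index=raw.index)
    warnings = 0
    have_items = all(c in raw.columns for c in HS_ITEM_COLUMNS)

    for role in REQUIRED_ROLES:
        col = schema.get(role, role)
        if col not in raw.columns:
            if role == "home_supervision" and have_items:
                continue
            raise SchemaError(f"required column for role '{role}' not found: '{col}'")

    if "child_id" in schema and schema["child_id"] in raw.columns:
        df["child_id"] = raw[schema["child_id"]]
    else:
        df["child_id"] = np.arange(1, len(raw) + 1).astype(str)

    for role in REQUIRED_ROLES:
        col = schema.get(role, role)
        if col not in raw.columns:
            continue
        vals = _coerce_numeric(raw[col].str.replace("−", "-", regex=False)
                               if raw[col].dtype == object else raw[col])
        if role in ORDINAL_RANGES:
            lo, hi = ORDINAL_RANGES[role]
            bad = vals.notna() & ((vals < lo) | (vals > hi) | (vals != np.round(vals)))
        elif role == "age":
            bad = vals.notna() & (vals <= 0)
        else:
            bad = pd.Series(False, index=vals.index)
        warnings += int(bad.sum())
        df[role] = vals.mask(bad)

    for c in HS_ITEM_COLUMNS:
        if c in raw.columns:
            vals = _coerce_numeric(raw[c])
            bad = vals.notna() & ((vals < 1) | (vals > 5))
            warnings += int(bad.sum())
            df[c] = vals.mask(bad)
    if "home_supervision" not in df.columns:
        df["home_supervision"] = df[HS_ITEM_COLUMNS].mean(axis=1)

    if snp_columns is None:
        snp_columns = [c for c in raw.columns if c.startswith("rs")]
    for c in snp_columns:
        if c not in raw.columns:
            raise SchemaError(f"genotype column '{c}' not found")
        df[c] = raw[c].str.strip().where(raw[c].notna(), None)

    return CohortTable(df, list(snp_columns), warnings)


def zscore(table: CohortTable | StandardizedView, variables: Sequence[str]) -> StandardizedView:
    """Replace ``variables`` by Z scores (sample SD, denominator n-1).

    Missing cells stay missing; each standardized column has mean 0 and SD 1
    over its non-missing entries.  Raises :class:`DegenerateVariableError` for
    columns with < 2 non-missing values or zero variance.
    """
    df = table.data.copy()
    scale: dict[str, tuple[float, float]] = {}
    prior = list(getattr(table, "standardized", []))
    if isinstance(table, StandardizedView):
        scale.update(table.scale)
    for v in variables:
        x = df[v].astype(float)
        obs = x.dropna()
        if len(obs) < 2:
            raise DegenerateVariableError(f"'{v}' has fewer than 2 non-missing values")
        m, s = obs.mean(), obs.std(ddof=1)
        if s == 0:
            raise DegenerateVariableError(f"'{v}' has zero variance")
        df[v] = (x - m) / s
        scale[v] = (float(m), float(s))
    return StandardizedView(
        df,
        standardized=sorted(set(prior) | set(variables)),
        scale=scale,
        snp_columns=list(getattr(table, "snp_columns", [])),
    )


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha for an n x k item matrix (listwise complete rows).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total
    score), sample variances with denominator n-1.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateVariableError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class EmTrace:
    loglik: list[float]
    converged: bool
    n_iter: int
    ridge_applied: bool = False


def _em_loglik(Y: np.ndarray, obs: np.ndarray, mu: np.ndarray, S: np.ndarray) -> float:
    """Observed-data log-likelihood of a MVN over rows with arbitrary
    missingness patterns."""
    ll = 0.0
    for pattern in np.unique(obs, axis=0):
        idx = np.where((obs == pattern).all(axis=1))[0]
        o = np.where(pattern)[0]
        if o.size == 0:
            continue
        sub = Y[np.ix_(idx, o)]
        ll += stats.multivariate_normal.logpdf(
            sub, mean=mu[o], cov=S[np.ix_(o, o)], allow_singular=True
        ).sum()
    return float(ll)


def em_impute(
    table: CohortTable | StandardizedView,
    variables: Sequence[str],
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[CohortTable | StandardizedView, EmTrace]:
    """EM imputation under a multivariate-normal model for ``variables``.

    E-step computes per-row conditional means and second moments of the
    missing entries given the observed ones at the current (mu, Sigma);
    M-step re-estimates mu and Sigma (MLE, denominator n).  Convergence on
    relative change of the observed-data log-likelihood.  After convergence
    missing cells are replaced by their conditional means.

    Returns the completed table (same type as input) and an :class:`EmTrace`
    whose log-likelihood sequence is monotone non-decreasing.  A table with no
    missing cells is returned unchanged after a single iteration.
    """
    df = table.data.copy()
    Y = df[list(variables)].to_numpy(dtype=float)
    n, p = Y.shape
    obs = ~np.isnan(Y)
    if not obs.any(axis=0).all():
        raise ValueError("some variable is 100% missing")

    mu = np.nanmean(Y, axis=0)
    Yfill = np.where(obs, Y, mu)
    S = np.cov(Yfill, rowvar=False, ddof=0)
    S = np.atleast_2d(S)

    ridge_applied = False

    def regularize(S: np.ndarray) -> np.ndarray:
        nonlocal ridge_applied
        # near-singular covariance gets a small ridge to keep E-steps stable
        eig = np.linalg.eigvalsh(S)
        if eig.min() < 1e-10 * max(eig.max(), 1.0):
            ridge_applied = True
            S = S + np.eye(p) * 1e-8 * np.trace(S) / p
        return S

    S = regularize(S)

    if obs.all():
        trace = EmTrace([_em_loglik(Y, obs, mu, S)], converged=True, n_iter=1)
        out = dataclasses.replace(table, data=df) if not isinstance(table, CohortTable) \
            else CohortTable(df, list(table.snp_columns), table.warnings)
        return out, trace

    loglik: list[float] = []
    Yhat = Yfill
    for it in range(1, max_iter + 1):
        Yhat = Y.copy()
        C = np.zeros((p, p))  # accumulated conditional covariances
        for pattern in np.unique(obs, axis=0):
            idx = np.where((obs == pattern).all(axis=1))[0]
            o = np.where(pattern)[0]
            m = np.where(~pattern)[0]
            if m.size == 0:
                continue
            if o.size == 0:
                Yhat[np.ix_(idx, m)] = mu[m]
                C[np.ix_(m, m)] += len(idx) * S[np.ix_(m, m)]
                continue
            Soo = S[np.ix_(o, o)]
            Smo = S[np.ix_(m, o)]
            B = np.linalg.solve(Soo, Smo.T).T  # regression of missing on observed
            resid = Y[np.ix_(idx, o)] - mu[o]
            Yhat[np.ix_(idx, m)] = mu[m] + resid @ B.T
            Cmm = S[np.ix_(m, m)] - B @ Smo.T
            C[np.ix_(m, m)] += len(idx) * Cmm
        mu_new = Yhat.mean(axis=0)
        S_new = (Yhat - mu_new).T @ (Yhat - mu_new) / n + C / n
        S_new = regularize(S_new)
        mu, S = mu_new, S_new
        ll = _em_loglik(Y, obs, mu, S)
        loglik.append(ll)
        if it > 1 and abs(ll - loglik[-2]) <= tol * (abs(loglik[-2]) + 1e-12):
            trace = EmTrace(loglik, converged=True, n_iter=it, ridge_applied=ridge_applied)
            break
    else:
        trace = EmTrace(loglik, converged=False, n_iter=max_iter, ridge_applied=ridge_applied)
        raise EmConvergenceError(f"EM did not converge in {max_iter} iterations", trace)

    df[list(variables)] = Yhat
    if isinstance(table, CohortTable):
        out: CohortTable | StandardizedView = CohortTable(df, list(table.snp_columns), table.warnings)
    else:
        out = dataclasses.replace(table, data=df)
    return out, trace


def correlation_report(
    table: CohortTable | StandardizedView,
    variables: Sequence[str],
    mode: str = "pairwise",
) -> CorrelationReport:
    """Pearson correlation matrix with two-sided p from the t distribution.

    ``mode`` selects pairwise-complete (default) or listwise-complete data.
    A constant column yields NaN correlations (undefined) for its pairs.
    """
    if mode not in ("pairwise", "listwise"):
        raise ValueError("mode must be 'pairwise' or 'listwise'")
    df = table.data[list(variables)].astype(float)
    if mode == "listwise":
        df = df.dropna()
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    npair = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for i, v in enumerate(variables):
        npair.loc[v, v] = int(df[v].notna().sum())
        for j in range(i + 1, k):
            w = variables[j]
            sub = df[[v, w]].dropna()
            m = len(sub)
            npair.loc[v, w] = npair.loc[w, v] = m
            if m < 3 or sub[v].std(ddof=1) == 0 or sub[w].std(ddof=1) == 0:
                r.loc[v, w] = r.loc[w, v] = np.nan
                continue
            rij, pij = stats.pearsonr(sub[v], sub[w])
            r.loc[v, w] = r.loc[w, v] = rij
            p.loc[v, w] = p.loc[w, v] = pij
    return CorrelationReport(
        variables=list(variables),
        mean=df.mean(),
        sd=df.std(ddof=1),
        r=r,
        p=p,
        n_pairs=npair,
        mode=mode,
    )
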