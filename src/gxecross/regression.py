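"""Hierarchical moderated OLS regression (the exploratory stage).

Terms are named by column, with ``"a*b"`` denoting the product of two
columns formed row-wise after any standardization the caller has applied
(products are not re-standardized).  Fits report raw and standardized
coefficients (beta = b * SD(x) / SD(y)), the coefficient covariance
sigma^2 (X'X)^-1, R^2 and the overall F; hierarchical block entry reports
Delta R^2 and its F test per added block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, StandardizedView

__all__ = [
    "OlsFit", "HierarchicalResult", "SimpleSlope", "CollinearityError",
    "SpecificationError", "fit_ols", "hierarchical_blocks", "simple_slopes",
    "fit_from_correlations",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class SpecificationError(ValueError):
    """Blocks are not nested / required terms are absent."""


def _term_column(term: str, df: pd.DataFrame) -> pd.Series:
    if "*" in term:
        a, b = (t.strip() for t in term.split("*", 1))
        return df[a].astype(float) * df[b].astype(float)
    return df[term].astype(float)


def build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({t: _term_column(t, df) for t in terms})
    X.insert(0, "(Intercept)", 1.0)
    return X


@dataclass
class OlsFit:
    terms: list[str]          # including "(Intercept)" first
    coef: np.ndarray
    beta_std: np.ndarray      # standardized coefficients; NaN for intercept
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    cov: np.ndarray           # coefficient covariance, order of ``terms``
    r2: float
    sse: float
    sst: float
    f: float
    df1: int
    df2: int
    f_p: float
    n: int
    y_name: str = "y"

    def __getitem__(self, term: str) -> int:
        return self.terms.index(term)

    def coef_of(self, term: str) -> float:
        return float(self.coef[self[term]])

    def cov_of(self, t1: str, t2: str) -> float:
        return float(self.cov[self[t1], self[t2]])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "b": self.coef, "beta": self.beta_std,
            "se": self.se, "t": self.t, "p": self.p,
        })


@dataclass
class HierarchicalResult:
    blocks: list[list[str]]           # cumulative term lists
    fits: list[OlsFit]
    delta_r2: list[float]
    delta_f: list[float]
    delta_df: list[tuple[int, int]]
    delta_p: list[float]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, fit in enumerate(self.fits):
            rows.append({
                "block": i + 1, "r2": fit.r2, "f": fit.f,
                "df1": fit.df1, "df2": fit.df2, "f_p": fit.f_p,
                "delta_r2": self.delta_r2[i], "delta_f": self.delta_f[i],
                "delta_df1": self.delta_df[i][0], "delta_df2": self.delta_df[i][1],
                "delta_p": self.delta_p[i],
            })
        return pd.DataFrame(rows)


@dataclass
class SimpleSlope:
    level_label: str
    level: float
    slope: float
    se: float
    t: float
    p: float


def fit_ols(
    y: str,
    terms: list[str],
    table: CohortTable | StandardizedView | pd.DataFrame,
    listwise: bool = True,
) -> OlsFit:
    """Ordinary least squares of ``y`` on ``terms`` (plus intercept)."""
    df = table if isinstance(table, pd.DataFrame) else table.data
    cols = {y} | {c for t in terms for c in (t.split("*") if "*" in t else [t])}
    cols = [c.strip() for c in cols]
    work = df[list(cols)].astype(float)
    if listwise:
        work = work.dropna()
    X = build_design(work, terms).to_numpy()
    yv = work[y].to_numpy(dtype=float)
    n, k1 = X.shape
    if n <= k1:
        raise ValueError(f"n={n} too small for {k1} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < k1:
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {k1}); check terms {terms}")
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ yv)
    resid = yv - X @ coef
    sse = float(resid @ resid)
    sst = float(((yv - yv.mean()) ** 2).sum())
    df2 = n - k1
    sigma2 = sse / df2
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df2)
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    df1 = k1 - 1
    if df1 > 0:
        f = (r2 / df1) / ((1 - r2) / df2) if 1 - r2 > 0 else np.inf
        f_p = stats.f.sf(f, df1, df2)
    else:
        f = f_p = np.nan
    sy = work[y].std(ddof=1)
    design_df = build_design(work, terms)
    sx = design_df.std(ddof=1).to_numpy()
    beta = coef * sx / sy
    beta[0] = np.nan  # intercept has no standardized coefficient
    return OlsFit(
        terms=list(design_df.columns), coef=coef, beta_std=beta, se=se,
        t=tstat, p=pvals, cov=cov, r2=float(r2), sse=sse, sst=sst,
        f=float(f), df1=df1, df2=df2, f_p=float(f_p), n=n, y_name=y,
    )


def hierarchical_blocks(
    y: str,
    blocks: list[list[str]],
    table: CohortTable | StandardizedView | pd.DataFrame,
) -> HierarchicalResult:
    """Ordered block entry: each block's term list extends the previous one.

    Delta F for block k = (Delta R^2 / Delta k) / ((1 - R^2_k) / df2_k), the
    increment F test using block k's own residual variance.  Rows are made
    listwise complete over the union of all blocks' columns so every block is
    fit on identical data.
    """
    for i in range(1, len(blocks)):
        if blocks[i][:len(blocks[i - 1])] != blocks[i - 1]:
            raise SpecificationError(f"block {i + 1} does not extend block {i}")
    df = table if isinstance(table, pd.DataFrame) else table.data
    cols = {y} | {c for t in blocks[-1] for c in (t.split("*") if "*" in t else [t])}
    work = df[[c.strip() for c in cols]].astype(float).dropna()

    fits, d_r2, d_f, d_df, d_p = [], [], [], [], []
    prev_r2, prev_k = 0.0, 0
    for terms in blocks:
        fit = fit_ols(y, terms, work, listwise=False)
        dk = len(terms) - prev_k
        dr2 = fit.r2 - prev_r2
        if dk == 0:
            f, p = 0.0, 1.0
        else:
            f = (dr2 / dk) / ((1 - fit.r2) / fit.df2)
            p = float(stats.f.sf(f, dk, fit.df2))
        fits.append(fit)
        d_r2.append(float(dr2))
        d_f.append(float(f))
        d_df.append((dk, fit.df2))
        d_p.append(p)
        prev_r2, prev_k = fit.r2, len(terms)
    return HierarchicalResult(blocks=[list(b) for b in blocks], fits=fits,
                              delta_r2=d_r2, delta_f=d_f, delta_df=d_df, delta_p=d_p)


def simple_slopes(
    fit: OlsFit,
    focal: str,
    moderator: str,
    levels: dict[str, float] | list[float],
) -> list[SimpleSlope]:
    """Slope of ``focal`` on the outcome at fixed moderator levels.

    slope(z) = b_focal + b_product * z with Var = V_ff + 2 z V_fp + z^2 V_pp,
    tested on the fit's residual df.  The product term must be present as
    ``focal*moderator`` (either order).
    """
    product = None
    for cand in (f"{focal}*{moderator}", f"{moderator}*{focal}"):
        if cand in fit.terms:
            product = cand
    if focal not in fit.terms or product is None:
        raise SpecificationError(
            f"fit must contain '{focal}' and its product with '{moderator}'")
    if isinstance(levels, list):
        levels = {str(v): v for v in levels}
    out = []
    b_f = fit.coef_of(focal)
    b_p = fit.coef_of(product)
    v_ff = fit.cov_of(focal, focal)
    v_fp = fit.cov_of(focal, product)
    v_pp = fit.cov_of(product, product)
    for label, z in levels.items():
        slope = b_f + b_p * z
        var = v_ff + 2 * z * v_fp + z * z * v_pp
        se = float(np.sqrt(var))
        t = slope / se
        p = float(2 * stats.t.sf(abs(t), fit.df2))
        out.append(SimpleSlope(label, float(z), float(slope), se, float(t), p))
    return out


def fit_from_correlations(
    R: np.ndarray,
    r: np.ndarray,
    n: int,
) -> tuple[np.ndarray, float, float]:
    """Standardized regression from a correlation structure.

    beta = R^-1 r, R^2 = r' beta, overall F = (R^2/k) / ((1-R^2)/(n-k-1)).
    ``R`` must be positive definite.
    """
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    if R.shape[0] != R.shape[1] or R.shape[0] != r.shape[0]:
        raise ValueError("dimension mismatch between R and r")
    eig = np.linalg.eigvalsh(R)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError("predictor correlation matrix is not positive definite")
    beta = np.linalg.solve(R, r)
    r2 = float(r @ beta)
    k = len(r)
    f = (r2 / k) / ((1 - r2) / (n - k - 1)) if r2 < 1 else np.inf
    return beta, r2, float(f)
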