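"""Regions-of-Significance diagnostics for a fitted moderated regression.

Given an interaction fit Y ~ ... + X + Z + X*Z, the genotype-group outcome
difference at environment value X is theta(X) = b_Z + b_XZ * X.  This module
locates the Johnson-Neyman boundaries where |theta(X)| / SE(theta(X)) equals
the critical t, the crossover point Xc = -b_Z / b_XZ, the proportion-of-
interaction (PoI) and proportion-affected (PA) indices that separate
diathesis-stress from differential-susceptibility patterns, a quadratic
(X^2, Z*X^2) mis-specification probe, and the Holm step-down (sequential
Bonferroni) multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import OlsFit, SpecificationError, fit_ols

__all__ = [
    "RosResult", "PoiPa", "NonlinearityCheck", "HolmResult",
    "UndefinedCrossoverError", "jn_boundaries", "crossover_point",
    "poi_index", "pa_index", "nonlinearity_probe", "holm_correction",
]


class UndefinedCrossoverError(ValueError):
    """Interaction coefficient is (numerically) zero: the lines never cross."""


@dataclass
class RosResult:
    lower: float | None
    upper: float | None
    t_crit: float
    alpha: float
    eval_range_m2sd: tuple[float, float]
    eval_range_observed: tuple[float, float] | None
    classification: str  # "low only" | "high only" | "both" | "neither" | "no moderation"

    @property
    def boundaries(self) -> list[float]:
        return [b for b in (self.lower, self.upper) if b is not None]


@dataclass
class PoiPa:
    crossover: float
    good_area: float | None = None
    bad_area: float | None = None
    poi: float | None = None
    pa: float | None = None
    range_convention: str | None = None
    pa_mode: str | None = None
    orientation: int = 1  # +1: good side is high X; -1: good side is low X


@dataclass
class NonlinearityCheck:
    p_x2: float
    p_zx2: float
    p_xz_base: float
    p_xz_augmented: float

    @property
    def quadratic_significant(self) -> bool:
        return self.p_x2 < 0.05 or self.p_zx2 < 0.05

    @property
    def interaction_robust(self) -> bool:
        return self.p_xz_augmented < 0.05


@dataclass
class HolmResult:
    p_sorted: np.ndarray
    order: np.ndarray          # original indices, ascending p
    critical: np.ndarray       # alpha / (m - i + 1) per rank i
    reject_sorted: np.ndarray
    reject: np.ndarray         # in original order
    alpha: float


def _theta_terms(fit: OlsFit, moderator: str, product: str) -> tuple[float, float]:
    if moderator not in fit.terms or product not in fit.terms:
        raise SpecificationError(
            f"fit lacks '{moderator}' or '{product}' needed for the group difference")
    return fit.coef_of(moderator), fit.coef_of(product)


def jn_boundaries(
    fit: OlsFit,
    focal: str,
    moderator: str,
    alpha: float = 0.05,
    x_observed: np.ndarray | None = None,
) -> RosResult:
    """Johnson-Neyman significance boundaries on the environment axis.

    Solves (b_XZ^2 - t^2 V_pp) X^2 + 2 (b_Z b_XZ - t^2 V_zp) X
    + (b_Z^2 - t^2 V_zz) = 0 with t = t(1 - alpha/2, df2); 0, 1 or 2 real
    roots.  The default evaluation window, mean +/- 2 SD of X, is reported
    alongside the observed min/max when ``x_observed`` is given.
    """
    product = f"{focal}*{moderator}" if f"{focal}*{moderator}" in fit.terms \
        else f"{moderator}*{focal}"
    b_z, b_xz = _theta_terms(fit, moderator, product)
    v_zz = fit.cov_of(moderator, moderator)
    v_zp = fit.cov_of(moderator, product)
    v_pp = fit.cov_of(product, product)
    t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df2))
    t2 = t_crit ** 2

    a = b_xz ** 2 - t2 * v_pp
    b = 2 * (b_z * b_xz - t2 * v_zp)
    c = b_z ** 2 - t2 * v_zz

    if x_observed is not None:
        x_observed = np.asarray(x_observed, dtype=float)
        x_observed = x_observed[~np.isnan(x_observed)]
        obs_range = (float(x_observed.min()), float(x_observed.max()))
        m, s = x_observed.mean(), x_observed.std(ddof=1)
        m2sd = (float(m - 2 * s), float(m + 2 * s))
    else:
        obs_range = None
        m2sd = (-2.0, 2.0)

    if abs(b_xz) < 1e-12 and abs(b_z) < 1e-12:
        return RosResult(None, None, t_crit, alpha, m2sd, obs_range, "no moderation")

    roots: list[float]
    if abs(a) < 1e-300:
        roots = [] if abs(b) < 1e-300 else [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        elif disc == 0:
            roots = [-b / (2 * a)]
        else:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])

    lower = roots[0] if roots else None
    upper = roots[1] if len(roots) > 1 else None

    def significant(x: float) -> bool:
        theta = b_z + b_xz * x
        var = v_zz + 2 * x * v_zp + x * x * v_pp
        if var <= 0:
            return abs(theta) > 0
        return abs(theta) / np.sqrt(var) > t_crit

    lo, hi = m2sd
    if len(roots) == 2:
        sig_low = significant(min(lo, roots[0] - 1.0))
        sig_high = significant(max(hi, roots[1] + 1.0))
        if sig_low and sig_high:
            cls = "both"
        elif sig_low:
            cls = "low only"
        elif sig_high:
            cls = "high only"
        else:
            cls = "neither"
    elif len(roots) == 1:
        cls = "low only" if significant(roots[0] - 1.0) else "high only"
    else:
        cls = "both" if significant(0.0) else "neither"
    return RosResult(lower, upper, t_crit, alpha, m2sd, obs_range, cls)


def crossover_point(fit: OlsFit, focal: str, moderator: str, tol: float = 1e-10) -> float:
    """Environment value where the two genotype-group lines intersect:
    Xc = -b_Z / b_XZ."""
    product = f"{focal}*{moderator}" if f"{focal}*{moderator}" in fit.terms \
        else f"{moderator}*{focal}"
    b_z, b_xz = _theta_terms(fit, moderator, product)
    if abs(b_xz) < tol:
        raise UndefinedCrossoverError("interaction coefficient is ~0; no crossover")
    return float(-b_z / b_xz)


def poi_index(
    crossover: float,
    x_range: tuple[float, float],
    orientation: int = 1,
) -> PoiPa:
    """Proportion of Interaction.

    With two straight group lines crossing at Xc, the between-line area on
    each side of Xc is proportional to the squared distance from Xc to the
    range end, so for a positive interaction (good side = high X)
    PoI = (hi - Xc)^2 / ((hi - Xc)^2 + (Xc - lo)^2); the orientation flips
    for a negative interaction.  PoI near 0.5 supports differential
    susceptibility; near 0, diathesis-stress.  A crossover outside the range
    is clamped to the nearer end (PoI 0 or 1).
    """
    lo, hi = x_range
    if not lo < hi:
        raise ValueError(f"degenerate range {x_range}")
    xc = min(max(crossover, lo), hi)
    good = (hi - xc) ** 2
    bad = (xc - lo) ** 2
    if orientation < 0:
        good, bad = bad, good
    poi = good / (good + bad)
    return PoiPa(crossover=float(crossover), good_area=float(good), bad_area=float(bad),
                 poi=float(poi), range_convention=f"[{lo:g}, {hi:g}]",
                 orientation=1 if orientation >= 0 else -1)


def pa_index(
    crossover: float,
    x_values: np.ndarray | None = None,
    orientation: int = 1,
    mode: str = "empirical",
) -> PoiPa:
    """Proportion Affected: share of children on the good side of the
    crossover.

    ``mode="empirical"`` counts observed x values strictly beyond Xc (good
    side = above Xc for a positive interaction); ``mode="normal"`` returns the
    standard-normal tail beyond Xc, appropriate when X is a Z score and raw
    values are unavailable.  Conventionally PA >= 0.16 is required to call
    differential susceptibility.
    """
    if mode == "normal":
        tail = float(stats.norm.sf(crossover))
        pa = tail if orientation >= 0 else 1 - tail
    elif mode == "empirical":
        if x_values is None or len(np.asarray(x_values)) == 0:
            raise ValueError("empirical PA needs at least one x value")
        x = np.asarray(x_values, dtype=float)
        x = x[~np.isnan(x)]
        share = float((x > crossover).mean())
        pa = share if orientation >= 0 else 1 - share
    else:
        raise ValueError("mode must be 'empirical' or 'normal'")
    return PoiPa(crossover=float(crossover), pa=float(pa), pa_mode=mode,
                 orientation=1 if orientation >= 0 else -1)


def nonlinearity_probe(
    y: str,
    focal: str,
    moderator: str,
    table,
    covariates: list[str] | None = None,
) -> NonlinearityCheck:
    """Quadratic mis-specification probe of the interaction model.

    Refits the interaction model augmented with X^2 and Z*X^2 and reports
    their p-values plus the X*Z p-value before and after augmentation: a
    spurious 'interaction' induced by curvature in X shows up here.
    """
    covariates = covariates or []
    df = (table if hasattr(table, "columns") else table.data).copy()
    df["_x2"] = df[focal].astype(float) ** 2
    base_terms = covariates + [focal, moderator, f"{focal}*{moderator}"]
    aug_terms = base_terms + ["_x2", f"{moderator}*_x2"]
    base = fit_ols(y, base_terms, df)
    aug = fit_ols(y, aug_terms, df)
    return NonlinearityCheck(
        p_x2=float(aug.p[aug["_x2"]]),
        p_zx2=float(aug.p[aug[f"{moderator}*_x2"]]),
        p_xz_base=float(base.p[base[f"{focal}*{moderator}"]]),
        p_xz_augmented=float(aug.p[aug[f"{focal}*{moderator}"]]),
    )


def holm_correction(p_values, alpha: float = 0.05) -> HolmResult:
    """Holm step-down (sequential Bonferroni) correction.

    The i-th smallest p-value is compared with alpha / (m - i + 1); testing
    stops at the first non-rejection, so rejections form a prefix of the
    sorted list.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    crit = alpha / (m - np.arange(1, m + 1) + 1)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p_sorted[i] <= crit[i]:
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    return HolmResult(p_sorted=p_sorted, order=order, critical=crit,
                      reject_sorted=reject_sorted, reject=reject, alpha=alpha)
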