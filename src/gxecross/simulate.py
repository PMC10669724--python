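"""Synthetic cohorts with the study's statistical structure.

The generator emulates a primary-school reading cohort: n children with
gender, age, three ordinal SES covariates, a five-item home-supervision scale
with its composite, genotype calls for three DYX1C1 SNPs, and a standardized
reading outcome generated from the two-group crossover regression

    Y = B0 + B_g * (X - C) + B4*gender + B5*age + B6*Z_PE + B7*Z_PO
        + B8*Z_MI + e,      B_g = B1 (non-risk group) or B3 (risk group)

under a chosen true interaction model (strong/weak differential
susceptibility, diathesis-stress, vantage sensitivity, or no interaction).
X is the within-sample Z score of the home-supervision composite, so the
generating design matrix is exactly what the analysis pipeline reconstructs.
Every draw flows from a single seed; the truth record stores all generating
parameters so downstream estimates can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = ["SimulationDesign", "DesignError", "simulate_cohort", "inject_missing",
           "DEFAULT_GENOTYPE_FREQS"]


class DesignError(ValueError):
    """Invalid simulation design."""


#: genotype-call frequencies observed in the study cohort (counts / 745)
DEFAULT_GENOTYPE_FREQS: dict[str, dict[str, float]] = {
    "rs3743205": {"CT": 33 / 745, "TT": 712 / 745},
    "rs11629841": {"GT": 155 / 745, "TT": 590 / 745},
    "rs8040756": {"GG": 539 / 745, "AG": 189 / 745, "AA": 17 / 745},
}

#: latent (pre-discretization) correlation targets among
#: gender, age, parental education, parental occupation, monthly income and
#: home supervision — rounded values of the study's descriptive table.
_COVARIATE_CORR = np.array([
    #  G      A      PE     PO     MI     HS
    [1.00, -0.06,  0.05, -0.11,  0.03,  0.04],
    [-0.06, 1.00, -0.04, -0.17, -0.02, -0.01],
    [0.05, -0.04,  1.00, -0.04, -0.36,  0.11],
    [-0.11, -0.17, -0.04, 1.00, -0.06,  0.00],
    [0.03, -0.02, -0.36, -0.06,  1.00,  0.11],
    [0.04, -0.01,  0.11,  0.00,  0.11,  1.00],
])

#: marginal category probabilities for the ordinal SES codes
_ORDINAL_PROBS = {
    "parental_education": [0.05, 0.15, 0.30, 0.25, 0.15, 0.10],   # 1..6
    "parental_occupation": [0.06, 0.08, 0.10, 0.12, 0.14, 0.14, 0.12, 0.10, 0.08, 0.06],
    "monthly_income": [0.15, 0.25, 0.30, 0.20, 0.10],             # 1..5
}


@dataclass
class SimulationDesign:
    """Generating parameters for one synthetic cohort.

    Effect-size defaults are the weak diathesis-stress estimates of the study
    (B1 = 0.10, B3 = 0.21, covariate effects B4..B8, crossover at the sample
    maximum of standardized home supervision).  ``residual_sd`` defaults to
    0.91: the systematic part contributes ~0.23 outcome variance (age
    0.52^2*0.69^2 ~ .13, occupation .14^2, education .10^2, gender ~ .002,
    environment slopes E[(b_g (X-C))^2] plus the between-group mean shift
    ~ .05 with C at the sample maximum), so sigma^2 ~ 0.23*(1-R2)/R2 with
    R2 = 0.214 gives sigma ~ 0.91; measured full-model R^2 under these
    defaults is 0.216.
    """

    n: int = 745
    model: str = "d"  # a..f or "null"
    b0: float = 5.14
    b1: float = 0.10
    b3: float = 0.21
    b4: float = 0.08
    b5: float = -0.52
    b6: float = 0.10
    b7: float = 0.14
    b8: float = 0.01
    crossover: float | None = None  # None -> per-model convention
    residual_sd: float = 0.91
    genotype_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_GENOTYPE_FREQS)
    risk_snp: str = "rs11629841"
    risk_genotype: str = "GT"
    seed: int = 20231027

    def __post_init__(self):
        if self.n < 10:
            raise DesignError("n must be >= 10")
        if self.model not in {"a", "b", "c", "d", "e", "f", "null"}:
            raise DesignError(f"unknown model id '{self.model}'")
        if self.residual_sd < 0:
            raise DesignError("residual_sd must be non-negative")
        for snp, freqs in self.genotype_freqs.items():
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-9 or any(f < 0 for f in freqs.values()):
                raise DesignError(f"{snp}: genotype frequencies must be a distribution")


def _zs(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _discretize(u: np.ndarray, probs) -> np.ndarray:
    """Map standard-normal draws to ordinal codes 1..k with given marginals."""
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    return 1 + np.searchsorted(cuts, u, side="left").astype(int)


def simulate_cohort(design: SimulationDesign) -> tuple[CohortTable, dict]:
    """Draw one cohort; returns (table, truth record).

    Same design (incl. seed) -> identical table.  The truth record carries
    every generating parameter, the realized crossover point, the risk-group
    indicator column name and the seed.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n

    # --- covariates via a Gaussian copula ------------------------------------
    L = np.linalg.cholesky(_COVARIATE_CORR)
    latent = rng.standard_normal((n, 6)) @ L.T
    gender = np.where(latent[:, 0] > 0, 2, 1)
    age = 9.78 + 0.69 * latent[:, 1]
    pe = _discretize(latent[:, 2], _ORDINAL_PROBS["parental_education"])
    po = _discretize(latent[:, 3], _ORDINAL_PROBS["parental_occupation"])
    mi = _discretize(latent[:, 4], _ORDINAL_PROBS["monthly_income"])
    hs_latent = latent[:, 5]
    hs_raw = 3.4 + 0.6 * hs_latent  # composite on the 1..5 item scale

    # five items sharing the composite's latent score; inter-item latent
    # correlation 0.40 lands scale reliability near 0.75 after 5-category
    # discretization
    lam = np.sqrt(0.40)
    items = lam * hs_latent[:, None] + np.sqrt(1 - lam ** 2) * rng.standard_normal((n, 5))
    item_cuts = [-1.5, -0.5, 0.5, 1.5]
    hs_items = 1 + np.searchsorted(item_cuts, items, side="left").astype(int)

    # --- genotypes: independent multinomials at the design frequencies -------
    geno: dict[str, np.ndarray] = {}
    for snp, freqs in design.genotype_freqs.items():
        calls = np.array(list(freqs.keys()))
        geno[snp] = rng.choice(calls, size=n, p=np.array(list(freqs.values())))

    # --- outcome from the crossover model ------------------------------------
    x = _zs(hs_raw)
    risk = (geno[design.risk_snp] == design.risk_genotype).astype(int)
    if risk.sum() == 0 or risk.sum() == n:
        raise DesignError("risk group degenerate in this draw; adjust frequencies or n")

    if design.crossover is not None:
        C = float(design.crossover)
    elif design.model in ("c", "d"):
        C = float(x.max())
    elif design.model in ("e", "f"):
        C = float(x.min())
    else:
        C = 0.49 if design.model in ("a", "b") else 0.0

    b1 = design.b1
    b3 = design.b3
    if design.model in ("a", "c", "e"):
        b1 = 0.0
    if design.model == "null":
        b3 = b1

    slope = np.where(risk == 1, b3, b1)
    mean = (design.b0 + slope * (x - C)
            + design.b4 * gender + design.b5 * age
            + design.b6 * _zs(pe.astype(float))
            + design.b7 * _zs(po.astype(float))
            + design.b8 * _zs(mi.astype(float)))
    y = mean + design.residual_sd * rng.standard_normal(n)

    df = pd.DataFrame({
        "child_id": [f"S{i:04d}" for i in range(1, n + 1)],
        "gender": gender.astype(float),
        "age": age,
        "parental_education": pe.astype(float),
        "parental_occupation": po.astype(float),
        "monthly_income": mi.astype(float),
        **{f"hs{j + 1}": hs_items[:, j].astype(float) for j in range(5)},
        "home_supervision": hs_raw,
        "reading": y,
    })
    for snp in design.genotype_freqs:
        df[snp] = geno[snp]

    truth = {
        **{k: v for k, v in asdict(design).items() if k != "genotype_freqs"},
        "genotype_freqs": {s: dict(f) for s, f in design.genotype_freqs.items()},
        "b1_effective": b1,
        "b3_effective": b3,
        "crossover_realized": C,
        "x_min": float(x.min()),
        "x_max": float(x.max()),
        "n_risk": int(risk.sum()),
    }
    return CohortTable(df, list(design.genotype_freqs)), truth


def inject_missing(
    table: CohortTable,
    rates: Mapping[str, float],
    seed: int,
) -> CohortTable:
    """Apply MCAR missingness at the requested per-variable rates.

    Same seed -> identical mask.  Rates must lie in [0, 1).
    """
    for col, r in rates.items():
        if not 0 <= r < 1:
            raise DesignError(f"missing rate for '{col}' must be in [0, 1), got {r}")
        if col not in table.data.columns:
            raise KeyError(f"no column '{col}' in table")
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    for col, r in rates.items():
        if r == 0:
            continue
        mask = rng.random(len(df)) < r
        if df[col].dtype == object:
            df.loc[mask, col] = None
        else:
            df.loc[mask, col] = np.nan
    return CohortTable(df, list(table.snp_columns), table.warnings)
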