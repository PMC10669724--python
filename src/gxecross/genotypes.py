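"""Genotype coding and per-SNP quality control.

Calls arrive as two-letter strings ("GG", "AG", ...).  Each SNP has a numeric
coding scheme mapping calls to integer codes used downstream as moderator
variables; QC reports call rate, allele frequencies, minor-allele frequency
and a Hardy–Weinberg equilibrium test (1-df chi-square by default, exact test
optionally), each against configurable thresholds.  QC failures are reported,
never silently dropped: downstream analyses take an explicit SNP include-list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, StandardizedView

__all__ = [
    "GenotypeCodingScheme",
    "QcThresholds",
    "SnpQcReport",
    "GenotypeCodingError",
    "DEFAULT_SCHEMES",
    "code_genotypes",
    "snp_qc",
    "hwe_chisq",
    "hwe_exact",
]


class GenotypeCodingError(ValueError):
    """Strict-mode coding hit a call not covered by the scheme."""


@dataclass(frozen=True)
class GenotypeCodingScheme:
    """Injective genotype-string -> integer-code map for one SNP."""

    snp_name: str
    mapping: dict[str, int]

    def __post_init__(self):
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError(f"{self.snp_name}: coding map must be injective")
        if any(int(c) != c for c in codes):
            raise ValueError(f"{self.snp_name}: codes must be integers")

    @property
    def valid_calls(self) -> list[str]:
        return list(self.mapping)


#: Dominant/additive codings for the three DYX1C1 SNPs: heterozygote-only
#: two-level factors for rs3743205 (CT=0, TT=1) and rs11629841 (GT=0, TT=1),
#: additive -1/0/1 for rs8040756 (GG/AG/AA).
DEFAULT_SCHEMES: dict[str, GenotypeCodingScheme] = {
    "rs3743205": GenotypeCodingScheme("rs3743205", {"CT": 0, "TT": 1}),
    "rs8040756": GenotypeCodingScheme("rs8040756", {"GG": -1, "AG": 0, "AA": 1}),
    "rs11629841": GenotypeCodingScheme("rs11629841", {"GT": 0, "TT": 1}),
}


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    min_hwe_p: float = 0.01

    def __post_init__(self):
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class SnpQcReport:
    snp_name: str
    n: int
    genotype_counts: dict[str, int]
    genotype_percent: dict[str, float]
    call_rate: float
    allele_freqs: dict[str, float]
    maf: float
    hwe_chi2: float  # NaN when undefined (monomorphic)
    hwe_p: float
    hwe_exact_p: float
    passed: dict[str, bool] = field(default_factory=dict)

    @property
    def passed_all(self) -> bool:
        return all(self.passed.values())

    def to_row(self) -> dict:
        row = {
            "snp": self.snp_name,
            "n": self.n,
            "call_rate": self.call_rate,
            "maf": self.maf,
            "hwe_chi2": self.hwe_chi2,
            "hwe_p": self.hwe_p,
            "hwe_exact_p": self.hwe_exact_p,
            **{f"pass_{k}": v for k, v in self.passed.items()},
        }
        for g, c in self.genotype_counts.items():
            row[f"count_{g}"] = c
            row[f"pct_{g}"] = self.genotype_percent[g]
        return row


def code_genotypes(
    table: CohortTable | StandardizedView,
    schemes: dict[str, GenotypeCodingScheme] | GenotypeCodingScheme | None = None,
    strict: bool = False,
    suffix: str = "_code",
) -> tuple[CohortTable | StandardizedView, int]:
    """Add a numeric column per SNP (name + ``suffix``) from its coding scheme.

    Unknown calls become missing with a warning count (lenient, default) or
    raise :class:`GenotypeCodingError` (strict).  Returns (table, n_warnings).
    """
    if schemes is None:
        schemes = {s: DEFAULT_SCHEMES[s] for s in table.snp_columns if s in DEFAULT_SCHEMES}
    if isinstance(schemes, GenotypeCodingScheme):
        schemes = {schemes.snp_name: schemes}
    df = table.data.copy()
    warnings = 0
    for snp, scheme in schemes.items():
        if snp not in df.columns:
            raise KeyError(f"SNP column '{snp}' not in table")
        calls = df[snp]
        coded = calls.map(scheme.mapping)
        unknown = calls.notna() & coded.isna()
        if unknown.any():
            if strict:
                bad = sorted(set(calls[unknown]))
                raise GenotypeCodingError(f"{snp}: unmapped call(s) {bad}")
            warnings += int(unknown.sum())
        df[snp + suffix] = coded.astype(float)
    out = table.copy() if isinstance(table, CohortTable) else table
    if isinstance(table, CohortTable):
        out = CohortTable(df, list(table.snp_columns), table.warnings)
    else:
        out = StandardizedView(df, list(table.standardized), dict(table.scale),
                               list(table.snp_columns))
    return out, warnings


def _allele_counts(genotype_counts: dict[str, int]) -> Counter:
    alleles: Counter = Counter()
    for call, c in genotype_counts.items():
        if len(call) != 2:
            raise ValueError(f"expected biallelic two-letter call, got '{call}'")
        alleles[call[0]] += c
        alleles[call[1]] += c
    return alleles


def hwe_chisq(genotype_counts: dict[str, int]) -> tuple[float, float]:
    """1-df Hardy–Weinberg chi-square (no continuity correction).

    Observed counts of the three genotype classes (hom-major, het, hom-minor;
    absent classes count 0) are compared with n*p^2, 2n*p*q, n*q^2 at the
    observed allele frequencies.  Monomorphic input returns (nan, nan).
    """
    alleles = _allele_counts(genotype_counts)
    if len(alleles) == 1:
        return float("nan"), float("nan")
    if len(alleles) > 2:
        raise ValueError("HWE test requires a biallelic SNP")
    (a1, c1), (a2, c2) = sorted(alleles.items(), key=lambda kv: -kv[1])
    n = sum(genotype_counts.values())
    p = c1 / (c1 + c2)
    q = 1 - p
    obs = np.array([
        genotype_counts.get(a1 + a1, 0),
        genotype_counts.get(a1 + a2, 0) + genotype_counts.get(a2 + a1, 0),
        genotype_counts.get(a2 + a2, 0),
    ], dtype=float)
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact(genotype_counts: dict[str, int]) -> float:
    """Exact Hardy–Weinberg test (sum of heterozygote-count probabilities no
    larger than the observed one, conditional on allele counts).

    Preferred over the chi-square when a genotype class is rare.
    """
    alleles = _allele_counts(genotype_counts)
    if len(alleles) == 1:
        return float("nan")
    if len(alleles) > 2:
        raise ValueError("HWE test requires a biallelic SNP")
    (a1, c1), (a2, c2) = sorted(alleles.items(), key=lambda kv: -kv[1])
    n_het_obs = sum(c for call, c in genotype_counts.items()
                    if len(set(call)) == 2)
    n = sum(genotype_counts.values())
    n_rare = min(c1, c2)
    # log-probability of each feasible heterozygote count given allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    def logp(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        return (h * np.log(2) + gammaln(n + 1)
                - gammaln(h + 1) - gammaln(hom_r + 1) - gammaln(hom_c + 1)
                + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1))

    lp = np.array([logp(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    p_obs = pr[hets == n_het_obs][0]
    return float(pr[pr <= p_obs + 1e-12].sum())


def snp_qc(
    table: CohortTable | StandardizedView,
    snp: str,
    thresholds: QcThresholds = QcThresholds(),
    hwe_method: str = "chisq",
) -> SnpQcReport:
    """QC metrics and pass/fail flags for one SNP column of string calls."""
    calls = table.data[snp]
    observed = calls.dropna()
    n = len(calls)
    if observed.empty:
        raise ValueError(f"{snp}: no non-missing calls")
    counts = dict(Counter(observed))
    total = sum(counts.values())
    percent = {g: 100.0 * c / total for g, c in counts.items()}
    call_rate = total / n
    alleles = _allele_counts(counts)
    total_alleles = sum(alleles.values())
    freqs = {a: c / total_alleles for a, c in alleles.items()}
    maf = 0.0 if len(freqs) == 1 else min(freqs.values())
    chi2, p_chi = hwe_chisq(counts) if len(alleles) > 1 else (float("nan"), float("nan"))
    p_exact = hwe_exact(counts) if len(alleles) > 1 else float("nan")
    hwe_p = p_exact if hwe_method == "exact" else p_chi
    passed = {
        "call_rate": call_rate >= thresholds.min_call_rate,
        "maf": maf > thresholds.min_maf,
        # undefined HWE (monomorphic) is reported as a failure of the criterion
        "hwe": bool(np.isfinite(hwe_p) and hwe_p > thresholds.min_hwe_p),
    }
    return SnpQcReport(
        snp_name=snp, n=n, genotype_counts=counts, genotype_percent=percent,
        call_rate=call_rate, allele_freqs=freqs, maf=maf,
        hwe_chi2=chi2, hwe_p=p_chi, hwe_exact_p=p_exact, passed=passed,
    )


def qc_table(reports: list[SnpQcReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
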