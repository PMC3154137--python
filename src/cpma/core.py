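"""Cross-phenotype meta-analysis (CPMA) statistics.

The CPMA statistic asks whether the association p-values of a single SNP
across several phenotypes are uniformly distributed, as they would be if the
SNP carried no signal beyond what is already known.  Under that null the
transformed values ``x_i = -ln(p_i)`` are exponential with rate ``lambda = 1``;
an excess of small p-values (multiple associations) drags the maximum
likelihood rate ``lambda_hat = n / sum(x_i)`` below 1.  The departure is
scored as a likelihood-ratio test with one degree of freedom, which keeps the
test powerful without enumerating phenotype subsets.

This module also provides the numerically stable chi-square log-tail used to
report extreme CPMA p-values, Fisher's omnibus combination, an exact
binomial upper tail, and the per-SNP classification rules (opposing-direction
effects, association to every phenotype in the panel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr, logsumexp

__all__ = [
    "AssociationCell",
    "SnpRecord",
    "AssociationMatrix",
    "CpmaResult",
    "FisherResult",
    "ScreenResult",
    "cpma",
    "cpma_arrays",
    "log_chi2_sf",
    "fisher_omnibus",
    "binomial_tail",
    "classify_directional",
    "is_associated_all",
    "multi_phenotype_screen",
]

_LN10 = math.log(10.0)

# p-values are clamped to this interval before -ln transform: p = 1.0 occurs
# in real summary tables (-ln p = 0 is fine cell-wise, but an all-ones vector
# would send lambda_hat to infinity), and p below 1e-300 would overflow -ln.
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AssociationCell:
    """One SNP-phenotype association: signed Z and two-sided p.

    Both fields are present or both are missing (``None``).  The sign
    convention of ``z`` is arbitrary but must be consistent for a SNP across
    phenotypes (e.g. always relative to the same reference allele).
    """

    z: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.z is None) != (self.p is None):
            raise ValueError("z and p must be both present or both missing")
        if self.p is not None:
            if not (0.0 < self.p <= 1.0):
                raise ValueError(f"p must be in (0, 1], got {self.p}")
            if not math.isfinite(self.z):
                raise ValueError("z must be finite when present")

    @property
    def missing(self) -> bool:
        return self.p is None


@dataclass
class SnpRecord:
    """Per-SNP summary across a phenotype panel."""

    snp_id: str
    cells: dict[str, AssociationCell]
    chrom: str = ""
    pos: int = 0
    major_allele: str = ""
    minor_allele: str = ""
    gene_label: str = ""
    discovery_phenotype: Optional[str] = None

    def pvalues(self, exclude: Iterable[str] = ()) -> dict[str, float]:
        """Non-missing p-values keyed by phenotype, minus any excluded."""
        excl = set(exclude)
        return {
            ph: c.p
            for ph, c in self.cells.items()
            if not c.missing and ph not in excl
        }

    def n_observed(self) -> int:
        return sum(not c.missing for c in self.cells.values())


@dataclass
class AssociationMatrix:
    """SNP x phenotype table of signed Z and two-sided p, missing cells allowed."""

    phenotypes: list[str]
    records: list[SnpRecord]

    def __post_init__(self) -> None:
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValueError("phenotype names must be unique")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id must be unique within a matrix")
        panel = set(self.phenotypes)
        for r in self.records:
            if set(r.cells) != panel:
                raise ValueError(
                    f"record {r.snp_id} does not share the phenotype panel"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def record(self, snp_id: str) -> SnpRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def p_frame(self) -> pd.DataFrame:
        """p-values as a SNP x phenotype DataFrame (NaN for missing)."""
        return pd.DataFrame(
            [
                [r.cells[ph].p if not r.cells[ph].missing else np.nan
                 for ph in self.phenotypes]
                for r in self.records
            ],
            index=self.snp_ids,
            columns=self.phenotypes,
            dtype=float,
        )

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [r.cells[ph].z if not r.cells[ph].missing else np.nan
                 for ph in self.phenotypes]
                for r in self.records
            ],
            index=self.snp_ids,
            columns=self.phenotypes,
            dtype=float,
        )


@dataclass(frozen=True)
class CpmaResult:
    """Outcome of the CPMA likelihood-ratio test for one SNP."""

    n_used: int
    sum_neglog: float
    lambda_hat: float
    lrt: float
    p_value: float
    log10_p: float


class FisherResult:
    """Fisher omnibus combination: behaves as (statistic, df, combined_p)."""

    __slots__ = ("statistic", "df", "combined_p", "log10_p")

    def __init__(self, statistic: float, df: int, combined_p: float,
                 log10_p: float) -> None:
        self.statistic = statistic
        self.df = df
        self.combined_p = combined_p
        self.log10_p = log10_p

    def __iter__(self):
        return iter((self.statistic, self.df, self.combined_p))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"FisherResult(statistic={self.statistic:.6g}, df={self.df}, "
                f"combined_p={self.combined_p:.6g})")


@dataclass
class ScreenResult:
    """Panel-wide CPMA screen: per-SNP results plus the enrichment tail."""

    table: pd.DataFrame
    n_snps: int
    n_significant: int
    cpma_alpha: float
    enrichment_p: float
    errors: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# chi-square log tail


def log_chi2_sf(x: float, df: int = 1) -> float:
    """log10 of the chi-square upper-tail probability P(X >= x).

    Stays finite far beyond double-precision underflow (CPMA p-values in
    practice reach below 1e-160).  df = 1 routes through the normal log-CDF
    (sf = 2 * Phi(-sqrt(x))); even df uses the closed-form Poisson survival
    sum in log space; odd df >= 3 is built from df = 1 by the standard
    recurrence Q(x; v + 2) = Q(x; v) + (x/2)^(v/2) e^(-x/2) / Gamma(v/2 + 1).
    """
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    df = int(df)
    x = float(x)
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    if x == 0.0:
        return 0.0
    if df % 2 == 0:
        # ln sf = -x/2 + ln sum_{k<df/2} (x/2)^k / k!
        k = np.arange(df // 2)
        terms = k * math.log(x / 2.0) - gammaln(k + 1.0)
        return (-x / 2.0 + logsumexp(terms)) / _LN10
    log_sf = math.log(2.0) + log_ndtr(-math.sqrt(x))  # df = 1
    for nu in range(1, df - 1, 2):
        extra = (nu / 2.0) * math.log(x / 2.0) - x / 2.0 - gammaln(nu / 2.0 + 1.0)
        log_sf = np.logaddexp(log_sf, extra)
    return float(log_sf) / _LN10


# ---------------------------------------------------------------------------
# the CPMA statistic


def _validate_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(pvalues), dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        bad = p[~(np.isfinite(p) & (p > 0.0) & (p <= 1.0))]
        raise ValueError(f"p-values must lie in (0, 1]; offending: {bad}")
    return p


def cpma_arrays(p: np.ndarray, axis: int = -1):
    """Vectorized CPMA over an array of valid p-values.

    Returns ``(lambda_hat, lrt, log10_p)`` arrays reduced along ``axis``.
    Inputs are clamped to [1e-300, 1 - 1e-16]; validation is the caller's
    responsibility (see :func:`cpma` for the checked scalar entry point).
    """
    p = np.clip(np.asarray(p, dtype=float), P_FLOOR, P_CEIL)
    x = -np.log(p)
    n = p.shape[axis]
    s = x.sum(axis=axis)
    lam = n / s
    lrt = 2.0 * (n * np.log(lam) - n + s)
    lrt = np.maximum(lrt, 0.0)  # guard roundoff at the null
    log10_p = (math.log(2.0) + log_ndtr(-np.sqrt(lrt))) / _LN10
    return lam, lrt, log10_p


def cpma(pvalues: Sequence[float]) -> CpmaResult:
    """CPMA likelihood-ratio test on one SNP's cross-phenotype p-values.

    With ``x_i = -ln(p_i)``, the exponential-rate MLE is
    ``lambda_hat = n / sum(x_i)`` and the statistic is
    ``LRT = 2 (n ln(lambda_hat) - n + sum(x_i))``, referred to a chi-square
    distribution with 1 degree of freedom.  The result does not depend on
    the order of the inputs.  The test is two-sided: both an excess
    (lambda_hat < 1) and a deficit (lambda_hat > 1) of small p-values move
    the statistic off zero.
    """
    p = _validate_pvalues(pvalues)
    if p.size < 2:
        raise ValueError(f"cpma requires at least 2 p-values, got {p.size}")
    p = np.sort(p)  # canonical summation order: bit-identical under reordering
    lam, lrt, log10_p = cpma_arrays(p)
    pc = np.clip(p, P_FLOOR, P_CEIL)
    return CpmaResult(
        n_used=int(p.size),
        sum_neglog=float(-np.log(pc).sum()),
        lambda_hat=float(lam),
        lrt=float(lrt),
        p_value=float(10.0 ** log10_p),
        log10_p=float(log10_p),
    )


# ---------------------------------------------------------------------------
# combinators


def fisher_omnibus(pvalues: Sequence[float]) -> FisherResult:
    """Fisher's omnibus combination of N p-values.

    ``S = -2 sum(ln p_i)`` follows chi-square with 2N degrees of freedom
    under the null of uniform, independent p-values.
    """
    p = _validate_pvalues(pvalues)
    if p.size < 1:
        raise ValueError("fisher_omnibus requires at least 1 p-value")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * int(p.size)
    log10_p = log_chi2_sf(stat, df)
    return FisherResult(stat, df, float(10.0 ** log10_p), log10_p)


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0), summed in log space."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    j = np.arange(k, n + 1)
    log_pmf = (
        gammaln(n + 1.0) - gammaln(j + 1.0) - gammaln(n - j + 1.0)
        + j * math.log(p0) + (n - j) * math.log1p(-p0)
    )
    return float(np.exp(logsumexp(log_pmf)))


# ---------------------------------------------------------------------------
# per-SNP classification rules


def classify_directional(record: SnpRecord, threshold: float = 1e-4) -> bool:
    """True if the SNP has strong effects of both signs across phenotypes.

    "Strong" means p strictly below ``threshold``; the SNP must show at
    least one such risk effect (z > 0) and one protective effect (z < 0).
    Missing cells are ignored.
    """
    pos = neg = False
    for cell in record.cells.values():
        if cell.missing or cell.p >= threshold:
            continue
        if cell.z > 0:
            pos = True
        elif cell.z < 0:
            neg = True
    return pos and neg


def is_associated_all(record: SnpRecord, alpha: float = 0.05) -> bool:
    """True if every phenotype in the panel shows nominal association.

    Requires a non-missing cell with p strictly below ``alpha`` for every
    phenotype; any missing cell fails the test.
    """
    return all(
        (not c.missing) and c.p < alpha for c in record.cells.values()
    )


# ---------------------------------------------------------------------------
# panel-wide screen


def multi_phenotype_screen(
    matrix: AssociationMatrix,
    cpma_alpha: float = 0.01,
    exclusion: str = "none",
) -> ScreenResult:
    """Run CPMA over every SNP of a panel and score the overall enrichment.

    ``exclusion="discovery"`` drops each SNP's discovery phenotype (the
    disease in which its association was originally reported) from its own
    CPMA computation, so the test asks for associations *beyond* the known
    one.  SNPs left with fewer than 2 usable cells are reported as per-record
    errors, not raised.  The count of SNPs with ``p_CPMA < cpma_alpha`` is
    referred to an exact binomial upper tail with success probability
    ``cpma_alpha``.
    """
    if exclusion not in ("none", "discovery"):
        raise ValueError(f"unknown exclusion policy: {exclusion!r}")
    rows = []
    errors: dict[str, str] = {}
    for rec in matrix.records:
        exclude: tuple[str, ...] = ()
        if (
            exclusion == "discovery"
            and rec.discovery_phenotype is not None
            and rec.discovery_phenotype in matrix.phenotypes
        ):
            exclude = (rec.discovery_phenotype,)
        ps = list(rec.pvalues(exclude=exclude).values())
        if len(ps) < 2:
            errors[rec.snp_id] = (
                f"only {len(ps)} usable p-value(s) after exclusion"
            )
            continue
        r = cpma(ps)
        rows.append(
            {
                "snp_id": rec.snp_id,
                "n_used": r.n_used,
                "lambda_hat": r.lambda_hat,
                "lrt": r.lrt,
                "p_value": r.p_value,
                "log10_p": r.log10_p,
                "significant": r.p_value < cpma_alpha,
                "directional": classify_directional(rec),
                "all_phenotypes": is_associated_all(rec),
            }
        )
    cols = [
        "snp_id", "n_used", "lambda_hat", "lrt", "p_value", "log10_p",
        "significant", "directional", "all_phenotypes",
    ]
    table = pd.DataFrame(rows, columns=cols)
    n_snps = len(table)
    n_sig = int(table["significant"].sum()) if n_snps else 0
    enrichment = (
        binomial_tail(n_sig, n_snps, cpma_alpha) if n_snps else float("nan")
    )
    return ScreenResult(
        table=table,
        n_snps=n_snps,
        n_significant=n_sig,
        cpma_alpha=cpma_alpha,
        enrichment_p=enrichment,
        errors=errors,
    )
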