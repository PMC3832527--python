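"""Allele-frequency estimation with exact binomial confidence intervals.

Genotype counts at a biallelic autosomal locus (e.g. a transposable
element insertion segregating in a fly population) are collapsed to
allele counts — each diploid individual contributes two alleles — and
the insertion frequency is reported with an exact Clopper-Pearson
interval computed from beta-distribution quantiles. Exact intervals are
conservative: their coverage is at least the nominal level for every
true frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta

from .synthetic_data import GenotypeSample

__all__ = [
    "AlleleFrequencyEstimate",
    "allele_counts_from_genotypes",
    "clopper_pearson_ci",
    "estimate_insertion_frequency",
]


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    """Point estimate k/n with a two-sided confidence interval."""

    k: int
    n: int
    estimate: float
    lower: float
    upper: float
    level: float
    method: str = "clopper-pearson"

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "estimate": self.estimate,
            "ci_lower": self.lower,
            "ci_upper": self.upper,
            "level": self.level,
            "method": self.method,
        }


def allele_counts_from_genotypes(g: GenotypeSample) -> tuple[int, int]:
    """Collapse diploid genotype counts to (insertion alleles, total alleles).

    k = 2 * homozygous-insertion + heterozygous; n = 2 * individuals.
    """
    if g.n_individuals == 0:
        raise ValueError("no individuals genotyped")
    k = 2 * g.n_hom_insertion + g.n_het
    n = 2 * g.n_individuals
    return k, n


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> AlleleFrequencyEstimate:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n.

    lower = Beta(alpha/2; k, n-k+1) quantile (0 when k = 0);
    upper = Beta(1-alpha/2; k+1, n-k) quantile (1 when k = n).
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must lie in (0,1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return AlleleFrequencyEstimate(
        k=k, n=n, estimate=k / n, lower=lower, upper=upper, level=level
    )


def estimate_insertion_frequency(
    g: GenotypeSample, level: float = 0.95
) -> AlleleFrequencyEstimate:
    """Insertion allele frequency with an exact CI from genotype counts."""
    k, n = allele_counts_from_genotypes(g)
    return clopper_pearson_ci(k, n, level)
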