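"""Synthetic inputs with known truth for the whole pipeline.

Emulates the statistical structure the analysis assumes: overdispersed
(quasi-Poisson) tag counts for a two-population, two-replicate design
with a smooth mean-dispersion trend; gene positions on chromosome arms,
optionally clustered; gene -> GO assignments with an optional spiked
enriched term; and diploid genotypes under Hardy-Weinberg equilibrium.

Counts are drawn with Var = phi * mean: negative binomial when phi > 1
(size r = mu / (phi - 1)), Poisson when phi = 1. Dispersion follows the
trend phi(lambda) = 1 + lambda / k with optional multiplicative
log-normal noise, floored at the Poisson bound phi = 1.

All generators take an explicit seed and are bit-reproducible; there is
no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneLocus

__all__ = [
    "SimulationParams",
    "GenotypeSample",
    "simulate_counts",
    "simulate_gene_map",
    "simulate_go_annotations",
    "simulate_genotypes",
    "dispersion_trend",
]

_PHI_POISSON_TOL = 1e-9


@dataclass
class SimulationParams:
    """Generative parameters for the two-condition count simulator.

    Defaults mirror the study design: two conditions ("G", "M") with two
    replicates each, gene means log-normal around 100 tags, dispersion
    following phi = 1 + lambda/100, and a small minority of genes truly
    differentially expressed at |log2 fold change| = 2.
    """

    n_genes: int
    seed: int
    n_replicates_per_condition: int = 2
    condition_labels: tuple[str, str] = ("G", "M")
    mean_log_location: float = math.log(100.0)
    mean_log_scale: float = 1.0
    dispersion_trend_k: float = 100.0
    dispersion_noise_sd: float = 0.0
    de_fraction: float = 0.05
    log2_fold_change: float | None = 2.0
    log2_fold_change_sd: float | None = None
    size_factors: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError(f"de_fraction must lie in [0,1], got {self.de_fraction}")
        if self.dispersion_trend_k <= 0 and not math.isinf(self.dispersion_trend_k):
            raise ValueError("dispersion_trend_k must be positive (inf for Poisson)")
        if self.dispersion_noise_sd < 0:
            raise ValueError("dispersion_noise_sd must be non-negative")
        if self.log2_fold_change is None and self.log2_fold_change_sd is None:
            raise ValueError("specify log2_fold_change or log2_fold_change_sd")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if sf.shape != (self.n_samples,):
                raise ValueError(
                    f"need {self.n_samples} size factors, got shape {sf.shape}"
                )
            if (sf <= 0).any():
                raise ValueError("size factors must be positive")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_replicates_per_condition

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{cond}{r + 1}"
            for cond in self.condition_labels
            for r in range(self.n_replicates_per_condition)
        ]


def dispersion_trend(lam: np.ndarray, k: float) -> np.ndarray:
    """Trend dispersion phi(lambda) = 1 + lambda/k (k = inf gives Poisson)."""
    lam = np.asarray(lam, dtype=float)
    if math.isinf(k):
        return np.ones_like(lam)
    return 1.0 + lam / k


def _draw_overdispersed(
    rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Counts with mean mu and variance phi*mu (NB when phi>1, else Poisson)."""
    out = np.zeros(mu.shape, dtype=np.int64)
    poisson_like = phi <= 1.0 + _PHI_POISSON_TOL
    pos = mu > 0
    pp = poisson_like & pos
    if pp.any():
        out[pp] = rng.poisson(mu[pp])
    nb = (~poisson_like) & pos
    if nb.any():
        r = mu[nb] / (phi[nb] - 1.0)
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-condition count matrix plus the generating truth.

    Returns
    -------
    matrix
        ExpressionMatrix with samples named ``<condition><replicate>``
        and the requested size factors attached.
    truth
        Per-gene DataFrame (index gene_id) with columns ``is_de``,
        ``log2_fold_change``, ``lambda_<cond1>``, ``lambda_<cond2>``
        and ``phi`` — the ground truth for every gene.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    c1, c2 = params.condition_labels

    lam_base = rng.lognormal(params.mean_log_location, params.mean_log_scale, size=n)
    phi = dispersion_trend(lam_base, params.dispersion_trend_k)
    if params.dispersion_noise_sd > 0:
        phi = phi * rng.lognormal(0.0, params.dispersion_noise_sd, size=n)
    phi = np.maximum(phi, 1.0)  # never generate underdispersion

    n_de = int(round(params.de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    de_idx = rng.choice(n, size=n_de, replace=False)
    is_de[de_idx] = True

    lfc = np.zeros(n)
    if params.log2_fold_change_sd is not None:
        lfc[is_de] = rng.normal(0.0, params.log2_fold_change_sd, size=n_de)
    else:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[is_de] = signs * abs(params.log2_fold_change)

    lam1 = lam_base.copy()
    lam2 = lam_base * np.exp2(lfc)  # condition-2 mean carries the fold change

    reps = params.n_replicates_per_condition
    if params.size_factors is None:
        sf = np.ones(params.n_samples)
    else:
        sf = np.asarray(params.size_factors, dtype=float)

    cols = {}
    for j, name in enumerate(params.sample_names):
        lam = lam1 if j < reps else lam2
        cols[name] = _draw_overdispersed(rng, sf[j] * lam, phi)
    counts = pd.DataFrame(cols, index=[f"gene{i:05d}" for i in range(n)])
    counts.index.name = "gene_id"

    design = {
        name: (c1 if j < reps else c2) for j, name in enumerate(params.sample_names)
    }
    matrix = ExpressionMatrix(
        counts=counts,
        design=design,
        size_factors=pd.Series(sf, index=params.sample_names),
    )
    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "log2_fold_change": lfc,
            f"lambda_{c1}": lam1,
            f"lambda_{c2}": lam2,
            "phi": phi,
        },
        index=counts.index,
    )
    return matrix, truth


def simulate_gene_map(
    n_genes: int,
    arm_lengths: Mapping[str, int],
    clustered_ids: Iterable[str] | None = None,
    cluster_span: int = 100_000,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    gene_length: int = 100,
) -> list[GeneLocus]:
    """Place genes on chromosome arms, optionally clustering a subset.

    Non-clustered genes land uniformly over the arms with probability
    proportional to arm length. Genes named in ``clustered_ids`` are
    placed inside a single random window of width ``cluster_span`` on
    one arm, so their midpoints span at most ``cluster_span`` bp.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    arms = list(arm_lengths)
    lengths = np.array([arm_lengths[a] for a in arms], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("arm lengths must be positive")
    if lengths.min() <= gene_length:
        raise ValueError("arms must be longer than the gene length")
    clustered = set(clustered_ids) if clustered_ids is not None else set()
    if clustered and cluster_span >= lengths.min():
        raise ValueError("cluster_span must be smaller than the shortest arm")
    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    unknown = clustered - set(gene_ids)
    if unknown:
        raise ValueError(f"clustered ids not among gene ids: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    half = gene_length / 2.0

    window_arm = window_lo = None
    if clustered:
        eligible = [i for i, L in enumerate(lengths) if L > cluster_span + gene_length]
        ai = int(rng.choice(eligible))
        window_arm = arms[ai]
        lo_min, lo_max = half, lengths[ai] - half - cluster_span
        window_lo = float(rng.uniform(lo_min, lo_max))

    probs = lengths / lengths.sum()
    loci: list[GeneLocus] = []
    for gid in gene_ids:
        if gid in clustered:
            arm = window_arm
            mid = window_lo + float(rng.uniform(0.0, cluster_span))
        else:
            ai = int(rng.choice(len(arms), p=probs))
            arm = arms[ai]
            mid = float(rng.uniform(half, lengths[ai] - half))
        start = int(round(mid - half))
        loci.append(GeneLocus(gid, arm, start, start + gene_length))
    return loci


def simulate_go_annotations(
    genes: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 300),
    spiked_term: tuple[str, int, Sequence[str], int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> GO-term assignments, optionally with a spiked term.

    Each decoy term annotates a uniform random subset of ``genes`` with
    size drawn uniformly from ``term_size_range``. ``spiked_term`` is a
    tuple ``(term_id, term_size, query_genes, n_overlap)``: its member
    set is forced to contain exactly ``n_overlap`` genes of the query,
    emulating a genuinely over-represented category.

    Returns a two-column DataFrame (gene_id, term).
    """
    genes = list(genes)
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError("term sizes must satisfy 1 <= min <= max <= n_genes")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        rows.extend((genes[i], f"GO:{t:07d}") for i in members)
    if spiked_term is not None:
        term_id, size, query, n_overlap = spiked_term
        query = [g for g in query if g in set(genes)]
        if n_overlap > size:
            raise ValueError("spiked overlap exceeds the term size")
        if n_overlap > len(query):
            raise ValueError("spiked overlap exceeds the query size")
        gene_set = set(genes)
        background = sorted(gene_set - set(query))
        if size - n_overlap > len(background):
            raise ValueError("term size exceeds available non-query genes")
        inside = rng.choice(len(query), size=n_overlap, replace=False)
        outside = rng.choice(len(background), size=size - n_overlap, replace=False)
        members2 = [query[i] for i in inside] + [background[i] for i in outside]
        rows.extend((g, term_id) for g in members2)
    return pd.DataFrame(rows, columns=["gene_id", "term"])


@dataclass(frozen=True)
class GenotypeSample:
    """Diploid genotype counts at a biallelic insertion locus."""

    n_hom_insertion: int
    n_het: int
    n_hom_reference: int
    population: str = ""

    def __post_init__(self) -> None:
        if min(self.n_hom_insertion, self.n_het, self.n_hom_reference) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.n_hom_insertion + self.n_het + self.n_hom_reference


def simulate_genotypes(
    n_individuals: int, allele_freq: float, seed: int = 0, population: str = ""
) -> GenotypeSample:
    """Draw genotype counts under Hardy-Weinberg proportions (p^2, 2pq, q^2)."""
    if n_individuals < 0:
        raise ValueError("n_individuals must be >= 0")
    if not 0 <= allele_freq <= 1:
        raise ValueError("allele_freq must lie in [0,1]")
    p = allele_freq
    rng = np.random.default_rng(seed)
    hom_ins, het, hom_ref = rng.multinomial(
        n_individuals, [p * p, 2 * p * (1 - p), (1 - p) ** 2]
    )
    return GenotypeSample(int(hom_ins), int(het), int(hom_ref), population)
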