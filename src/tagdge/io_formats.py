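"""Readers, writers and validated containers for the pipeline's external files.

All tabular formats are UTF-8, tab-delimited, LF-terminated. Genomic
coordinates follow the BED convention (0-based, half-open) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "GeneLocus",
    "RunConfig",
    "compute_size_factors",
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_gene2go",
    "write_gene2go",
    "write_results",
    "read_results",
    "load_config",
    "mapping_error_rate",
    "RESULT_FIXED_COLUMNS",
]


class FormatError(ValueError):
    """Malformed external input; readers raise rather than coerce."""


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a chromosome arm (0-based, half-open)."""

    gene_id: str
    arm: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"locus {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ExpressionMatrix:
    """Integer tag counts for genes x samples with a two-condition design.

    Parameters
    ----------
    counts
        Genes in rows (unique ids as index), samples in columns.
        Entries must be non-negative integers.
    design
        Sample id -> condition label. Exactly two condition levels,
        each with at least one sample.
    size_factors
        Per-sample positive scaling constants; defaults to 1 for every
        sample (i.e. no depth normalisation).
    """

    counts: pd.DataFrame
    design: dict[str, str]
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = [s for s in self.counts.columns if s not in self.design]
        if missing:
            raise FormatError(f"samples absent from design: {missing}")
        extra = [s for s in self.design if s not in self.counts.columns]
        if extra:
            raise FormatError(f"design samples absent from matrix: {extra}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            bad = ~np.equal(np.mod(vals, 1), 0)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-integer count {vals[g, s]!r} for gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count for gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        levels = sorted(set(self.design.values()))
        if len(levels) != 2:
            raise FormatError(f"design must have exactly 2 conditions, got {levels}")
        if self.size_factors is None:
            self.size_factors = pd.Series(1.0, index=self.counts.columns)
        else:
            sf = self.size_factors
            if isinstance(sf, (pd.Series, dict)):
                sf = pd.Series(sf, dtype=float).reindex(self.counts.columns)
            else:  # positional sequence, one factor per sample column
                sf = np.asarray(sf, dtype=float)
                if sf.shape != (self.counts.shape[1],):
                    raise FormatError(
                        f"need {self.counts.shape[1]} size factors, got {sf.shape}"
                    )
                sf = pd.Series(sf, index=self.counts.columns)
            self.size_factors = sf
            if self.size_factors.isna().any() or (self.size_factors <= 0).any():
                raise FormatError("size factors must be positive for every sample")

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, sorted."""
        return sorted(set(self.design.values()))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]

    def normalized(self) -> pd.DataFrame:
        """Counts divided by the per-sample size factors."""
        return self.counts / self.size_factors

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[list(gene_ids)],
            design=dict(self.design),
            size_factors=self.size_factors.copy(),
        )


@dataclass
class RunConfig:
    """Validated run parameters for the end-to-end pipeline."""

    fdr_level: float = 0.05
    loess_span: float = 0.3
    dispersion_floor: float = 1.0
    size_factor_method: str = "total-count"  # or "none"
    clustering_iterations: int = 10_000
    seed: int = 0
    excluded_go_terms: tuple[str, ...] = ()
    consistency_mode: str = "minmax"  # or "pairwise"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError(f"FDR level must be in (0,1), got {self.fdr_level}")
        if not 0 < self.loess_span <= 1:
            raise ValueError(f"loess span must be in (0,1], got {self.loess_span}")
        if self.dispersion_floor < 0:
            raise ValueError("dispersion floor must be non-negative")
        if self.clustering_iterations < 1:
            raise ValueError("clustering iterations must be >= 1")
        if self.size_factor_method not in ("total-count", "none"):
            raise ValueError(f"unknown size-factor method {self.size_factor_method!r}")
        if self.consistency_mode not in ("minmax", "pairwise"):
            raise ValueError(f"unknown consistency mode {self.consistency_mode!r}")
        self.excluded_go_terms = tuple(self.excluded_go_terms)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a flat-key YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping")
    known = RunConfig.__dataclass_fields__
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise FormatError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def compute_size_factors(
    counts: pd.DataFrame, method: str = "total-count"
) -> pd.Series:
    """Per-sample scaling constants.

    ``total-count``: column total divided by the geometric mean of the
    column totals, so the factors multiply to one and normalised library
    sizes are equal. ``none``: all ones.
    """
    if method == "none":
        return pd.Series(1.0, index=counts.columns)
    if method != "total-count":
        raise ValueError(f"unknown size-factor method {method!r}")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    return totals / math.exp(np.log(totals).mean())


# ---------------------------------------------------------------------------
# Count tables


def read_counts(path: str | Path, design: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene x sample count TSV (first column gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    unknown = [c for c in df.columns if c not in design]
    if unknown:
        raise FormatError(f"samples in {path} not present in design: {unknown}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            as_float = df[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric count in sample {col!r}: {exc}") from exc
        frac = as_float % 1
        if (frac != 0).any():
            gene = df.index[(frac != 0).to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-integer count {as_float.loc[gene]} for gene {gene!r}, "
                f"sample {col!r}"
            )
        numeric[col] = as_float.astype(np.int64)
    return ExpressionMatrix(counts=numeric, design=dict(design))


def write_counts(path: str | Path, matrix: ExpressionMatrix) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# BED gene maps


def read_bed(path: str | Path) -> list[GeneLocus]:
    """Read a BED file with >= 4 columns into gene loci, order preserved."""
    loci: list[GeneLocus] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            arm, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            strand = parts[5] if len(parts) >= 6 else None
            try:
                loci.append(GeneLocus(name, arm, start, end, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_bed(path: str | Path, loci: Sequence[GeneLocus]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for loc in loci:
            fields = [loc.arm, str(loc.start), str(loc.end), loc.gene_id]
            if loc.strand is not None:
                fields += ["0", loc.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene -> GO associations


def read_gene2go(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene_id, term), many-to-many, header required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "term"]
    if list(df.columns[:2]) != required:
        raise FormatError(
            f"{path}: expected columns {required}, got {list(df.columns[:2])}"
        )
    if df[required].isna().any().any():
        raise FormatError(f"{path}: empty gene_id or term field")
    return df[required]


def write_gene2go(path: str | Path, table: pd.DataFrame) -> None:
    table[["gene_id", "term"]].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Results tables

RESULT_FIXED_COLUMNS = [
    "mean",
    "raw_dispersion",
    "smoothed_dispersion",
    "lrt_stat",
    "p_value",
    "q_value",
    "direction",
    "consistent",
]


def write_results(path: str | Path, results: pd.DataFrame) -> None:
    """Write the per-gene results table.

    Columns: gene_id, one count column per sample, then the fixed
    statistics columns (mean, raw/smoothed dispersion, LRT statistic,
    p, BH q, direction, consistency flag). A ``de`` call column, if
    present, is derivable from direction + consistent and is not
    written.
    """
    missing = [c for c in RESULT_FIXED_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing columns: {missing}")
    lead = [
        c for c in results.columns if c not in RESULT_FIXED_COLUMNS and c != "de"
    ]
    out = results[lead + RESULT_FIXED_COLUMNS].copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in RESULT_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Mapping-parameter arithmetic


def mapping_error_rate(read_length: int, max_mismatches: int) -> float:
    """Maximum tolerated per-base error rate, as a percentage.

    For short-read alignment allowing ``max_mismatches`` mismatches on
    reads of ``read_length`` bases (e.g. 2 mismatches on 32-mers gives
    6.25%).
    """
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    if not 0 <= max_mismatches <= read_length:
        raise ValueError("mismatches must be between 0 and the read length")
    return 100.0 * max_mismatches / read_length
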