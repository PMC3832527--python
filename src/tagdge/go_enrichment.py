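"""GO term over-representation by the one-sided hypergeometric test.

For each term with X annotated genes in the universe and N in the query
of size q, the p-value is the upper hypergeometric tail
P(count >= N | universe, X, q) — Fisher's exact test for
over-representation. p-values are Benjamini-Hochberg adjusted across
terms. The universe is restricted to genes carrying at least one
annotation, matching the convention of genome-background enrichment
tools; no GO-graph ancestor propagation is performed (pre-propagated
annotation tables are accepted as-is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GOTermResult", "enrich"]


@dataclass(frozen=True)
class GOTermResult:
    term: str
    n_query: int  # N: query genes carrying the term
    n_universe: int  # X: universe genes carrying the term
    query_size: int
    universe_size: int
    p_value: float
    q_value: float
    name: str | None = None


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    gene2go: pd.DataFrame,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank GO terms by over-representation in the query gene list.

    Parameters
    ----------
    query, universe
        Gene id sets; the query must be a subset of the universe. Both
        are restricted to genes with at least one annotation before
        testing.
    gene2go
        Two-column DataFrame (gene_id, term), many-to-many.

    Returns
    -------
    DataFrame sorted by ascending p with columns ``term``, ``n_query``
    (N), ``n_universe`` (X), ``query_size``, ``universe_size``,
    ``p_value``, ``q_value`` and optional ``name``.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)[:5]}")

    anno = gene2go[gene2go["gene_id"].isin(universe)]
    annotated = set(anno["gene_id"])
    universe &= annotated
    query &= annotated
    M, q = len(universe), len(query)
    if M == 0:
        raise ValueError("no annotated genes in the universe")

    per_term = anno.groupby("term")["gene_id"].agg(set)
    rows = []
    for term, members in per_term.items():
        X = len(members)
        N = len(members & query)
        # P(count >= N) given q draws from M with X successes
        p = float(hypergeom.sf(N - 1, M, X, q)) if N > 0 else 1.0
        rows.append((term, N, X, q, M, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["term", "n_query", "n_universe", "query_size", "universe_size", "p_value"],
    )
    if len(table):
        _, qvals, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["q_value"] = np.maximum(qvals, table["p_value"])
    else:
        table["q_value"] = pd.Series(dtype=float)
    if term_names:
        table["name"] = table["term"].map(term_names)
    table = table.sort_values(
        ["p_value", "term"], kind="stable", ignore_index=True
    )
    return table
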