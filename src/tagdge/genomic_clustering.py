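"""Monte Carlo test for genomic clustering of a gene set.

The statistic is the mean nearest-neighbour distance: for each selected
gene, the distance from its midpoint to the closest other selected gene
on the same chromosome arm, averaged over genes that have at least one
within-arm neighbour (cross-arm distances are undefined and treated as
infinite). The null distribution is obtained by repeatedly drawing the
same number of genes uniformly without replacement from the analysed
universe; the p-value is the add-one estimate of the probability of a
mean distance as small or smaller under the null, so clustered sets
yield small p.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneLocus

__all__ = [
    "ClusteringTestResult",
    "nearest_neighbor_mean_distance",
    "clustering_test",
]


@dataclass
class ClusteringTestResult:
    observed: float
    n_iterations: int
    p_value: float
    n_selected: int
    null_sample: np.ndarray | None = None
    exact: bool = False

    def as_dict(self) -> dict:
        return {
            "observed_mean_nn_distance": self.observed,
            "iterations": self.n_iterations,
            "p_value": self.p_value,
            "n_selected": self.n_selected,
            "exact": self.exact,
        }


def _mean_nn_from_arrays(arm_codes: np.ndarray, mids: np.ndarray) -> float:
    """Mean within-arm nearest-neighbour distance; NaN if no arm has >= 2."""
    order = np.lexsort((mids, arm_codes))
    a = arm_codes[order]
    m = mids[order]
    n = m.size
    if n < 2:
        return np.nan
    gaps = np.diff(m)
    same = a[:-1] == a[1:]
    left = np.full(n, np.inf)
    right = np.full(n, np.inf)
    right[:-1] = np.where(same, gaps, np.inf)
    left[1:] = right[:-1]
    nn = np.minimum(left, right)
    finite = np.isfinite(nn)
    if not finite.any():
        return np.nan
    return float(nn[finite].mean())


def nearest_neighbor_mean_distance(selected: Sequence[GeneLocus]) -> float:
    """Average distance from each gene to its nearest selected neighbour.

    Distances are between midpoints and only defined within a
    chromosome arm; genes alone on their arm are excluded from the
    average. Raises if no arm carries at least two selected genes.
    """
    arms = {loc.arm for loc in selected}
    codes = {a: i for i, a in enumerate(sorted(arms))}
    arm_codes = np.array([codes[loc.arm] for loc in selected])
    mids = np.array([loc.midpoint for loc in selected], dtype=float)
    val = _mean_nn_from_arrays(arm_codes, mids)
    if np.isnan(val):
        raise ValueError("no chromosome arm contains two or more selected genes")
    return val


def clustering_test(
    universe: Sequence[GeneLocus],
    selected_ids: Iterable[str],
    n_iterations: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> ClusteringTestResult:
    """Test whether the selected genes sit closer together than random sets.

    Monte Carlo (default): ``n_iterations`` uniform draws of
    ``len(selected)`` genes without replacement from the universe; the
    p-value is ``(1 + #{null <= observed}) / (n_iterations + 1)`` (ties
    count as at-least-as-clustered, and the estimator never returns 0).

    Exhaustive: enumerate every subset of the universe of the selected
    size and return the exact probability ``#{stat <= observed} /
    C(n, k)``; feasible only for small universes.
    """
    ids = {loc.gene_id for loc in universe}
    selected_ids = set(selected_ids)
    missing = selected_ids - ids
    if missing:
        raise ValueError(f"selected ids absent from universe: {sorted(missing)[:5]}")
    k = len(selected_ids)
    n = len(universe)
    if k > n:
        raise ValueError("selection larger than universe")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    arms = sorted({loc.arm for loc in universe})
    codes = {a: i for i, a in enumerate(arms)}
    arm_codes = np.array([codes[loc.arm] for loc in universe])
    mids = np.array([loc.midpoint for loc in universe], dtype=float)
    sel_mask = np.array([loc.gene_id in selected_ids for loc in universe])

    observed = _mean_nn_from_arrays(arm_codes[sel_mask], mids[sel_mask])
    if np.isnan(observed):
        raise ValueError("no chromosome arm contains two or more selected genes")

    if exhaustive:
        total = comb(n, k)
        hits = 0
        for combo in combinations(range(n), k):
            idx = np.fromiter(combo, dtype=int, count=k)
            val = _mean_nn_from_arrays(arm_codes[idx], mids[idx])
            if not np.isnan(val) and val <= observed:
                hits += 1
        return ClusteringTestResult(
            observed=observed,
            n_iterations=total,
            p_value=hits / total,
            n_selected=k,
            exact=True,
        )

    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for b in range(n_iterations):
        idx = rng.choice(n, size=k, replace=False)
        null[b] = _mean_nn_from_arrays(arm_codes[idx], mids[idx])
    valid = ~np.isnan(null)
    hits = int((null[valid] <= observed).sum())
    p = (1 + hits) / (n_iterations + 1)
    return ClusteringTestResult(
        observed=observed,
        n_iterations=n_iterations,
        p_value=p,
        n_selected=k,
        null_sample=null,
    )
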