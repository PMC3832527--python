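"""Two-condition overdispersed-Poisson testing with plug-in dispersion.

Step 2 of the procedure: for each gene, condition-specific means are
fitted by maximum likelihood under a Poisson likelihood on the
depth-normalised counts (the dispersion scales the quasi-likelihood and
leaves the mean MLEs unchanged), and the population contrast
H0: lambda_G = lambda_M is tested by a likelihood-ratio statistic scaled
by the smoothed dispersion from step 1, referred to chi-square with one
degree of freedom.
p-values are corrected by Benjamini-Hochberg step-up at the configured
FDR level. Two auxiliary stages bracket the test: an annotation-based
gene exclusion applied before any statistics, and a replicate
consistency filter applied to the significant genes afterwards.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dispersion_model import (
    DispersionEstimates,
    estimate_gene_dispersion,
    loess_smooth_dispersion,
)
from .io_formats import ExpressionMatrix, RunConfig, compute_size_factors

__all__ = [
    "exclude_genes_by_terms",
    "fit_condition_means",
    "lrt_test",
    "bh_adjust",
    "consistency_filter",
    "run_de_pipeline",
]

logger = logging.getLogger(__name__)


def exclude_genes_by_terms(
    matrix: ExpressionMatrix,
    gene2go: pd.DataFrame,
    excluded_terms: Iterable[str],
) -> ExpressionMatrix:
    """Drop genes annotated to any of the excluded GO terms.

    Applied before any statistics so that the excluded genes (e.g. an
    immunity category confounded by a known contamination) contribute
    neither to dispersion estimation nor to the multiple-testing burden.
    Annotations for genes absent from the matrix are ignored with a
    warning.
    """
    excluded_terms = set(excluded_terms)
    if not excluded_terms:
        return matrix
    hits = gene2go[gene2go["term"].isin(excluded_terms)]
    flagged = set(hits["gene_id"])
    unknown = flagged - set(matrix.counts.index)
    if unknown:
        logger.warning(
            "%d excluded-term genes not present in the count matrix", len(unknown)
        )
    keep = [g for g in matrix.counts.index if g not in flagged]
    removed = matrix.n_genes - len(keep)
    logger.info("excluded %d genes annotated to %d terms", removed, len(excluded_terms))
    return matrix.subset(keep)


def fit_condition_means(
    matrix: ExpressionMatrix, gene: str
) -> tuple[float, float, float]:
    """Closed-form ML condition means for one gene.

    The model is fitted on the depth-normalised counts z_r = Y_r / s_r
    (the same scale on which the step-1 dispersion is estimated), so
    lambda_c is the average of z over the replicates of condition c and
    the common (null) mean averages all samples. With equal size
    factors this coincides with the count-scale fit with offsets.
    Returns ``(lambda_cond1, lambda_cond2, lambda_null)`` with
    conditions in sorted label order.
    """
    c1, c2 = matrix.conditions
    z = matrix.normalized().loc[gene]
    out = []
    for cond in (c1, c2):
        samples = matrix.samples_for(cond)
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        out.append(z[samples].mean())
    return out[0], out[1], z.mean()


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Sum over samples of y*log(mu) - mu, with 0*log(0) = 0 (y! dropped)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return (term - mu).sum(axis=1)


def lrt_test(
    matrix: ExpressionMatrix, dispersions: DispersionEstimates
) -> pd.DataFrame:
    """Quasi-likelihood-ratio test of the condition contrast per gene.

    T_g = 2 * [l(lambda_1, lambda_2) - l(lambda_0)] / phi_g with l the
    Poisson log-likelihood evaluated on the depth-normalised counts
    (the scale of the step-1 dispersion; identical to the count-scale
    fit with offsets when library sizes are equal) and phi_g the
    smoothed plug-in dispersion; p from the upper chi-square(1) tail.
    Genes with zero total count are untestable (NaN statistic and p).

    Returns a DataFrame indexed by gene with columns ``mean_<c1>``,
    ``mean_<c2>``, ``mean_null``, ``dispersion``, ``lrt_stat``,
    ``p_value``, ``testable``.
    """
    c1, c2 = matrix.conditions
    z = matrix.normalized().to_numpy(dtype=float)
    in1 = np.array([matrix.design[c] == c1 for c in matrix.counts.columns])
    z1, z2 = z[:, in1], z[:, ~in1]

    lam1 = z1.mean(axis=1)
    lam2 = z2.mean(axis=1)
    lam0 = z.mean(axis=1)

    phi = dispersions.smoothed.reindex(matrix.counts.index).to_numpy()
    testable = dispersions.testable.reindex(matrix.counts.index).to_numpy()
    if np.isnan(phi[testable]).any():
        raise ValueError("smoothed dispersion missing for a testable gene")

    ll_alt = _poisson_loglik(z1, np.broadcast_to(lam1[:, None], z1.shape)) + (
        _poisson_loglik(z2, np.broadcast_to(lam2[:, None], z2.shape))
    )
    ll_null = _poisson_loglik(z, np.broadcast_to(lam0[:, None], z.shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        T = 2.0 * (ll_alt - ll_null) / phi
    T = np.where(testable, np.maximum(T, 0.0), np.nan)
    p = np.where(testable, stats.chi2.sf(T, df=1), np.nan)

    return pd.DataFrame(
        {
            f"mean_{c1}": lam1,
            f"mean_{c2}": lam2,
            "mean_null": lam0,
            "dispersion": phi,
            "lrt_stat": T,
            "p_value": p,
            "testable": testable,
        },
        index=matrix.counts.index,
    )


def bh_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(qvalues, reject)``; a gene is rejected when its q-value
    is <= alpha (boundary counts as significant). NaN p-values pass
    through as NaN / not rejected and do not contribute to m.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
        reject[ok] = q_ok <= alpha
    return q, reject


def _assign_directions(
    results: pd.DataFrame, reject: np.ndarray, c1: str, c2: str
) -> pd.Series:
    direction = pd.Series("none", index=results.index)
    up1 = reject & (results[f"mean_{c1}"] > results[f"mean_{c2}"]).to_numpy()
    up2 = reject & (results[f"mean_{c2}"] > results[f"mean_{c1}"]).to_numpy()
    direction[up1] = f"up_in_{c1}"
    direction[up2] = f"up_in_{c2}"
    return direction


def consistency_filter(
    results: pd.DataFrame,
    matrix: ExpressionMatrix,
    mode: str = "minmax",
) -> pd.DataFrame:
    """Require every replicate of the higher condition to beat the other.

    A gene called up in condition A keeps its DE status only if its
    normalised replicate counts are consistently greater than those in
    the other condition: in ``minmax`` mode (default, stricter) the
    smallest A replicate must strictly exceed the largest B replicate;
    in ``pairwise`` mode the r-th A replicate must exceed the r-th B
    replicate for every r (requires equal replicate numbers). Filtered
    genes keep their p/q values but are no longer counted as DE.

    Adds/overwrites the ``consistent`` and ``de`` columns.
    """
    if mode not in ("minmax", "pairwise"):
        raise ValueError(f"unknown consistency mode {mode!r}")
    c1, c2 = matrix.conditions
    z = matrix.normalized()
    z1 = z[matrix.samples_for(c1)].to_numpy()
    z2 = z[matrix.samples_for(c2)].to_numpy()
    out = results.copy()
    direction = out["direction"]

    if mode == "pairwise" and z1.shape[1] != z2.shape[1]:
        raise ValueError("pairwise mode requires equal replicate numbers")

    if mode == "minmax":
        ok_up1 = z1.min(axis=1) > z2.max(axis=1)
        ok_up2 = z2.min(axis=1) > z1.max(axis=1)
    else:
        ok_up1 = (z1 > z2).all(axis=1)
        ok_up2 = (z2 > z1).all(axis=1)

    consistent = np.ones(len(out), dtype=bool)
    is_up1 = (direction == f"up_in_{c1}").to_numpy()
    is_up2 = (direction == f"up_in_{c2}").to_numpy()
    consistent[is_up1] = ok_up1[is_up1]
    consistent[is_up2] = ok_up2[is_up2]

    out["consistent"] = consistent
    pre = is_up1 | is_up2
    out["de"] = pre & consistent
    n_filtered = int(pre.sum() - out["de"].sum())
    logger.info(
        "consistency filter: %d of %d DE genes removed, %d remain",
        n_filtered,
        int(pre.sum()),
        int(out["de"].sum()),
    )
    return out


def run_de_pipeline(
    matrix: ExpressionMatrix,
    config: RunConfig | None = None,
    gene2go: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full two-step analysis: exclusion, normalisation, dispersion,
    Loess smoothing, quasi-LRT, BH correction, consistency filter.

    Returns ``(results, summary)``. ``results`` is indexed by gene and
    contains the per-sample counts, pooled mean, raw and smoothed
    dispersion, LRT statistic, p, q, direction, consistency flag and
    final ``de`` call. ``summary`` carries the stage-by-stage gene
    bookkeeping; ``n_post_filter_de == n_pre_filter_de - n_filtered``
    always holds.
    """
    config = config or RunConfig()
    n_input = matrix.n_genes
    if gene2go is not None and config.excluded_go_terms:
        matrix = exclude_genes_by_terms(matrix, gene2go, config.excluded_go_terms)
    n_excluded = n_input - matrix.n_genes

    sf = compute_size_factors(matrix.counts, config.size_factor_method)
    matrix = ExpressionMatrix(
        counts=matrix.counts, design=dict(matrix.design), size_factors=sf
    )

    est = estimate_gene_dispersion(matrix)
    est = loess_smooth_dispersion(
        est, span=config.loess_span, floor=config.dispersion_floor
    )
    res = lrt_test(matrix, est)
    q, reject = bh_adjust(res["p_value"], alpha=config.fdr_level)
    res["q_value"] = q

    c1, c2 = matrix.conditions
    res["direction"] = _assign_directions(res, reject, c1, c2)
    res = consistency_filter(res, matrix, mode=config.consistency_mode)

    n_up1 = int((res["direction"] == f"up_in_{c1}").sum())
    n_up2 = int((res["direction"] == f"up_in_{c2}").sum())
    n_pre = n_up1 + n_up2
    n_post = int(res["de"].sum())

    results = matrix.counts.copy().astype(float)
    results["mean"] = est.mean
    results["raw_dispersion"] = est.raw
    results["smoothed_dispersion"] = est.smoothed
    for col in ("lrt_stat", "p_value", "q_value"):
        results[col] = res[col]
    results["direction"] = res["direction"]
    results["consistent"] = res["consistent"]
    results["de"] = res["de"]

    summary = {
        "n_input": n_input,
        "n_excluded": n_excluded,
        "n_testable": int(res["testable"].sum()),
        "n_pre_filter_de": n_pre,
        f"n_up_in_{c1}": n_up1,
        f"n_up_in_{c2}": n_up2,
        "n_filtered": n_pre - n_post,
        "n_post_filter_de": n_post,
        "fdr_level": config.fdr_level,
        "size_factor_method": config.size_factor_method,
    }
    assert summary["n_post_filter_de"] == summary["n_pre_filter_de"] - summary["n_filtered"]
    logger.info("pipeline summary: %s", summary)
    return results, summary
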