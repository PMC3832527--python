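"""Per-gene dispersion estimation and smoothing along the mean trend.

Step 1 of the two-step testing procedure. Under the hypothesis that most
genes are not differentially expressed, a common-mean overdispersed
Poisson model is fitted gene by gene across ALL replicates, pooled over
conditions, to give a moment estimate of the per-gene dispersion
phi_g (quasi-Poisson scale, Var = phi * mean). Because genes of similar
average expression have similar dispersion, the noisy per-gene estimates
are then replaced by a Loess fit of dispersion against log10 mean
expression, evaluated at each gene. A global quadratic regression on the
same axis is provided as a diagnostic comparison; on real tag data the
two curves nearly coincide.

For truly non-DE genes the moment estimator is unbiased; for DE genes
the pooled mean inflates it, which makes the downstream test
conservative rather than anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "DispersionEstimates",
    "estimate_gene_dispersion",
    "loess_smooth_dispersion",
    "quadratic_dispersion_fit",
    "loess_fit",
]


@dataclass
class DispersionEstimates:
    """Per-gene mean and dispersion estimates.

    ``table`` is indexed by gene id with columns:

    - ``mean``: mean normalised count lambda_g (pooled over conditions)
    - ``raw_dispersion``: moment estimate phi_g (NaN for zero-mean genes)
    - ``smoothed_dispersion``: Loess estimate, NaN until smoothing runs
    - ``testable``: False for genes with zero counts in every sample
    """

    table: pd.DataFrame

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def raw(self) -> pd.Series:
        return self.table["raw_dispersion"]

    @property
    def smoothed(self) -> pd.Series:
        return self.table["smoothed_dispersion"]

    @property
    def testable(self) -> pd.Series:
        return self.table["testable"]


def estimate_gene_dispersion(matrix: ExpressionMatrix) -> DispersionEstimates:
    """Moment estimate of the per-gene dispersion from pooled replicates.

    With normalised counts z_{g,r} = Y_{g,r} / s_r over all R samples,

        lambda_g = mean_r z_{g,r}
        phi_g    = sum_r (z_{g,r} - lambda_g)^2 / ((R - 1) * lambda_g)

    Genes with lambda_g = 0 carry no information; they get NaN dispersion
    and are flagged not testable.
    """
    z = matrix.normalized().to_numpy(dtype=float)
    n_genes, R = z.shape
    if R < 2:
        raise ValueError("need at least two samples to estimate dispersion")
    lam = z.mean(axis=1)
    if not (lam > 0).any():
        raise ValueError("all-zero count matrix")
    ss = ((z - lam[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = ss / ((R - 1) * lam)
    phi[lam == 0] = np.nan
    table = pd.DataFrame(
        {
            "mean": lam,
            "raw_dispersion": phi,
            "smoothed_dispersion": np.nan,
            "testable": lam > 0,
        },
        index=matrix.counts.index,
    )
    return DispersionEstimates(table)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    For each evaluation point, the nearest ``ceil(span * n)`` data
    points (a contiguous window in sorted x) are fitted by weighted
    least squares of the given degree and the fit is evaluated at the
    point. No robustness iterations. If a window is degenerate (all x
    identical), the tricube-weighted mean is returned instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be one-dimensional and equal length")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0,1], got {span}")
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 2)
    if k > n:
        raise ValueError(
            f"window of {k} points exceeds the {n} usable genes; "
            "increase span or provide more genes"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)

    out = np.empty(x_eval.size)
    lo = 0  # sliding window left edge over sorted x
    for idx in np.argsort(x_eval, kind="stable"):
        x0 = x_eval[idx]
        # advance window while the next point is closer than the current far edge
        while lo + k < n and (xs[lo + k] - x0) < (x0 - xs[lo]):
            lo += 1
        xw = xs[lo : lo + k]
        yw = ys[lo : lo + k]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            # every neighbour ties at distance 0: average all points at x0
            out[idx] = ys[xs == x0].mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w[w < 0] = 0.0
        xc = xw - x0  # center for conditioning; intercept is the fitted value
        X = np.vander(xc, degree + 1, increasing=True)
        WX = X * w[:, None]
        xtx = X.T @ WX
        xty = WX.T @ yw
        try:
            beta = np.linalg.solve(xtx, xty)
            out[idx] = beta[0]
        except np.linalg.LinAlgError:
            out[idx] = np.average(yw, weights=w) if w.sum() > 0 else yw.mean()
    return out


def loess_smooth_dispersion(
    est: DispersionEstimates, span: float = 0.3, floor: float = 1.0
) -> DispersionEstimates:
    """Fill smoothed dispersions by Loess of phi on log10(mean).

    Local quadratic, tricube weights; the result is clamped from below
    at ``floor`` (default 1, the Poisson bound) so the step-2 test is
    never scaled by a sub-Poisson dispersion. Genes flagged not testable
    keep NaN. Output order matches input order.
    """
    usable = est.table["testable"] & est.table["raw_dispersion"].notna()
    if usable.sum() < 10:
        raise ValueError("need at least 10 genes with defined dispersion")
    x = np.log10(est.table.loc[usable, "mean"].to_numpy())
    y = est.table.loc[usable, "raw_dispersion"].to_numpy()
    smooth = loess_fit(x, y, span=span, degree=2)
    table = est.table.copy()
    table.loc[usable, "smoothed_dispersion"] = np.maximum(smooth, floor)
    return DispersionEstimates(table)


def quadratic_dispersion_fit(
    est: DispersionEstimates,
) -> tuple[np.ndarray, np.ndarray]:
    """Global least-squares fit of phi on (1, x, x^2), x = log10(mean).

    Returns ``(coefficients, fitted)`` with coefficients ordered
    (intercept, linear, quadratic); ``fitted`` is NaN for genes without
    a defined raw dispersion. Diagnostic companion to the Loess curve.
    """
    usable = est.table["testable"] & est.table["raw_dispersion"].notna()
    x = np.log10(est.table.loc[usable, "mean"].to_numpy())
    y = est.table.loc[usable, "raw_dispersion"].to_numpy()
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct mean values for a quadratic fit")
    X = np.vander(x, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = np.full(len(est.table), np.nan)
    fitted[usable.to_numpy()] = X @ coef
    return coef, fitted


def dispersion_diagnostic_table(
    est: DispersionEstimates,
) -> pd.DataFrame:
    """Per-gene table of (log10 mean, raw, smoothed, quadratic-fit) values.

    The data layer of the standard mean-dispersion diagnostic plot.
    """
    _, fitted = quadratic_dispersion_fit(est)
    with np.errstate(divide="ignore"):
        log_mean = np.log10(est.table["mean"].to_numpy())
    return pd.DataFrame(
        {
            "log10_mean": log_mean,
            "raw_dispersion": est.table["raw_dispersion"],
            "smoothed_dispersion": est.table["smoothed_dispersion"],
            "quadratic_fit": fitted,
        },
        index=est.table.index,
    )
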