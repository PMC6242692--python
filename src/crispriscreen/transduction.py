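"""Per-gene linear model separating capsid-production defects from growth.

After packaging a guide-bearing cosmid library into phage capsids and
transducing a recipient strain, a guide's post-transduction log2FC
mostly reflects the growth cost of the guide.  To find host genes that
disproportionately reduce the yield of functional capsids, a linear
model is fitted for each gene over all retained coding-strand guides:

    y = b0 + b1 * x + b2 * z

where y is the transduction log2FC, x the growth-screen log2FC and z
an indicator marking the focal gene's guides.  The gene is a hit when z
significantly improves the fit (nested F-test, one numerator degree of
freedom) after Benjamini-Hochberg correction (FDR < 0.05); b2 (the
"estimate") ranks genes, negative values meaning silencing decreases
functional-capsid output.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .stats import bh_adjust

__all__ = [
    "HostFactorRegressor",
    "fit_gene_model",
    "host_factor_screen",
    "global_fitness_regression",
]


def fit_gene_model(
    y: np.ndarray, x: np.ndarray, z: np.ndarray
) -> tuple[float, float, float]:
    """OLS of y = b0 + b1 x + b2 z with a nested F-test on z.

    Returns (estimate, F, p) where estimate is b2.  ``z`` must mark a
    non-empty proper subset of the guides; a design collinear in x and z
    yields (nan, 0, 1) with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(y)
    if not (len(x) == len(z) == n):
        raise ValueError("y, x, z must have equal length")
    if z.min() == z.max():
        raise ValueError("gene indicator must mark a non-empty proper subset")
    if n < 6:
        raise ValueError("need at least 3 more guides than the 3 parameters")

    X_full = np.column_stack([np.ones(n), x, z])
    rank = np.linalg.matrix_rank(X_full)
    if rank < 3:
        warnings.warn("x and z are collinear; gene effect not identifiable",
                      stacklevel=2)
        return float("nan"), 0.0, 1.0
    X_red = X_full[:, :2]
    beta_full, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_red, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta_full) ** 2))
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))
    df_resid = n - 3
    tol = 1e-12 * (float(np.sum(y**2)) + 1.0)
    if rss_full <= tol:  # full model (near-)perfect
        if rss_red - rss_full <= tol:  # ... but z added nothing
            return float(beta_full[2]), 0.0, 1.0
        return float(beta_full[2]), float("inf"), 0.0
    f_stat = max((rss_red - rss_full) / (rss_full / df_resid), 0.0)
    p = float(sps.f.sf(f_stat, 1, df_resid))
    return float(beta_full[2]), float(f_stat), p


class HostFactorRegressor(BaseEstimator):
    """Per-gene nested-OLS screen over all retained coding-strand guides.

    ``fit`` takes an annotated library (``guide_id``, ``gene``) and two
    aligned per-guide Series: ``y`` (transduction log2FC) and ``x``
    (growth log2FC).  Guides missing either value are dropped and
    counted in ``n_dropped_``.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per gene: ``n_guides, estimate, F, pvalue, fdr, hit, direction``,
        ranked by estimate (most capsid-decreasing first).
    """

    def __init__(self, alpha: float = 0.05, min_guides: int = 1):
        self.alpha = alpha
        self.min_guides = min_guides

    def fit(
        self, library: pd.DataFrame, y: pd.Series, x: pd.Series
    ) -> "HostFactorRegressor":
        lib = library.dropna(subset=["gene"]).copy()
        if "is_control" in lib.columns:
            lib = lib[~lib["is_control"].astype(bool)]
        data = pd.DataFrame(
            {
                "gene": lib.set_index("guide_id")["gene"],
                "y": y,
                "x": x,
            }
        ).loc[lib["guide_id"]]
        complete = data.dropna(subset=["y", "x"])
        self.n_dropped_ = len(data) - len(complete)

        yv = complete["y"].to_numpy()
        xv = complete["x"].to_numpy()
        genes = complete["gene"].to_numpy()
        rows = []
        for gene in pd.unique(genes):
            z = (genes == gene).astype(float)
            n_g = int(z.sum())
            if n_g < self.min_guides or n_g == len(z):
                continue
            try:
                est, f_stat, p = fit_gene_model(yv, xv, z)
            except ValueError:
                continue
            rows.append(
                {"gene": gene, "n_guides": n_g, "estimate": est, "F": f_stat,
                 "pvalue": p}
            )
        res = pd.DataFrame(rows).set_index("gene")
        res["fdr"] = bh_adjust(res["pvalue"])
        res["hit"] = res["fdr"] < self.alpha
        res["direction"] = np.where(
            res["estimate"] < 0, "decreases_capsids", "increases_capsids"
        )
        self.results_ = res.sort_values("estimate")
        return self


def host_factor_screen(
    library: pd.DataFrame, y: pd.Series, x: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene transduction statistics (see :class:`HostFactorRegressor`)."""
    return HostFactorRegressor(alpha=alpha).fit(library, y, x).results_


def global_fitness_regression(
    y: np.ndarray | pd.Series, x: np.ndarray | pd.Series
) -> tuple[float, float, int, float]:
    """Simple OLS of transduction log2FC on growth log2FC.

    Returns (slope, F, residual df, p) from the F-test of the slope;
    used for the QC correlation plot.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 guides")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - 2
    if rss <= tss * 1e-14:
        return float(beta[1]), float("inf"), df, 0.0
    f_stat = (tss - rss) / (rss / df)
    p = float(sps.f.sf(f_stat, 1, df))
    return float(beta[1]), float(f_stat), df, p
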