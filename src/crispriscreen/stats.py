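"""Per-guide fold-change statistics for paired before/after screens.

Counts are normalized by the reads of a non-targeting control guide: the
control's per-sample counts act as the size factors of the comparison.
Two normalization scales are exposed:

* :func:`normalize_by_control` — the literal per-sample ratio
  ``count / control_count`` (the control row becomes all ones);
* size-factor normalization with geometric-mean-centred control counts,
  which keeps values on the count scale.  ``baseMean`` is defined on
  this scale so that a ``baseMean`` read-depth floor is meaningful.

Both scales give identical log2 fold-changes (the centring constant
cancels in the before/after ratio).

Significance is a documented stand-in for DESeq2, not a port: ratio-of-
means log2FC without shrinkage, method-of-moments negative-binomial
dispersion (shrunk toward the across-library trend, floored), a Wald
test on the per-guide log2FC with the control guide's own counting noise
propagated, and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenDesign",
    "FoldChangeEstimator",
    "normalize_by_control",
    "size_factors",
    "guide_log2fc",
    "nb_test",
    "base_mean",
    "bh_adjust",
]

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class ScreenDesign:
    """Paired before/after sample layout of a screen.

    ``samples`` maps sample_id -> (condition, replicate_id) with
    condition in {"before", "after"}; every after sample must pair with
    exactly one before sample of the same replicate.
    """

    samples: tuple[tuple[str, str, str], ...]  # (sample_id, condition, replicate)
    control_guide_id: str = "control"

    def __post_init__(self) -> None:
        reps: dict[str, dict[str, str]] = {}
        for sample_id, condition, rep in self.samples:
            if condition not in ("before", "after"):
                raise ValueError(f"unknown condition {condition!r}")
            slot = reps.setdefault(str(rep), {})
            if condition in slot:
                raise ValueError(f"replicate {rep} has two {condition!r} samples")
            slot[condition] = sample_id
        incomplete = [r for r, s in reps.items() if set(s) != {"before", "after"}]
        if incomplete or not reps:
            raise ValueError(f"unpaired replicates: {incomplete or 'none defined'}")

    @classmethod
    def from_frame(cls, design: pd.DataFrame, control_guide_id: str = "control") -> "ScreenDesign":
        rows = tuple(
            (str(r.sample_id), str(r.condition), str(r.replicate))
            for r in design.itertuples()
        )
        return cls(rows, control_guide_id)

    @property
    def pairs(self) -> list[tuple[str, str, str]]:
        """(replicate, before_sample, after_sample) sorted by replicate."""
        reps: dict[str, dict[str, str]] = {}
        for sample_id, condition, rep in self.samples:
            reps.setdefault(rep, {})[condition] = sample_id
        return [(r, s["before"], s["after"]) for r, s in sorted(reps.items())]

    @property
    def n_replicates(self) -> int:
        return len(self.pairs)

    def sample_ids(self) -> list[str]:
        return [s for s, _, _ in self.samples]


def _control_counts(counts: pd.DataFrame, design: ScreenDesign) -> pd.Series:
    gid = design.control_guide_id
    if gid not in counts.index:
        raise ValueError(f"control guide {gid!r} absent from count matrix")
    ctl = counts.loc[gid]
    zero = ctl[ctl <= 0]
    if len(zero):
        raise ValueError(
            f"control guide has zero reads in sample(s) {list(zero.index)}; "
            "cannot normalize"
        )
    return ctl.astype(float)


def normalize_by_control(counts: pd.DataFrame, design: ScreenDesign) -> pd.DataFrame:
    """Per-sample ratio to the control guide; the control row becomes 1."""
    ctl = _control_counts(counts, design)
    return counts.astype(float).div(ctl, axis=1)


def size_factors(counts: pd.DataFrame, design: ScreenDesign) -> pd.Series:
    """Control-guide size factors, geometric-mean-centred (count scale)."""
    ctl = _control_counts(counts, design)
    return ctl / np.exp(np.mean(np.log(ctl)))


def base_mean(normalized: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of normalized counts across all samples, per guide."""
    return normalized.mean(axis=1)


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


class FoldChangeEstimator(BaseEstimator):
    """Paired before/after per-guide log2 fold-change with significance.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Raw-read pseudocount; propagated through normalization (scaled by
        each sample's size factor) before the log ratio.
    dispersion_floor : float, default 0.01
        Lower bound on the per-guide negative-binomial dispersion.
    trim : float, default 0.1
        Trimming fraction for the across-library trend dispersion.

    Attributes (after :meth:`fit`)
    ------------------------------
    guide_stats_ : pandas.DataFrame
        Columns ``log2FC, baseMean, pvalue, padj`` indexed by guide.
    size_factors_ : pandas.Series
        Geometric-mean-centred control size factors.
    dispersion_ : pandas.Series
        Per-guide shrunk dispersion estimates.
    """

    def __init__(self, pseudocount: float = 0.5, dispersion_floor: float = 0.01,
                 trim: float = 0.1):
        self.pseudocount = pseudocount
        self.dispersion_floor = dispersion_floor
        self.trim = trim

    def fit(self, counts: pd.DataFrame, design: ScreenDesign) -> "FoldChangeEstimator":
        if counts.empty:
            raise ValueError("count matrix is empty")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        sf = size_factors(counts, design)
        norm = counts.astype(float).div(sf, axis=1)  # count scale
        eps = self.pseudocount / sf  # raw pseudocount propagated per sample

        pairs = design.pairs
        R = len(pairs)
        befores = [b for _, b, _ in pairs]
        afters = [a for _, _, a in pairs]
        nb = norm[befores].to_numpy()
        na = norm[afters].to_numpy()
        eb = eps[befores].to_numpy()
        ea = eps[afters].to_numpy()

        bmean = norm.to_numpy().mean(axis=1)

        # The single control guide's own counting noise is shared by all
        # guides of a sample.  A residual per-sample factor (median of
        # ratios over guides against a geometric-mean reference) removes
        # it; the control anchors the overall scale, the refinement only
        # absorbs its sampling noise.  Valid because a majority of
        # guides are null in every screen this pipeline handles.
        f_all = self._residual_factors(np.concatenate([nb, na], axis=1))
        fb, fa = f_all[:R], f_all[R:]
        nb_c, na_c = nb / fb, na / fa
        eb_c, ea_c = eb / fb, ea / fa

        log_ratios = np.log2(na_c + ea_c) - np.log2(nb_c + eb_c)
        log2fc = log_ratios.mean(axis=1)

        disp = self._dispersion(nb_c, na_c, bmean)
        pvals = self._wald(nb_c, na_c, eb_c, ea_c, disp, log2fc, R)
        padj = bh_adjust(pvals)

        idx = counts.index
        self.size_factors_ = sf
        self.normalized_ = norm
        self.dispersion_ = pd.Series(disp, index=idx, name="dispersion")
        self.guide_stats_ = pd.DataFrame(
            {"log2FC": log2fc, "baseMean": bmean, "pvalue": pvals, "padj": padj},
            index=idx,
        )
        self.guide_stats_.index.name = "guide_id"
        return self

    @staticmethod
    def _residual_factors(mat: np.ndarray) -> np.ndarray:
        """Per-sample median-of-ratios factors against the across-sample
        geometric-mean reference (computed over positive counts)."""
        with np.errstate(divide="ignore"):
            logn = np.log(mat)
        logn[~np.isfinite(logn)] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref = np.nanmean(logn, axis=1)
            dev = logn - ref[:, None]
            f = np.nanmedian(dev, axis=0)
        f[~np.isfinite(f)] = 0.0
        return np.exp(f - f.mean())

    def _dispersion(self, nb: np.ndarray, na: np.ndarray,
                    bmean: np.ndarray) -> np.ndarray:
        """Method-of-moments NB dispersion, shrunk toward a mean trend.

        The across-replicate variance of control-normalized counts
        already carries every noise source of a sample (counting,
        library sampling, the control guide's own noise), so the MoM
        estimate absorbs them all; no separate control term is added to
        the Wald variance.  The trend is the DESeq-style parametric
        ``a0 / mean + a1`` fitted across guides.
        """
        R = nb.shape[1]
        if R < 2:
            return np.full(nb.shape[0], self.dispersion_floor)
        ests = []
        for mat in (nb, na):
            m = mat.mean(axis=1)
            v = mat.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                a = (v - m) / m**2
            a[~np.isfinite(a)] = np.nan
            ests.append(a)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            raw = np.nanmean(np.column_stack(ests), axis=1)

        ok = np.isfinite(raw) & (bmean > 0)
        if ok.sum() >= 10:
            # least squares of raw ~ a0 / mean + a1, clipped at zero
            hi = np.nanquantile(raw[ok], 0.99)
            y = np.clip(raw[ok], 0.0, hi)
            X = np.column_stack([1.0 / bmean[ok], np.ones(ok.sum())])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        else:
            a0, a1 = 0.0, float(np.nanmedian(raw)) if ok.any() else 0.0
        with np.errstate(divide="ignore"):
            trend = np.where(bmean > 0, a0 / np.maximum(bmean, 1e-12) + a1, a1)
        trend = np.maximum(trend, self.dispersion_floor)

        w = (R - 1) / (R - 1 + 4.0)  # few replicates -> lean on the trend
        shrunk = np.where(np.isfinite(raw), w * raw + (1 - w) * trend, trend)
        return np.maximum(shrunk, self.dispersion_floor)

    def _wald(self, nb, na, eb, ea, disp, log2fc, R) -> np.ndarray:
        n_guides = nb.shape[0]
        if R < 2:
            warnings.warn(
                "fewer than 2 replicates: dispersion not estimable, p set to 1",
                stacklevel=2,
            )
            return np.ones(n_guides)
        # delta-method variance of log2(after/before) per replicate; the
        # dispersion absorbs all super-Poisson noise incl. the control
        d = disp[:, None]
        var_r = (
            1.0 / (nb + eb[None, :]) + 1.0 / (na + ea[None, :]) + 2.0 * d
        ) / LOG2**2
        var = var_r.sum(axis=1) / R**2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / np.sqrt(var)
        p = 2.0 * sps.norm.sf(np.abs(z))
        p = np.where(np.isfinite(p), p, 1.0)
        all_zero = (nb.sum(axis=1) + na.sum(axis=1)) == 0
        p[all_zero] = 1.0
        return p


def guide_log2fc(
    counts: pd.DataFrame, design: ScreenDesign, pseudocount: float = 0.5
) -> pd.Series:
    """Mean over replicates of the paired log2 normalized-count ratio."""
    est = FoldChangeEstimator(pseudocount=pseudocount).fit(counts, design)
    return est.guide_stats_["log2FC"]


def nb_test(counts: pd.DataFrame, design: ScreenDesign, **kwargs) -> pd.DataFrame:
    """Per-guide two-sided Wald p-values and BH-adjusted p-values."""
    est = FoldChangeEstimator(**kwargs).fit(counts, design)
    return est.guide_stats_[["pvalue", "padj"]]
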