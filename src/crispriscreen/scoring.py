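"""Gene-level aggregation of guide statistics and screen-level calls.

A gene's depletion signal is the median log2FC of the guides that
hybridize to its coding strand (template-strand guides only weakly
repress and are summarized separately).  Candidate essential genes are
called below a strict median threshold; in a phage screen the same
median, computed on post-infection log2FC, is the gene's resistance
score (positive = silencing protects from lysis).  MAD values are
reported unscaled (no 1.4826 consistency factor), mirroring
median-absolute-deviation error bars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "GeneScorer",
    "score_genes",
    "call_essential",
    "roc_auc",
    "resistance_score",
    "select_resistant",
    "fisher_exact_2x2",
    "geneset_mannwhitney",
    "compare_screens",
]

ESSENTIAL_THRESHOLD = -2.0


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


class GeneScorer(BaseEstimator):
    """Aggregate per-guide log2FC to per-gene strand-wise medians.

    ``fit`` expects guide statistics (indexed by guide_id with a
    ``log2FC`` column) and an annotated library carrying ``guide_id``,
    ``gene`` and ``targets_coding``; multi-target and QC-failed guides
    are assumed to be already removed.

    Attributes
    ----------
    scores_ : pandas.DataFrame
        Indexed by gene with columns ``median_coding, mad_coding,
        median_template, mad_template, n_coding, n_template``.
    """

    def __init__(self, essential_threshold: float = ESSENTIAL_THRESHOLD):
        self.essential_threshold = essential_threshold

    def fit(self, guide_stats: pd.DataFrame, library: pd.DataFrame) -> "GeneScorer":
        lib = library[~library["is_control"].astype(bool)] if "is_control" in library else library
        lib = lib.dropna(subset=["gene"])
        merged = lib.merge(
            guide_stats["log2FC"], left_on="guide_id", right_index=True, how="inner"
        )
        rows = {}
        for (gene, coding), grp in merged.groupby(
            ["gene", merged["targets_coding"].astype(bool)]
        ):
            vals = grp["log2FC"].to_numpy(dtype=float)
            key = "coding" if coding else "template"
            row = rows.setdefault(gene, {})
            row[f"median_{key}"] = float(np.median(vals))
            row[f"mad_{key}"] = _mad(vals)
            row[f"n_{key}"] = len(vals)
        scores = pd.DataFrame.from_dict(rows, orient="index")
        for col in ("median_coding", "mad_coding", "median_template", "mad_template"):
            if col not in scores.columns:
                scores[col] = np.nan
        for col in ("n_coding", "n_template"):
            scores[col] = (
                scores[col].fillna(0).astype(int) if col in scores.columns else 0
            )
        scores.index.name = "gene"
        self.scores_ = scores.sort_index()
        return self

    def call(self) -> pd.Series:
        """Candidate-essential calls (strict median_coding < threshold)."""
        return call_essential(self.scores_, self.essential_threshold)


def score_genes(guide_stats: pd.DataFrame, library: pd.DataFrame) -> pd.DataFrame:
    """Per-gene strand-wise median and MAD of guide log2FC."""
    return GeneScorer().fit(guide_stats, library).scores_


def call_essential(
    scores: pd.DataFrame, threshold: float = ESSENTIAL_THRESHOLD
) -> pd.Series:
    """Strictly-below-threshold candidate essential calls.

    Genes without coding-strand guides (median undefined) are never
    called; ties at the threshold are not called.
    """
    med = scores["median_coding"]
    return (med < threshold) & med.notna()


def roc_auc(
    scores: pd.DataFrame, gold_labels: pd.Series
) -> tuple[pd.DataFrame, float]:
    """ROC of -median_coding against gold essentiality labels.

    AUC uses the rank (Mann-Whitney) formula with midrank tie
    correction.  Only genes with a defined coding median and a label are
    scored.  Returns the (FPR, TPR) curve points and the AUC.
    """
    df = pd.DataFrame({"score": -scores["median_coding"]}).dropna()
    labels = gold_labels.reindex(df.index).dropna().astype(bool)
    df = df.loc[labels.index]
    pos = df.loc[labels, "score"].to_numpy()
    neg = df.loc[~labels, "score"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative label")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (len(pos) * len(neg))
    fpr, tpr, _ = _sk_roc_curve(labels.to_numpy(), df["score"].to_numpy())
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return curve, auc


def resistance_score(
    phage_guide_stats: pd.DataFrame, library: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene resistance scores from a phage screen.

    The score is the median log2FC of the gene's coding-strand guides
    after infection; positive scores mean silencing protects from lysis.
    """
    scores = score_genes(phage_guide_stats, library)
    scores = scores.rename(
        columns={"median_coding": "resistance_score", "mad_coding": "mad"}
    )
    return scores[["resistance_score", "mad", "n_coding"]]


def select_resistant(
    scores: pd.DataFrame, fraction: float = 0.2, min_guides: int = 2
) -> set[str]:
    """Genes with >= ``min_guides`` coding guides scoring above
    ``fraction`` of the maximum resistance score."""
    s = scores["resistance_score"]
    if not (s > 0).any():
        warnings.warn("no positive resistance score; empty selection", stacklevel=2)
        return set()
    cutoff = fraction * float(s.max())
    keep = (scores["n_coding"] >= min_guides) & (s > cutoff)
    return set(scores.index[keep.fillna(False)])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Uses the minimum-likelihood two-sided rule; p-values far below
    double underflow territory (e.g. 1e-41) are returned exactly since
    hypergeometric tail masses are accumulated in log space internally.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def geneset_mannwhitney(
    guide_log2fc: pd.Series, member_guide_ids: set[str] | list[str]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of member guides' log2FC vs all others.

    Normal approximation with tie correction.
    """
    members = pd.Index(member_guide_ids)
    in_set = guide_log2fc.index.isin(members)
    if not in_set.any() or in_set.all():
        raise ValueError("member set must be a non-empty proper subset")
    x = guide_log2fc.to_numpy(dtype=float)[in_set]
    y = guide_log2fc.to_numpy(dtype=float)[~in_set]
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_screens(
    score_tables: dict[str, pd.Series],
    selections: dict[str, set[str]] | None = None,
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Pairwise Pearson correlations and Venn-style overlap counts.

    ``score_tables`` maps screen name -> per-gene score Series.
    Correlations are computed over genes scored in every table.  When
    ``selections`` (name -> selected gene set) is given, exclusive
    intersection counts are returned for every non-empty combination.
    """
    if len(score_tables) < 2:
        raise ValueError("need at least two score tables")
    df = pd.DataFrame(score_tables).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 genes shared across tables")
    corr = df.corr(method="pearson")

    venn: dict[frozenset, int] = {}
    if selections:
        names = sorted(selections)
        universe = set().union(*selections.values())
        for gene in universe:
            key = frozenset(n for n in names if gene in selections[n])
            venn[key] = venn.get(key, 0) + 1
    return corr, venn
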