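"""Figures and a markdown summary for a completed pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["make_report"]


def _rank_plot(scores: pd.DataFrame, threshold: float, path: Path) -> None:
    s = scores["median_coding"].dropna().sort_values()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(s)), s.to_numpy(), ".", ms=2)
    ax.axhline(threshold, ls="--", c="k", lw=0.8)
    ax.set_xlabel("gene rank")
    ax.set_ylabel("median coding-strand log2FC")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _roc_plot(curve: pd.DataFrame, auc: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve["fpr"], curve["tpr"])
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"essentiality prediction (AUC = {auc:.3f})")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _strand_scatter(scores: pd.DataFrame, path: Path) -> int:
    both = scores.dropna(subset=["median_coding", "median_template"])
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(both["median_coding"], both["median_template"], ".", ms=3)
    ax.set_xlabel("median coding-strand log2FC")
    ax.set_ylabel("median template-strand log2FC")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return len(both)


def _volcano(guide_stats: pd.DataFrame, padj_line: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        y = -np.log10(guide_stats["padj"].clip(lower=1e-300))
    ax.plot(guide_stats["log2FC"], y, ".", ms=2)
    ax.axhline(-np.log10(padj_line), ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2FC")
    ax.set_ylabel("-log10 adjusted p")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _estimate_fdr(results: pd.DataFrame, alpha: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        y = -np.log10(results["fdr"].clip(lower=1e-300))
    ax.plot(results["estimate"], y, ".", ms=3)
    ax.axhline(-np.log10(alpha), ls="--", c="k", lw=0.8)
    ax.set_xlabel("estimate (gene-indicator coefficient)")
    ax.set_ylabel("-log10 FDR")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_report(
    outdir: str | Path,
    gene_scores: pd.DataFrame | None = None,
    roc: tuple[pd.DataFrame, float] | None = None,
    phage_guide_stats: pd.DataFrame | None = None,
    transduction_results: pd.DataFrame | None = None,
    essential_threshold: float = -2.0,
    padj_line: float = 1e-3,
    fdr_alpha: float = 0.05,
) -> Path:
    """Write figures and ``report.md``; absent tables are noted, not fatal."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# CRISPRi screen report", ""]

    if gene_scores is not None and len(gene_scores):
        _rank_plot(gene_scores, essential_threshold, outdir / "rank_plot.png")
        n_called = int((gene_scores["median_coding"] < essential_threshold).sum())
        lines += [
            f"- genes scored: {len(gene_scores)}",
            f"- candidate essential (median coding log2FC < {essential_threshold}): "
            f"{n_called}",
            "- rank plot: rank_plot.png",
        ]
        n_scatter = _strand_scatter(gene_scores, outdir / "strand_scatter.png")
        lines.append(
            f"- coding-vs-template scatter ({n_scatter} genes with both medians): "
            "strand_scatter.png"
        )
    else:
        lines.append("- gene scores: absent")

    if roc is not None:
        curve, auc = roc
        _roc_plot(curve, auc, outdir / "roc.png")
        lines.append(f"- essentiality ROC AUC = {auc:.3f}: roc.png")

    if phage_guide_stats is not None and len(phage_guide_stats):
        _volcano(phage_guide_stats, padj_line, outdir / "phage_volcano.png")
        lines.append(f"- phage volcano (dashed line padj = {padj_line:g}): "
                     "phage_volcano.png")
    else:
        lines.append("- phage guide statistics: absent")

    if transduction_results is not None and len(transduction_results):
        _estimate_fdr(transduction_results, fdr_alpha, outdir / "transduction.png")
        n_hits = int(transduction_results["hit"].sum())
        lines.append(
            f"- transduction hits (FDR < {fdr_alpha:g}): {n_hits}: transduction.png"
        )
    else:
        lines.append("- transduction results: absent")

    report = outdir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
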