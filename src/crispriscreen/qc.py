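"""Guide exclusion rules: bad seeds, off-targets, multi-targets, read floors.

dCas9 is toxic when the sgRNA carries one of ten specific 5-nt
PAM-proximal seed sequences, and represses off-target loci with as
little as 9 nt of PAM-proximal identity.  Guides are therefore dropped
when they carry a bad seed, when their 9 PAM-proximal bases match next
to an NGG inside a gene's promoter window (100 nt upstream through
20 nt downstream of the start codon, either orientation), when their 11
PAM-proximal bases match next to an NGG in an orientation that lets the
sgRNA hybridize to a gene's coding strand, when they target multiple
perfect sites, or when their read support is too low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .genome import SPACER_LEN, Genome, find_protospacers, revcomp, spacer_midpoint
from .stats import ScreenDesign, size_factors

__all__ = ["BAD_SEEDS", "QCConfig", "QCReport", "GuideFilter", "has_bad_seed",
           "offtarget_flags", "count_filters", "apply_qc", "promoter_window"]

#: The ten strongest toxicity-causing 5-nt PAM-proximal seeds.
BAD_SEEDS = frozenset(
    ["AGGAA", "TAGGA", "ACCCA", "TTGGA", "TATAG",
     "GAGGC", "AAAGG", "GGGAT", "TAGAC", "GTCCT"]
)

FLAG_COLUMNS = ["bad_seed", "offtarget_promoter", "offtarget_coding",
                "multi_target", "low_reads", "low_base_mean"]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for the guide exclusion rules."""

    bad_seeds: frozenset[str] = BAD_SEEDS
    k_promoter: int = 9
    k_coding: int = 11
    promoter_window: tuple[int, int] = (100, 20)  # nt upstream, downstream of start
    min_total_reads: int = 20
    min_base_mean: float = 10.0
    drop_multi_target: bool = True

    def __post_init__(self) -> None:
        if any(len(s) != 5 for s in self.bad_seeds):
            raise ValueError("bad seeds must all be 5-mers")
        if not 1 <= self.k_promoter <= self.k_coding <= SPACER_LEN:
            raise ValueError("need 1 <= k_promoter <= k_coding <= 20")
        if min(self.promoter_window) < 0:
            raise ValueError("promoter window bounds must be >= 0")


@dataclass
class QCReport:
    """Per-guide flags plus exclusion counts per reason."""

    flags: pd.DataFrame  # boolean columns FLAG_COLUMNS + retained
    summary: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_flags(cls, flags: pd.DataFrame) -> "QCReport":
        summary = {c: int(flags[c].sum()) for c in FLAG_COLUMNS if c in flags}
        summary["retained"] = int(flags["retained"].sum())
        summary["total"] = len(flags)
        return cls(flags=flags, summary=summary)


def has_bad_seed(spacer: str, config: QCConfig = QCConfig()) -> bool:
    """True iff the 5 PAM-proximal nt of the spacer are a known bad seed."""
    return spacer[-5:] in config.bad_seeds


def promoter_window(left: int, right: int, strand: str,
                    upstream: int, downstream: int) -> tuple[int, int]:
    """Forward-axis half-open promoter interval measured on the gene strand.

    Covers ``[start-upstream, start+downstream)`` in transcription
    direction around the first base of the start codon.
    """
    if strand == "+":
        return left - upstream, left + downstream
    return right - downstream, right + upstream


class _SuffixIndex:
    """PAM-adjacent k-mer lookup built in one pass over the genome.

    For a circular genome every k-mer adjacent to an NGG is the suffix
    of an enumerated 20-nt protospacer window, so the index is derived
    from :func:`find_protospacers`.
    """

    def __init__(self, genome: Genome, ks: tuple[int, ...]):
        self.genome = genome
        sites = find_protospacers(genome)
        self._by_k: dict[int, dict[str, list[tuple[int, str]]]] = {}
        starts = sites["start"].to_numpy()
        strands = sites["strand"].to_numpy()
        spacers = sites["spacer"].to_numpy()
        for k in ks:
            d: dict[str, list[tuple[int, str]]] = {}
            for start, strand, spc in zip(starts, strands, spacers):
                d.setdefault(spc[-k:], []).append((int(start), strand))
            self._by_k[k] = d
        if not genome.circular:
            self._add_linear_edges(ks)

    def _add_linear_edges(self, ks: tuple[int, ...]) -> None:
        # k-mer+PAM sites near the ends of a linear genome whose full
        # 20-nt window runs off the edge are not protospacer sites but
        # are still k-mer matches
        seq = self.genome.sequence
        L = len(seq)
        for k in ks:
            d = self._by_k[k]
            for p in range(-(SPACER_LEN - k), 0):  # window start before origin
                q = p + SPACER_LEN - k
                if q + k + 2 < L and seq[q : q + k] and len(seq[q : q + k]) == k \
                        and seq[q + k + 1 : q + k + 3] == "GG":
                    d.setdefault(seq[q : q + k], []).append((p, "+"))
            rc = revcomp(seq)
            for p in range(-(SPACER_LEN - k), 0):
                q = p + SPACER_LEN - k
                if q + k + 2 < L and len(rc[q : q + k]) == k \
                        and rc[q + k + 1 : q + k + 3] == "GG":
                    d.setdefault(rc[q : q + k], []).append((L - (p + SPACER_LEN), "-"))

    def lookup(self, spacer: str, k: int) -> list[tuple[int, str]]:
        return self._by_k[k].get(spacer[-k:], [])


def _interval_contains(mid: int, lo: int, hi: int, L: int, circular: bool) -> bool:
    if circular:
        lo_m, hi_m = lo % L, hi % L
        if lo_m < hi_m:
            return lo_m <= mid < hi_m
        return mid >= lo_m or mid < hi_m  # wraps the origin
    return lo <= mid < hi


def offtarget_flags(
    guide: pd.Series | dict,
    genome: Genome,
    genes: pd.DataFrame,
    config: QCConfig = QCConfig(),
    index: _SuffixIndex | None = None,
) -> tuple[bool, bool]:
    """Off-target flags for one guide (needs ``spacer``, ``start``, ``strand``).

    ``offtarget_promoter``: a k_promoter-suffix match (excluding the
    on-target site) whose spacer midpoint falls in any gene's promoter
    window, in either match orientation.  ``offtarget_coding``: a
    k_coding-suffix match inside a gene body in the orientation that
    hybridizes the sgRNA to that gene's coding strand.
    """
    if index is None:
        index = _SuffixIndex(genome, (config.k_promoter, config.k_coding))
    L = len(genome)
    own = (int(guide["start"]), guide["strand"])
    up, down = config.promoter_window
    windows = [
        promoter_window(g.left, g.right, g.strand, up, down)
        for g in genes.itertuples()
    ]

    flag_prom = False
    for start, strand in index.lookup(guide["spacer"], config.k_promoter):
        if (start, strand) == own:
            continue
        mid = spacer_midpoint(start, L, genome.circular)
        if any(_interval_contains(mid, lo, hi, L, genome.circular) for lo, hi in windows):
            flag_prom = True
            break

    flag_cod = False
    for start, strand in index.lookup(guide["spacer"], config.k_coding):
        if (start, strand) == own:
            continue
        mid = spacer_midpoint(start, L, genome.circular)
        for g in genes.itertuples():
            # sgRNA hybridizes to the coding strand iff the off-target
            # protospacer lies on the template strand
            if g.left <= mid < g.right and strand != g.strand:
                flag_cod = True
                break
        if flag_cod:
            break
    return flag_prom, flag_cod


def count_filters(
    counts: pd.DataFrame,
    config: QCConfig = QCConfig(),
    mode: str = "growth",
    design: ScreenDesign | None = None,
) -> pd.DataFrame:
    """Read-support flags: ``low_reads`` (growth) and ``low_base_mean`` (phage).

    Growth mode flags guides whose summed raw reads over all samples
    fall below ``min_total_reads``; phage mode additionally flags guides
    whose baseMean (mean size-factor-normalized count) falls below
    ``min_base_mean``.
    """
    if mode not in ("growth", "phage"):
        raise ValueError(f"mode must be 'growth' or 'phage', got {mode!r}")
    if counts.empty:
        raise ValueError("count matrix is empty")
    low_reads = counts.sum(axis=1) < config.min_total_reads
    out = pd.DataFrame({"low_reads": low_reads})
    if mode == "phage":
        if design is None:
            raise ValueError("phage mode needs the screen design for baseMean")
        sf = size_factors(counts, design)
        bmean = counts.astype(float).div(sf, axis=1).mean(axis=1)
        out["low_base_mean"] = bmean < config.min_base_mean
    else:
        out["low_base_mean"] = False
    return out


class GuideFilter(BaseEstimator):
    """sklearn-style transformer applying all guide exclusion rules.

    ``fit`` computes per-guide flags from the library, genome, gene
    table and count matrix; ``transform`` returns the retained library.
    The non-targeting control guide is always retained.
    """

    def __init__(self, config: QCConfig = QCConfig(), mode: str = "growth"):
        self.config = config
        self.mode = mode

    def fit(
        self,
        library: pd.DataFrame,
        genome: Genome | None = None,
        genes: pd.DataFrame | None = None,
        counts: pd.DataFrame | None = None,
        design: ScreenDesign | None = None,
    ) -> "GuideFilter":
        cfg = self.config
        if "is_control" not in library.columns or not library["is_control"].any():
            raise ValueError(
                "control guide absent from library; downstream normalization "
                "is impossible"
            )
        lib = library.set_index("guide_id", drop=False)
        flags = pd.DataFrame(False, index=lib.index, columns=FLAG_COLUMNS)

        flags["bad_seed"] = lib["spacer"].str[-5:].isin(cfg.bad_seeds)

        if genome is not None and genes is not None:
            index = _SuffixIndex(genome, (cfg.k_promoter, cfg.k_coding))
            prom, cod = [], []
            for _, g in lib.iterrows():
                if g["is_control"] or pd.isna(g["start"]):
                    prom.append(False)
                    cod.append(False)
                else:
                    fp, fc = offtarget_flags(g, genome, genes, cfg, index)
                    prom.append(fp)
                    cod.append(fc)
            flags["offtarget_promoter"] = prom
            flags["offtarget_coding"] = cod

        if cfg.drop_multi_target and "n_perfect_sites" in lib.columns:
            flags["multi_target"] = lib["n_perfect_sites"].fillna(0).astype(int) > 1

        if counts is not None:
            cf = count_filters(counts, cfg, self.mode, design)
            flags["low_reads"] = cf["low_reads"].reindex(flags.index, fill_value=True)
            flags["low_base_mean"] = cf["low_base_mean"].reindex(
                flags.index, fill_value=True
            )

        flags.loc[lib["is_control"], FLAG_COLUMNS] = False  # control always kept
        flags["retained"] = ~flags[FLAG_COLUMNS].any(axis=1)
        self.flags_ = flags
        self.report_ = QCReport.from_flags(flags)
        return self

    def transform(self, library: pd.DataFrame) -> pd.DataFrame:
        retained = self.flags_.index[self.flags_["retained"]]
        return library[library["guide_id"].isin(retained)].reset_index(drop=True)

    def fit_transform(self, library: pd.DataFrame, **fit_params) -> pd.DataFrame:
        return self.fit(library, **fit_params).transform(library)


def apply_qc(
    library: pd.DataFrame,
    genome: Genome | None = None,
    genes: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
    config: QCConfig = QCConfig(),
    mode: str = "growth",
    design: ScreenDesign | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply every enabled exclusion rule; returns (retained library, report)."""
    flt = GuideFilter(config=config, mode=mode).fit(
        library, genome=genome, genes=genes, counts=counts, design=design
    )
    return flt.transform(library), flt.report_
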