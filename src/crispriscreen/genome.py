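"""Genome, gene and guide data model plus protospacer sequence primitives.

Coordinates are 0-based half-open on the forward strand throughout the
package; user-facing tables written by :mod:`crispriscreen.io` convert to
1-based inclusive (GFF-style) coordinates.

A protospacer *site* is reported as the forward-axis start of its 20-nt
window together with the strand carrying the spacer sequence.  For a
``+`` site the NGG PAM occupies ``[start+20, start+23)``; for a ``-``
site the spacer is the reverse complement of the window and the PAM
occupies ``[start-3, start)`` on the forward axis (``CCN`` in forward
letters).  Bacterial chromosomes are circular by default and windows may
wrap across the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "Gene",
    "TranscriptionUnit",
    "CONTROL_SPACER",
    "revcomp",
    "find_protospacers",
    "match_pam_proximal",
    "count_perfect_sites",
    "annotate_guide",
    "annotate_library",
    "spacer_midpoint",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Non-targeting control guide spacer carried by the library.
CONTROL_SPACER = "TGAGACCAGTCTAGGTCTCG"

SPACER_LEN = 20
PAM_LEN = 3


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str) -> None:
    if set(seq) - set("ACGT"):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(
            f"genome sequence contains non-ACGT characters: {bad}; "
            "ambiguity codes are not supported"
        )


@dataclass(frozen=True)
class Genome:
    """A bacterial replicon.

    Parameters
    ----------
    identifier : str
        Sequence name (e.g. an accession).
    sequence : str
        Uppercase DNA over the strict {A, C, G, T} alphabet.
    circular : bool, default True
        Whether protospacer windows may wrap across the origin.
    """

    identifier: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if len(self.sequence) <= SPACER_LEN + PAM_LEN:
            raise ValueError(
                f"genome must be longer than {SPACER_LEN + PAM_LEN} nt, "
                f"got {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """A gene interval on the forward axis; ``strand`` is the coding strand."""

    name: str
    left: int
    right: int
    strand: str
    essential: bool | None = None
    tu_id: str | None = None
    tu_rank: int | None = None

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError(f"gene {self.name}: left must be < right")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")


@dataclass(frozen=True)
class TranscriptionUnit:
    """An operon: genes ordered 5'->3' in transcription direction."""

    tu_id: str
    gene_names: tuple[str, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_names:
            raise ValueError(f"TU {self.tu_id} has no genes")
        if self.strand not in "+-":
            raise ValueError(f"TU {self.tu_id}: strand must be '+' or '-'")


@dataclass
class Guide:
    """One sgRNA with its genomic site and gene context."""

    guide_id: str
    spacer: str
    protospacer_strand: str | None = None
    start: int | None = None
    target_gene: str | None = None
    targets_coding: bool | None = None
    n_perfect_sites: int = 0
    is_control: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(
                f"guide {self.guide_id}: spacer must be {SPACER_LEN} nt"
            )

    @property
    def seed5(self) -> str:
        """The 5 PAM-proximal nucleotides of the spacer (5'->3')."""
        return self.spacer[-5:]


def _char_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def find_protospacers(genome: Genome) -> pd.DataFrame:
    """Enumerate all 20-nt protospacers adjacent to an NGG PAM.

    Both strands are scanned; circular genomes wrap across the origin.

    Returns
    -------
    pandas.DataFrame
        Columns ``start`` (forward-axis window start), ``strand``,
        ``spacer`` (5'->3' on the protospacer strand) and ``pam``,
        sorted by (start, strand).
    """
    seq = genome.sequence
    L = len(seq)
    arr = _char_array(seq)
    is_g = arr == b"G"
    is_c = arr == b"C"

    # forward site at p: GG at (p+21, p+22); reverse site at p: CC at (p-3, p-2)
    plus = np.roll(is_g, -21) & np.roll(is_g, -22)
    minus = np.roll(is_c, 3) & np.roll(is_c, 2)
    if not genome.circular:
        pos = np.arange(L)
        plus &= pos <= L - (SPACER_LEN + PAM_LEN)
        minus &= (pos >= PAM_LEN) & (pos <= L - SPACER_LEN)

    seq2 = seq + seq  # wrap-safe slicing
    records: list[tuple[int, str, str, str]] = []
    for p in np.flatnonzero(plus):
        p = int(p)
        records.append(
            (p, "+", seq2[p : p + SPACER_LEN],
             seq2[p + SPACER_LEN : p + SPACER_LEN + PAM_LEN])
        )
    for p in np.flatnonzero(minus):
        p = int(p)
        window = seq2[p : p + SPACER_LEN]
        pam_fwd = seq2[(p - PAM_LEN) % L : (p - PAM_LEN) % L + PAM_LEN]
        records.append((p, "-", revcomp(window), revcomp(pam_fwd)))
    df = pd.DataFrame(records, columns=["start", "strand", "spacer", "pam"])
    return df.sort_values(["start", "strand"], ignore_index=True)


def match_pam_proximal(spacer: str, k: int, genome: Genome) -> pd.DataFrame:
    """All sites where the ``k`` PAM-proximal spacer bases match next to NGG.

    The match is exact over the 3'-terminal ``k`` nt of the spacer.  The
    guide's own on-target site is included; callers exclude it when
    looking for off-targets.  Sites whose full 20-nt window would run off
    the end of a linear genome are still reported (``start`` may then be
    negative or extend past the end); on circular genomes ``start`` is
    always reported modulo the genome length.

    Returns a DataFrame with columns ``start`` and ``strand``.
    """
    if not 1 <= k <= SPACER_LEN:
        raise ValueError(f"k must be in [1, {SPACER_LEN}], got {k}")
    if len(spacer) != SPACER_LEN:
        raise ValueError("spacer must be 20 nt")
    suffix = spacer[-k:]
    L = len(genome)
    sites: list[tuple[int, str]] = []

    def _scan(hay: str, limit: int, strand: str) -> None:
        # hay is forward seq (strand '+') or reverse complement ('-');
        # occurrence q means suffix occupies [q, q+k), PAM GG at (q+k+1, q+k+2)
        q = hay.find(suffix)
        while q != -1 and q < limit:
            if q + k + 2 < len(hay) and hay[q + k + 1] == "G" and hay[q + k + 2] == "G":
                p = q + k - SPACER_LEN  # start of the 20-nt window in hay coords
                if strand == "+":
                    start = p % L if genome.circular else p
                else:
                    start = (L - (p + SPACER_LEN)) % L if genome.circular else L - (p + SPACER_LEN)
                sites.append((start, strand))
            q = hay.find(suffix, q + 1)

    if genome.circular:
        fwd = genome.sequence + genome.sequence[: k + PAM_LEN - 1]
        rev = revcomp(genome.sequence)
        rev = rev + rev[: k + PAM_LEN - 1]
        _scan(fwd, L, "+")
        _scan(rev, L, "-")
    else:
        _scan(genome.sequence, L, "+")
        _scan(revcomp(genome.sequence), L, "-")
    df = pd.DataFrame(sites, columns=["start", "strand"])
    return df.sort_values(["start", "strand"], ignore_index=True)


def count_perfect_sites(spacer: str, genome: Genome) -> int:
    """Number of genomic positions (both strands) where the full 20-nt
    spacer matches exactly with NGG immediately 3'."""
    return len(match_pam_proximal(spacer, SPACER_LEN, genome))


def spacer_midpoint(start: int, genome_length: int, circular: bool = True) -> int:
    """Representative midpoint position of a 20-nt spacer window."""
    mid = start + SPACER_LEN // 2
    return mid % genome_length if circular else mid


def annotate_guide(
    start: int,
    protospacer_strand: str,
    genes: pd.DataFrame,
    genome_length: int,
    circular: bool = True,
) -> tuple[str | None, bool | None]:
    """Assign a guide site to a gene and derive its strand semantics.

    The target gene is the gene whose ``[left, right)`` interval contains
    the spacer midpoint; overlaps are resolved by smallest ``left`` then
    name order.  ``targets_coding`` is True iff the sgRNA hybridizes to
    the gene's sense (coding) strand, i.e. the protospacer lies on the
    template strand: ``protospacer_strand != gene strand``.

    Returns ``(None, None)`` for intergenic sites.
    """
    mid = spacer_midpoint(start, genome_length, circular)
    hits = genes[(genes["left"] <= mid) & (mid < genes["right"])]
    if hits.empty:
        return None, None
    hit = hits.sort_values(["left", "name"]).iloc[0]
    return hit["name"], protospacer_strand != hit["strand"]


def annotate_library(
    library: pd.DataFrame, genes: pd.DataFrame, genome: Genome
) -> pd.DataFrame:
    """Vectorised :func:`annotate_guide` over a guide table.

    ``library`` needs columns ``start`` and ``strand``; returns a copy
    with ``gene`` and ``targets_coding`` columns filled (control or
    intergenic guides get missing values).
    """
    lib = library.copy()
    L = len(genome)
    genes_sorted = genes.sort_values(["left", "name"], ignore_index=True)
    lefts = genes_sorted["left"].to_numpy()
    rights = genes_sorted["right"].to_numpy()
    names = genes_sorted["name"].to_numpy()
    strands = genes_sorted["strand"].to_numpy()

    out_gene: list[str | None] = []
    out_coding: list[bool | None] = []
    for start, strand in zip(lib["start"], lib["strand"]):
        if pd.isna(start):
            out_gene.append(None)
            out_coding.append(None)
            continue
        mid = spacer_midpoint(int(start), L, genome.circular)
        # first interval containing mid in (left, name) order
        idx = np.flatnonzero((lefts <= mid) & (mid < rights))
        if idx.size == 0:
            out_gene.append(None)
            out_coding.append(None)
        else:
            i = idx[0]
            out_gene.append(names[i])
            out_coding.append(strand != strands[i])
    lib["gene"] = out_gene
    lib["targets_coding"] = pd.array(out_coding, dtype="boolean")
    return lib
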