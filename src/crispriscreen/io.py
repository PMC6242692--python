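"""Readers and writers for the package's file formats.

Genomes travel as FASTA (via Biopython), gene and transcription-unit
annotations as tab-separated tables, guide libraries as CSV mirroring a
deposited-library layout (``guide_id, spacer, position, ori, coding,
gene, gene_left, gene_right, gene_ori, essential``), and count matrices
as TSV with one column per sample.  Genomic coordinates are 1-based
inclusive in files and converted to the package's internal 0-based
half-open convention on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Genome

__all__ = [
    "read_genome_fasta",
    "write_genome_fasta",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_tus_tsv",
    "write_tus_tsv",
    "read_library_csv",
    "write_library_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_design_tsv",
    "write_design_tsv",
]

GENE_COLUMNS = ["name", "left", "right", "strand", "essential", "tu_id", "tu_rank"]
TU_COLUMNS = ["tu_id", "gene", "rank", "strand"]


def read_genome_fasta(path: str | Path, circular: bool = True) -> Genome:
    """Read the first record of a FASTA file as a :class:`Genome`."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return Genome(record.id, str(record.seq).upper(), circular=circular)


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.identifier, description="")
    SeqIO.write([record], str(path), "fasta")


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    """Gene table with 1-based inclusive file coordinates -> internal 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"name", "left", "right", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df = df.copy()
    df["left"] = df["left"].astype(int) - 1  # 1-based incl -> 0-based half-open
    df["right"] = df["right"].astype(int)
    for col in ("essential", "tu_id", "tu_rank"):
        if col not in df.columns:
            df[col] = pd.NA
    return df[GENE_COLUMNS + [c for c in df.columns if c not in GENE_COLUMNS]]


def write_genes_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["left"] = out["left"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_tus_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(TU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TU table missing columns: {sorted(missing)}")
    return df


def write_tus_tsv(tus: pd.DataFrame, path: str | Path) -> None:
    tus.to_csv(path, sep="\t", index=False)


def write_library_csv(library: pd.DataFrame, genes: pd.DataFrame | None, path: str | Path) -> None:
    """Write a guide library in the deposited-table layout (1-based positions)."""
    out = pd.DataFrame(
        {
            "guide_id": library["guide_id"],
            "spacer": library["spacer"],
            "position": library["start"].astype("Int64") + 1,
            "ori": library["strand"],
            "coding": library["targets_coding"],
            "gene": library["gene"],
        }
    )
    if genes is not None:
        gmap = genes.set_index("name")
        out["gene_left"] = library["gene"].map(gmap["left"]).astype("Int64") + 1
        out["gene_right"] = library["gene"].map(gmap["right"]).astype("Int64")
        out["gene_ori"] = library["gene"].map(gmap["strand"])
        if "essential" in gmap.columns:
            out["essential"] = library["gene"].map(gmap["essential"])
    if "is_control" in library.columns:
        out["is_control"] = library["is_control"]
    if "n_perfect_sites" in library.columns:
        out["n_perfect_sites"] = library["n_perfect_sites"]
    out.to_csv(path, index=False)


def read_library_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    lib = pd.DataFrame(
        {
            "guide_id": df["guide_id"],
            "spacer": df["spacer"],
            "start": df["position"].astype("Int64") - 1,
            "strand": df["ori"],
            "targets_coding": df.get("coding"),
            "gene": df.get("gene"),
        }
    )
    if "targets_coding" in lib.columns:
        lib["targets_coding"] = lib["targets_coding"].astype("boolean")
    lib["is_control"] = (
        df["is_control"].astype(bool) if "is_control" in df.columns else False
    )
    if "n_perfect_sites" in df.columns:
        lib["n_perfect_sites"] = df["n_perfect_sites"]
    return lib


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Counts TSV: first column guide_id, one integer column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError("count matrix is empty")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="guide_id")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"sample_id", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)
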