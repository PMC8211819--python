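"""Readers/writers for the small set of on-disk formats the pipeline uses.

FASTA goes through Biopython; BED6 and TSV tables through pandas. All
coordinates on disk are BED-style 0-based half-open.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS, comment="#")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def genes_to_bed6(genes: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a gene table; exon_count is carried in the score column."""
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int),
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
            "score": genes["exon_count"].astype(int),
            "strand": genes["strand"],
        }
    )


def bed6_to_genes(bed: pd.DataFrame, biotype: str = "protein_coding") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
            "exon_count": bed["score"].astype(int),
            "biotype": biotype,
        }
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
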