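"""Per-gene RLFS density metrics and sequence features.

Genes are analysed on *flanked windows*: 2 kb added upstream of the
transcription start and downstream of the termination site to include
promoter and terminator regions, clamped to contig bounds. Two density
metrics are reported per gene:

* ``rlfs_per_kb`` — merged RLFS intervals overlapping the window by >=1 bp,
  divided by the window length in kb. An interval partially overlapping
  the window counts fully (it is an event count).
* ``pct_coverage`` — percent of window bases covered by merged RLFS
  (clipped to the window; a length measure).

By default the density denominator is the flanked window length, matching
a workflow that adds flanks before quantification; pass
``include_flanks_in_denominator=False`` to divide by the unflanked gene
length instead.

Sequence features (computed on the unflanked gene body): GC percent and
the count of canonical G-quadruplex motifs ``G{3,}(N{1,7}G{3,}){3,}`` on
both strands (non-overlapping matches per strand).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .rlfs import MergedRlfsSet, revcomp

G4_PATTERN = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3,}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int = 1
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")

    @classmethod
    def from_row(cls, row) -> "GeneModel":
        return cls(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            exon_count=int(row.get("exon_count", 1)),
            biotype=row.get("biotype", "protein_coding"),
        )


@dataclass(frozen=True)
class GeneRlfsMetrics:
    gene_id: str
    window_length_bp: int
    rlfs_count: int
    rlfs_per_kb: float
    pct_coverage: float
    gc_pct: float
    g4_count: int
    gene_length_bp: int
    exon_count: int


def flank_window(gene, flank: int = 2000,
                 chrom_length: int | None = None) -> tuple[int, int, bool]:
    """Flanked analysis window ``[max(0, start-flank), min(L, end+flank))``.

    Returns (start, end, truncated) where ``truncated`` records clamping
    at either contig edge.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = int(gene.start) - flank
    end = int(gene.end) + flank
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_length is not None and end > chrom_length:
        end, truncated = chrom_length, True
    return start, end, truncated


def rlfs_density(gene, merged: MergedRlfsSet, flank: int = 2000,
                 chrom_length: int | None = None, strand: str | None = None,
                 include_flanks_in_denominator: bool = True,
                 sequence: str | None = None) -> GeneRlfsMetrics:
    """Density metrics for one gene against a merged RLFS set.

    ``strand`` selects the merged view: pass ``gene.strand`` for
    co-transcriptional analysis (the usual case), or ``None`` for the
    strand-collapsed view. Sequence features are zeroed unless ``sequence``
    (the chromosome sequence) is supplied.
    """
    w_start, w_end, _ = flank_window(gene, flank, chrom_length)
    window_len = w_end - w_start
    denom_len = window_len if include_flanks_in_denominator else (gene.end - gene.start)
    count = merged.count_overlapping(gene.chrom, w_start, w_end, strand)
    covered = merged.covered_bp(gene.chrom, w_start, w_end, strand)
    gc, g4 = (0.0, 0)
    if sequence is not None:
        _, _, gc, g4 = gene_features(gene, sequence)
    return GeneRlfsMetrics(
        gene_id=gene.gene_id,
        window_length_bp=window_len,
        rlfs_count=count,
        rlfs_per_kb=count / (denom_len / 1000.0),
        pct_coverage=100.0 * covered / window_len,
        gc_pct=gc,
        g4_count=g4,
        gene_length_bp=gene.end - gene.start,
        exon_count=gene.exon_count,
    )


def gene_features(gene, sequence: str) -> tuple[int, int, float, int]:
    """(gene_length_bp, exon_count, gc_pct, g4_count) on the gene body."""
    if len(sequence) < gene.end:
        raise ValueError(
            f"sequence ({len(sequence)} bp) shorter than gene span of {gene.gene_id}"
        )
    body = sequence[gene.start : gene.end].upper()
    acgt = sum(body.count(b) for b in "ACGT")
    gc = 100.0 * (body.count("G") + body.count("C")) / acgt if acgt else 0.0
    g4 = len(G4_PATTERN.findall(body)) + len(G4_PATTERN.findall(revcomp(body)))
    return gene.end - gene.start, gene.exon_count, gc, g4


def compute_gene_metrics(genes: pd.DataFrame, merged: MergedRlfsSet,
                         sequences: dict[str, str] | None = None,
                         flank: int = 2000, co_transcriptional: bool = True,
                         include_flanks_in_denominator: bool = True) -> pd.DataFrame:
    """Metrics table (one row per gene) for a gene table.

    With ``co_transcriptional=True`` each gene is scored against the merged
    view of its own strand only.
    """
    chrom_lengths = {c: len(s) for c, s in sequences.items()} if sequences else {}
    rows = []
    for _, row in genes.iterrows():
        gene = GeneModel.from_row(row)
        if sequences is not None and gene.chrom not in sequences:
            raise KeyError(f"unknown chromosome {gene.chrom!r} for gene {gene.gene_id}")
        m = rlfs_density(
            gene,
            merged,
            flank=flank,
            chrom_length=chrom_lengths.get(gene.chrom),
            strand=gene.strand if co_transcriptional else None,
            include_flanks_in_denominator=include_flanks_in_denominator,
            sequence=sequences.get(gene.chrom) if sequences else None,
        )
        rows.append(m.__dict__)
    out = pd.DataFrame(rows)
    if "biotype" in genes.columns:
        out["biotype"] = genes["biotype"].values
    return out
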