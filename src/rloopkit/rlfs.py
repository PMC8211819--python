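"""Prediction and merging of R-loop forming sequences (RLFS).

An RLFS is modelled as an R-loop initiation zone (RIZ) — a cluster of
guanine tracts — followed, after a short linker, by an R-loop elongation
zone (REZ) of sustained G-richness on the same strand. The concrete model
here is a desk-scale reimplementation of the published RIZ/linker/REZ
structure of quantitative RLFS predictors; every threshold is a field of
:class:`RlfsModel` so users can match other parameterisations.

Default model
-------------
* RIZ: >=3 G-tracts of >=3 consecutive G, adjacent tracts separated by
  <=10 nt. Tract clusters are maximal, hence disjoint.
* RIZ->REZ linker: the REZ may start up to 50 nt downstream of the RIZ end
  (the first workable start is taken, scanning left to right).
* REZ: the longest window of 50..2000 nt with overall G fraction >=0.40
  and, once the window reaches 100 nt, every 100-nt sub-window also at
  G fraction >=0.40 (sustained richness, not a single G spike).
* ``N`` bases break G-tracts and terminate REZ growth (conservative).

Minus-strand hits are found by scanning the reverse complement and mapping
coordinates back, so strand symmetry holds by construction. All
coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_VALID = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class RlfsModel:
    """Tunable thresholds of the RIZ/linker/REZ scanner."""

    min_g_tract: int = 3
    min_tracts: int = 3
    max_tract_gap: int = 10
    max_riz_rez_gap: int = 50
    min_rez_length: int = 50
    max_rez_length: int = 2000
    rez_g_min: float = 0.4
    rez_window: int = 100


DEFAULT_MODEL = RlfsModel()


@dataclass(frozen=True)
class RlfsHit:
    """One predicted RLFS: the full span plus its RIZ/REZ sub-spans.

    ``riz_span`` precedes ``rez_span`` in the direction of transcription;
    for minus-strand hits the RIZ therefore has the *larger* genomic
    coordinates.
    """

    chrom: str
    start: int
    end: int
    strand: str
    riz_span: tuple[int, int]
    rez_span: tuple[int, int]
    g_tract_count: int
    rez_g_fraction: float


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def _g_tract_clusters(seq: str, model: RlfsModel) -> list[list[tuple[int, int]]]:
    """Maximal clusters of G-tracts with inter-tract gaps <= max_tract_gap."""
    runs = [(m.start(), m.end()) for m in re.finditer(f"G{{{model.min_g_tract},}}", seq)]
    clusters: list[list[tuple[int, int]]] = []
    for run in runs:
        if clusters and run[0] - clusters[-1][-1][1] <= model.max_tract_gap:
            clusters[-1].append(run)
        else:
            clusters.append([run])
    return [c for c in clusters if len(c) >= model.min_tracts]


def _grow_rez(gprefix: np.ndarray, n_stop: np.ndarray, start: int, seq_len: int,
              model: RlfsModel) -> tuple[int, int, float] | None:
    """Longest REZ window starting at ``start``; None if < min_rez_length.

    ``gprefix``/``n_stop`` are prefix counts of G and N over the whole
    sequence, shared across calls for O(1) window sums.
    """
    if start >= seq_len:
        return None
    cap = min(seq_len, start + model.max_rez_length)
    # N terminates growth: truncate at the first N at/after start.
    n_here = n_stop[start]
    hi = cap
    if n_stop[cap] > n_here:  # an N occurs in [start, cap)
        lo, h = start, cap
        while lo < h:
            mid = (lo + h) // 2
            if n_stop[mid + 1] > n_here:
                h = mid
            else:
                lo = mid + 1
        hi = lo
    avail = hi - start
    if avail < model.min_rez_length:
        return None
    w = model.rez_window
    need = model.rez_g_min

    def gcount(a: int, b: int) -> int:
        return int(gprefix[b] - gprefix[a])

    if avail >= w:
        # first failing 100-nt sub-window caps the usable length at f + w - 1
        win = gprefix[start + w : start + avail + 1] - gprefix[start : start + avail - w + 1]
        fails = win < need * w
        length = int(np.argmax(fails)) + w - 1 if fails.any() else avail
    else:
        length = avail
    # shrink until the overall fraction clears the threshold too
    while length >= model.min_rez_length and gcount(start, start + length) < need * length:
        length -= 1
    if length < model.min_rez_length:
        return None
    frac = gcount(start, start + length) / length
    return start, start + length, frac


def _scan_plus(seq: str, chrom: str, model: RlfsModel) -> list[RlfsHit]:
    seq_len = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gprefix = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    n_stop = np.concatenate([[0], np.cumsum(arr == ord("N"))])
    hits = []
    for cluster in _g_tract_clusters(seq, model):
        riz = (cluster[0][0], cluster[-1][1])
        for gap in range(model.max_riz_rez_gap + 1):
            rez = _grow_rez(gprefix, n_stop, riz[1] + gap, seq_len, model)
            if rez is not None:
                hits.append(
                    RlfsHit(
                        chrom=chrom,
                        start=riz[0],
                        end=rez[1],
                        strand="+",
                        riz_span=riz,
                        rez_span=(rez[0], rez[1]),
                        g_tract_count=len(cluster),
                        rez_g_fraction=rez[2],
                    )
                )
                break
    return hits


def _mirror_hit(hit: RlfsHit, seq_len: int, strand: str) -> RlfsHit:
    flip = lambda span: (seq_len - span[1], seq_len - span[0])  # noqa: E731
    s, e = flip((hit.start, hit.end))
    return RlfsHit(
        chrom=hit.chrom,
        start=s,
        end=e,
        strand=strand,
        riz_span=flip(hit.riz_span),
        rez_span=flip(hit.rez_span),
        g_tract_count=hit.g_tract_count,
        rez_g_fraction=hit.rez_g_fraction,
    )


def find_rlfs(seq: str, strand: str = "+", chrom: str = "seq",
              model: RlfsModel = DEFAULT_MODEL) -> list[RlfsHit]:
    """Predict RLFS on one strand of ``seq``.

    Parameters
    ----------
    seq
        Nucleotide sequence over ``ACGTN`` (case-insensitive). ``N`` never
        matches. An empty sequence yields an empty result.
    strand
        ``'+'`` scans the sequence as given; ``'-'`` scans its reverse
        complement and maps hit coordinates back to the forward frame.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = _validate_sequence(seq)
    if not seq:
        return []
    if strand == "+":
        return _scan_plus(seq, chrom, model)
    plus = _scan_plus(revcomp(seq), chrom, model)
    mirrored = [_mirror_hit(h, len(seq), "-") for h in plus]
    return sorted(mirrored, key=lambda h: h.start)


def find_rlfs_chunked(seq: str, strand: str = "+", chrom: str = "seq",
                      model: RlfsModel = DEFAULT_MODEL, chunk_size: int = 1_000_000,
                      pad: int | None = None) -> list[RlfsHit]:
    """Chunked scan, identical to :func:`find_rlfs` on the whole sequence.

    Each chunk is scanned with ``pad`` nt of flanking context; only hits
    whose start lies in the chunk core are kept. ``pad`` defaults to the
    maximum possible hit span under ``model`` plus cluster slack.
    """
    seq = _validate_sequence(seq)
    if pad is None:
        pad = model.max_rez_length + model.max_riz_rez_gap + 5000
    if len(seq) <= chunk_size:
        return find_rlfs(seq, strand, chrom, model)
    hits: list[RlfsHit] = []
    for core_start in range(0, len(seq), chunk_size):
        core_end = min(len(seq), core_start + chunk_size)
        lo = max(0, core_start - pad)
        hi = min(len(seq), core_end + pad)
        offset = lo
        for h in find_rlfs(seq[lo:hi], strand, chrom, model):
            start = h.start + offset
            if core_start <= start < core_end:
                shift = lambda span: (span[0] + offset, span[1] + offset)  # noqa: E731
                hits.append(
                    replace(h, start=start, end=h.end + offset,
                            riz_span=shift(h.riz_span), rez_span=shift(h.rez_span))
                )
    return sorted(hits, key=lambda h: (h.start, h.end))


def hits_to_frame(hits: list[RlfsHit]) -> pd.DataFrame:
    """BED6-compatible table; score = round(1000 * rez_g_fraction)."""
    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [f"RLFS_{h.chrom}_{h.start}_{h.strand}" for h in hits],
            "score": [round(1000 * h.rez_g_fraction) for h in hits],
            "strand": [h.strand for h in hits],
        }
    )


def merge_intervals(starts, ends, min_overlap: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals that share at least ``min_overlap`` bp.

    Touching half-open intervals ([0,10) and [10,20)) share zero bases and
    are NOT merged under the default. Raises on empty or negative-length
    input intervals.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("empty or negative-length interval in input")
    order = np.lexsort((ends, starts))
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if out_e[-1] - s >= min_overlap:  # overlap of at least min_overlap bp
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


class MergedRlfsSet:
    """Sorted, disjoint merged RLFS intervals with per-strand and
    strand-collapsed views, supporting overlap counting and coverage."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._views: dict[tuple[str, str | None], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_hits(cls, hits, min_overlap: int = 1) -> "MergedRlfsSet":
        """Build from RlfsHit objects or a BED-like frame (chrom/start/end/strand)."""
        if isinstance(hits, pd.DataFrame):
            df = hits[["chrom", "start", "end", "strand"]].copy()
        else:
            df = pd.DataFrame(
                {
                    "chrom": [h.chrom for h in hits],
                    "start": [h.start for h in hits],
                    "end": [h.end for h in hits],
                    "strand": [h.strand for h in hits],
                }
            )
        rows = []
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
            s, e = merge_intervals(grp["start"].values, grp["end"].values, min_overlap)
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "strand": strand}))
        merged = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        )
        return cls(merged.sort_values(["chrom", "start"], kind="mergesort"))

    def view(self, chrom: str, strand: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome; strand=None collapses strands
        (re-merging across strands under the same >=1 bp overlap rule)."""
        key = (chrom, strand)
        if key not in self._views:
            sel = self.frame["chrom"] == chrom
            if strand is not None:
                sel &= self.frame["strand"] == strand
            sub = self.frame.loc[sel]
            if strand is None and len(sub):
                s, e = merge_intervals(sub["start"].values, sub["end"].values)
            else:
                s = sub["start"].values.astype(np.int64)
                e = sub["end"].values.astype(np.int64)
            self._views[key] = (s, e)
        return self._views[key]

    def count_overlapping(self, chrom: str, start: int, end: int,
                          strand: str | None = None) -> int:
        """Number of merged intervals sharing >=1 bp with [start, end)."""
        s, e = self.view(chrom, strand)
        if s.size == 0:
            return 0
        hi = np.searchsorted(s, end, side="left")
        lo = np.searchsorted(e, start, side="right")
        return int(hi - lo)

    def covered_bp(self, chrom: str, start: int, end: int,
                   strand: str | None = None) -> int:
        """Bases of [start, end) covered by merged intervals (clipped)."""
        s, e = self.view(chrom, strand)
        if s.size == 0:
            return 0
        hi = np.searchsorted(s, end, side="left")
        lo = np.searchsorted(e, start, side="right")
        if hi <= lo:
            return 0
        cs = np.clip(s[lo:hi], start, end)
        ce = np.clip(e[lo:hi], start, end)
        return int(np.sum(ce - cs))

    def total_covered_bp(self, chrom: str, strand: str | None = None) -> int:
        s, e = self.view(chrom, strand)
        return int(np.sum(e - s))


def merge_hits(hits, min_overlap: int = 1) -> MergedRlfsSet:
    """Merge predicted hits into a :class:`MergedRlfsSet` (union of the
    input coverage is preserved exactly; merging is per chromosome and
    strand)."""
    return MergedRlfsSet.from_hits(hits, min_overlap=min_overlap)


def co_transcriptional_filter(hits: list[RlfsHit], gene, flank: int = 2000,
                              chrom_length: int | None = None) -> list[RlfsHit]:
    """Keep hits whose strand matches the gene's transcribed strand and
    which overlap the gene's flanked window by >=1 bp.

    ``gene`` needs ``chrom``, ``start``, ``end`` and ``strand`` attributes
    (a :class:`rloopkit.metrics.GeneModel` or any namespace/row).
    """
    strand = getattr(gene, "strand", None)
    if strand not in ("+", "-"):
        raise ValueError(f"gene {getattr(gene, 'gene_id', '?')} has no usable strand")
    w_start = max(0, int(gene.start) - flank)
    w_end = int(gene.end) + flank
    if chrom_length is not None:
        w_end = min(chrom_length, w_end)
    return [
        h
        for h in hits
        if h.strand == strand
        and h.chrom == gene.chrom
        and h.start < w_end
        and h.end > w_start
    ]


def scan_genome(sequences: dict[str, str], model: RlfsModel = DEFAULT_MODEL,
                chunk_size: int = 5_000_000) -> list[RlfsHit]:
    """Scan every sequence on both strands."""
    hits: list[RlfsHit] = []
    for chrom, seq in sequences.items():
        for strand in "+-":
            hits.extend(find_rlfs_chunked(seq, strand, chrom, model, chunk_size))
    return hits
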