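"""RLFS scanner, interval merging and the co-transcriptional filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from oracles import (
    bitmap,
    naive_plus_hits,
    naive_riz_clusters,
)
from rloopkit import rlfs
from rloopkit.metrics import GeneModel

RIZ_EXAMPLE = "GGGAGGGAGGG"  # three G3 tracts, 1-nt linkers


class TestFindRlfs:
    def test_poly_a_has_no_hits(self):
        assert rlfs.find_rlfs("A" * 10_000) == []

    def test_empty_sequence_is_empty_not_error(self):
        assert rlfs.find_rlfs("") == []

    def test_non_iupac_character_raises(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            rlfs.find_rlfs("ACGTX")

    def test_bad_strand_raises(self):
        with pytest.raises(ValueError, match="strand"):
            rlfs.find_rlfs("ACGT", strand="*")

    def test_riz_plus_gc_rich_tail_yields_one_hit(self):
        # a 50% G tail of 50 nt is a valid elongation zone
        seq = RIZ_EXAMPLE + "T" + "GT" * 25
        hits = rlfs.find_rlfs(seq)
        assert len(hits) == 1
        (hit,) = hits
        assert hit.strand == "+"
        assert hit.riz_span == (0, len(RIZ_EXAMPLE))
        assert hit.g_tract_count == 3
        assert hit.rez_g_fraction >= 0.4
        # independent naive scanner agrees
        assert naive_plus_hits(seq) == [(0, len(RIZ_EXAMPLE))]

    def test_two_tracts_are_not_enough(self):
        seq = "GGGAGGG" + "T" + "GT" * 25
        assert rlfs.find_rlfs(seq) == []

    def test_riz_without_elongation_zone_is_rejected(self):
        seq = RIZ_EXAMPLE + "AT" * 200
        assert rlfs.find_rlfs(seq) == []
        assert naive_plus_hits(seq) == []

    def test_n_breaks_tracts_and_windows(self):
        assert rlfs.find_rlfs("N" * 500) == []
        # N immediately after the RIZ truncates every candidate REZ start
        seq = RIZ_EXAMPLE + "N" * 60 + "GT" * 25
        assert rlfs.find_rlfs(seq) == []

    def test_hits_satisfy_model_invariants(self, rng):
        seq = random_sequence(rng, 20_000, p_g=0.4)
        for hit in rlfs.find_rlfs(seq):
            assert hit.start < hit.end <= len(seq)
            assert hit.riz_span[0] == hit.start and hit.rez_span[1] == hit.end
            assert hit.riz_span[1] <= hit.rez_span[0]
            assert hit.rez_g_fraction >= rlfs.DEFAULT_MODEL.rez_g_min
            assert hit.g_tract_count >= rlfs.DEFAULT_MODEL.min_tracts

    def test_minus_strand_mirrors_plus_scan_of_revcomp(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, 2000, p_g=0.4)
            minus = rlfs.find_rlfs(seq, "-")
            plus_of_rc = rlfs.find_rlfs(rlfs.revcomp(seq), "+")
            L = len(seq)
            mirrored = sorted(
                (L - h.end, L - h.start) for h in plus_of_rc
            )
            assert [(h.start, h.end) for h in minus] == mirrored
            assert all(h.strand == "-" for h in minus)

    def test_planted_cassette_found_on_both_strands(self, rng):
        cassette = RIZ_EXAMPLE + "ACT" * 5 + "G" * 2 + ("GGT" + "GAT") * 50
        background = random_sequence(rng, 3000, p_g=0.25)
        pos = 1200
        seq = background[:pos] + cassette + background[pos:]
        plus_hits = rlfs.find_rlfs(seq, "+")
        assert any(h.start <= pos < h.end or pos <= h.start < pos + 20 for h in plus_hits)
        rc = rlfs.revcomp(seq)
        minus_hits = rlfs.find_rlfs(rc, "-")
        target = (len(rc) - (pos + len(cassette)), len(rc) - pos)
        assert any(h.end > target[0] and h.start < target[1] for h in minus_hits)

    def test_chunked_scan_matches_whole_sequence(self, rng):
        seq = random_sequence(rng, 30_000, p_g=0.42)
        whole = rlfs.find_rlfs(seq)
        chunked = rlfs.find_rlfs_chunked(seq, chunk_size=4000)
        assert [(h.start, h.end, h.riz_span) for h in whole] == [
            (h.start, h.end, h.riz_span) for h in chunked
        ]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_riz_clusters_match_naive_oracle(self, seed):
        seq = random_sequence(np.random.default_rng(seed), 1500, p_g=0.45)
        ours = [
            (c[0][0], c[-1][1], len(c))
            for c in rlfs._g_tract_clusters(seq, rlfs.DEFAULT_MODEL)
        ]
        assert ours == naive_riz_clusters(seq)


class TestMerge:
    def test_empty_input(self):
        merged = rlfs.merge_hits([])
        assert len(merged.frame) == 0
        assert merged.count_overlapping("chr1", 0, 100) == 0

    def test_touching_intervals_not_merged_overlapping_are(self):
        s, e = rlfs.merge_intervals([0, 10], [10, 20])
        assert list(s) == [0, 10] and list(e) == [10, 20]
        s, e = rlfs.merge_intervals([0, 9], [10, 20])
        assert list(s) == [0] and list(e) == [20]

    def test_min_overlap_two_requires_two_shared_bases(self):
        s, e = rlfs.merge_intervals([0, 9], [10, 20], min_overlap=2)
        assert list(s) == [0, 9]
        s, e = rlfs.merge_intervals([0, 8], [10, 20], min_overlap=2)
        assert list(s) == [0] and list(e) == [20]

    def test_negative_or_empty_interval_raises(self):
        with pytest.raises(ValueError):
            rlfs.merge_intervals([5], [5])
        with pytest.raises(ValueError):
            rlfs.merge_intervals([5], [3])

    def test_random_intervals_match_bitmap_union(self, rng):
        length = 5000
        starts = rng.integers(0, length - 50, 500)
        ends = starts + rng.integers(1, 50, 500)
        s, e = rlfs.merge_intervals(starts, ends)
        # output is sorted, disjoint, and covers exactly the union bitmap
        assert np.all(s[1:] >= e[:-1])
        assert np.array_equal(
            bitmap(zip(s, e), length), bitmap(zip(starts, ends), length)
        )

    def test_coverage_conservation(self, rng):
        starts = rng.integers(0, 9000, 300)
        ends = starts + rng.integers(1, 400, 300)
        s, e = rlfs.merge_intervals(starts, ends)
        assert int((e - s).sum()) == int(bitmap(zip(starts, ends), 10_000).sum())


class TestCoTranscriptionalFilter:
    def _hit(self, start, end, strand, chrom="chr1"):
        return rlfs.RlfsHit(chrom, start, end, strand, (start, start + 9),
                            (start + 9, end), 3, 0.5)

    def test_opposite_strand_hits_all_removed(self):
        gene = GeneModel("g", "chr1", 1000, 2000, "-")
        hits = [self._hit(900, 1500, "+"), self._hit(1200, 1800, "+")]
        assert rlfs.co_transcriptional_filter(hits, gene) == []

    def test_mixed_strands_keep_matching_and_window_overlap(self):
        gene = GeneModel("g", "chr1", 10_000, 12_000, "+")
        keep = self._hit(8500, 9000, "+")        # inside the 2 kb flank
        wrong_strand = self._hit(10_500, 11_000, "-")
        far_away = self._hit(100, 400, "+")
        out = rlfs.co_transcriptional_filter([keep, wrong_strand, far_away], gene)
        assert out == [keep]

    def test_strandless_gene_raises(self):
        class Dummy:
            chrom, start, end, strand, gene_id = "chr1", 0, 10, ".", "g"

        with pytest.raises(ValueError, match="strand"):
            rlfs.co_transcriptional_filter([], Dummy())

    def test_filter_then_merge_equals_merge_of_matching_subset(self, rng):
        gene = GeneModel("g", "chr1", 3000, 6000, "+")
        hits = [
            self._hit(int(s), int(s) + int(l), "+" if rng.random() < 0.5 else "-")
            for s, l in zip(rng.integers(0, 9000, 100), rng.integers(60, 600, 100))
        ]
        filtered = rlfs.co_transcriptional_filter(hits, gene, chrom_length=10_000)
        a = rlfs.merge_hits(filtered).view("chr1", "+")
        subset = [h for h in hits if h.strand == "+" and h.start < 8000 and h.end > 1000]
        b = rlfs.merge_hits(subset).view("chr1", "+")
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestMergedSetQueries:
    def test_count_and_coverage_against_naive(self, rng):
        intervals = []
        starts = rng.integers(0, 9500, 120)
        ends = starts + rng.integers(1, 500, 120)
        import pandas as pd

        frame = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": ends, "strand": "+"}
        )
        merged = rlfs.MergedRlfsSet.from_hits(frame)
        ms, me = merged.view("chr1", "+")
        mask = bitmap(zip(ms, me), 10_000)
        for _ in range(50):
            w0 = int(rng.integers(0, 9000))
            w1 = w0 + int(rng.integers(100, 1000))
            assert merged.covered_bp("chr1", w0, w1, "+") == int(mask[w0:w1].sum())
            naive = sum(1 for s, e in zip(ms, me) if s < w1 and e > w0)
            assert merged.count_overlapping("chr1", w0, w1, "+") == naive
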