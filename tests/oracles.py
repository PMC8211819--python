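"""Independent brute-force oracles used by the tests.

Deliberately naive (per-base loops, bitmaps, exhaustive enumeration) and
written without reference to the library implementations they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

# --- naive RLFS scanner ---------------------------------------------------

MIN_TRACT = 3
MIN_TRACTS = 3
MAX_GAP = 10
MAX_LINKER = 50
MIN_REZ = 50
MAX_REZ = 2000
REZ_G_MIN = 0.4
REZ_WINDOW = 100


def naive_g_runs(seq: str) -> list[tuple[int, int]]:
    runs, i = [], 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= MIN_TRACT:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def naive_riz_clusters(seq: str) -> list[tuple[int, int, int]]:
    """(start, end, n_tracts) of maximal G-tract clusters with >= MIN_TRACTS."""
    clusters: list[list[tuple[int, int]]] = []
    for run in naive_g_runs(seq):
        if clusters and run[0] - clusters[-1][-1][1] <= MAX_GAP:
            clusters[-1].append(run)
        else:
            clusters.append([run])
    return [
        (c[0][0], c[-1][1], len(c)) for c in clusters if len(c) >= MIN_TRACTS
    ]


def naive_rez_ok(seq: str, start: int) -> bool:
    """Is there a valid REZ window starting exactly at ``start``?"""
    region = seq[start : start + MAX_REZ]
    if "N" in region:
        region = region[: region.index("N")]
    for length in range(len(region), MIN_REZ - 1, -1):
        window = region[:length]
        if window.count("G") / length < REZ_G_MIN:
            continue
        if length >= REZ_WINDOW:
            ok = all(
                window[f : f + REZ_WINDOW].count("G") / REZ_WINDOW >= REZ_G_MIN
                for f in range(0, length - REZ_WINDOW + 1)
            )
            if not ok:
                continue
        return True
    return False


def naive_plus_hits(seq: str) -> list[tuple[int, int]]:
    """RIZ spans (start, end) of plus-strand hits found naively."""
    hits = []
    for riz_start, riz_end, _n in naive_riz_clusters(seq):
        if any(naive_rez_ok(seq, riz_end + d) for d in range(MAX_LINKER + 1)):
            hits.append((riz_start, riz_end))
    return hits


# --- bitmap interval oracle ----------------------------------------------


def bitmap(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def bitmap_covered_in(intervals, w_start: int, w_end: int, length: int) -> int:
    return int(bitmap(intervals, length)[w_start:w_end].sum())


def count_overlapping_naive(intervals, w_start: int, w_end: int) -> int:
    return sum(1 for s, e in intervals if s < w_end and e > w_start)


# --- rank-product enumeration oracle --------------------------------------


def enumerate_rank_product_pfp(observed_log_rp: np.ndarray, k: int) -> np.ndarray:
    """pfp under exhaustive enumeration of all rank matrices (k independent
    permutations of 1..n per comparison); feasible only for tiny n."""
    n = observed_log_rp.size
    perms = list(permutations(range(1, n + 1)))
    pools = []
    if k != 2:
        raise NotImplementedError("oracle written for k=2")
    for p1 in perms:
        for p2 in perms:
            pools.append((np.log(p1) + np.log(p2)) / 2)
    null = np.sort(np.concatenate(pools))
    n_matrices = len(perms) ** 2
    expected = (
        np.searchsorted(null, observed_log_rp + 1e-12, side="right") / n_matrices
    )
    order = observed_log_rp.argsort(kind="stable")
    ranks = np.empty(n)
    # average ranks for ties, matching the implementation's tie rule
    sorted_vals = observed_log_rp[order]
    i = 0
    while i < n:
        j = i
        while j < n and np.isclose(sorted_vals[j], sorted_vals[i]):
            j += 1
        ranks[order[i:j]] = (i + 1 + j) / 2
        i = j
    return expected / ranks


# --- naive Spearman -------------------------------------------------------


def naive_spearman_rho(x, y) -> float:
    def rank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            r[order[i:j]] = (i + 1 + j) / 2
            i = j
        return r

    rx, ry = rank(x), rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
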