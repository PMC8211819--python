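"""Rank-product differential expression with permutation-based pfp, plus
FPKM normalisation for reporting.

The rank product of gene *g* over *k* pairwise between-group comparisons
is the geometric mean of its fold-change ranks, ``RP_g = (prod r_gc)^(1/k)``
— rank 1 being the strongest change in the direction under test (up or
down). Significance is the pfp (proportion of false predictions): with
``c_g`` the number of null rank products at or below ``RP_g`` pooled over
``n_permutations`` permutations, ``E_g = c_g / n_permutations`` estimates
the expected number of genes scoring that well by chance and
``pfp_g = E_g / rank(RP_g)``.

Two permutation nulls are available:

* ``null_method='rank-shuffle'`` (default): independent uniform rank
  assignments per comparison — the classic rank-product null. It is exact
  when the comparisons are independent, which holds in ``mode='paired'``
  (disjoint replicate pairs). In ``mode='all-pairs'`` the comparisons
  reuse samples, their fold-change ranks are positively correlated, and
  this null *overstates* significance: treat all-pairs pfp as a ranking
  score, or use the paired mode when a calibrated pfp matters.
* ``null_method='sample-permutation'``: group labels permuted over the
  pooled samples, rank products recomputed on group-mean-centred log
  expression (permutation of residuals). Honest to the between-comparison
  correlation (top-gene pfp roughly calibrated even in all-pairs mode)
  but conservative when a large fraction of genes is truly differential,
  because the permuted data lets null genes occupy the top ranks that the
  differential genes hold in the observed ranking.

Notes on conventions (all surfaced as arguments):

* A pseudocount (default 0.5 at the pipeline level) should be added
  upstream; ``rank_product`` requires strictly positive expression.
* Ties in fold change receive average ranks.
* Contrasts default to all replicate pairs between the two groups
  (``mode='all-pairs'``); ``mode='paired'`` pairs replicates positionally.
* Rank products run on counts (plus pseudocount) by default; FPKM is for
  reporting. Because ranking is within-sample, gene length cancels from
  between-sample fold changes only when lengths are constant — the caller
  chooses the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def fpkm(counts: pd.DataFrame, gene_length_bp: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm[g, s] = counts[g, s] / ((length_g / 1e3) * (total_s / 1e6))``.
    """
    lengths = gene_length_bp.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("gene_length_bp missing for some genes in the count matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total samples: {bad}")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


@dataclass
class DEResult:
    table: pd.DataFrame  # rank_product_up/down, pfp_up/down, mean_log2fc
    group_a: str
    group_b: str
    n_comparisons: int
    n_permutations: int
    seed: int | None = None
    pfp_cutoff: float = 0.05
    up_set: list[str] = field(default_factory=list)
    down_set: list[str] = field(default_factory=list)


def _comparison_columns(design: pd.Series, group_a: str, group_b: str,
                        mode: str) -> list[tuple[str, str]]:
    a_cols = list(design.index[design == group_a])
    b_cols = list(design.index[design == group_b])
    if not a_cols:
        raise ValueError(f"group {group_a!r} absent from design")
    if not b_cols:
        raise ValueError(f"group {group_b!r} absent from design")
    if mode == "all-pairs":
        return list(product(a_cols, b_cols))
    if mode == "paired":
        if len(a_cols) != len(b_cols):
            raise ValueError("paired mode needs equal replicate counts")
        return list(zip(a_cols, b_cols))
    raise ValueError("mode must be 'all-pairs' or 'paired'")


def _log_rp_from_values(log_vals: np.ndarray, a_idx: np.ndarray,
                        b_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log RP_up, log RP_down) from log-expression and comparison index
    pairs; ties in fold change get average ranks."""
    fc = log_vals[:, b_idx] - log_vals[:, a_idx]
    ranks_up = rankdata(-fc, axis=0)
    ranks_down = rankdata(fc, axis=0)
    return np.log(ranks_up).mean(axis=1), np.log(ranks_down).mean(axis=1)


def _null_rank_shuffle(n_genes: int, k: int, n_permutations: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Pooled log rank products under independent random rank assignment."""
    logs = np.zeros((n_permutations, n_genes))
    log_ranks = np.log(np.arange(1, n_genes + 1, dtype=float))
    base = np.tile(np.arange(n_genes), (n_permutations, 1))
    for _ in range(k):
        idx = rng.permuted(base, axis=1)
        logs += log_ranks[idx]
    return (logs / k).ravel()


def _null_sample_permutation(log_vals: np.ndarray, a_cols: np.ndarray,
                             b_cols: np.ndarray, mode: str,
                             n_permutations: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Pooled log rank products with group labels permuted over samples.

    Permutes group-mean-centred values (residuals) so genuinely
    differential genes do not contaminate the null."""
    centred = log_vals.copy()
    centred[:, a_cols] -= log_vals[:, a_cols].mean(axis=1, keepdims=True)
    centred[:, b_cols] -= log_vals[:, b_cols].mean(axis=1, keepdims=True)
    n_a = a_cols.size
    n_samples = log_vals.shape[1]
    parts = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_samples)
        pa, pb = perm[:n_a], perm[n_a:]
        if mode == "all-pairs":
            a_idx = np.repeat(pa, pb.size)
            b_idx = np.tile(pb, pa.size)
        else:
            a_idx, b_idx = pa, pb
        up, _ = _log_rp_from_values(centred, a_idx, b_idx)
        parts.append(up)
    return np.concatenate(parts)


def rank_product(expr: pd.DataFrame, design: pd.Series, group_a: str, group_b: str,
                 n_permutations: int = 100, rng: np.random.Generator | None = None,
                 mode: str = "all-pairs", pfp_cutoff: float = 0.05,
                 null_method: str = "rank-shuffle",
                 seed: int | None = None) -> DEResult:
    """Rank-product test of ``group_b`` relative to ``group_a``.

    "Up" means higher in ``group_b``. ``expr`` must be strictly positive
    (apply a pseudocount first); ``design`` maps sample name -> group.
    """
    design = pd.Series(design)
    if (expr.values <= 0).any():
        raise ValueError("expression must be strictly positive; add a pseudocount")
    pairs = _comparison_columns(design, group_a, group_b, mode)
    k = len(pairs)
    n_genes = expr.shape[0]
    # canonical column order makes the permutation null invariant to an
    # A/B label swap, so swapping groups swaps up/down results exactly
    cols = sorted({c for p in pairs for c in p})
    col_pos = {c: i for i, c in enumerate(cols)}
    log_vals = np.log2(expr[cols].values)
    a_idx = np.array([col_pos[a] for a, _ in pairs])
    b_idx = np.array([col_pos[b] for _, b in pairs])
    log_rp_up, log_rp_down = _log_rp_from_values(log_vals, a_idx, b_idx)
    log2fc = log_vals[:, b_idx] - log_vals[:, a_idx]

    if rng is None:
        rng = np.random.default_rng(seed)
    if null_method == "sample-permutation":
        a_cols = np.unique(a_idx)
        b_cols = np.unique(b_idx)
        null = _null_sample_permutation(log_vals, a_cols, b_cols, mode,
                                        n_permutations, rng)
    elif null_method == "rank-shuffle":
        null = _null_rank_shuffle(n_genes, k, n_permutations, rng)
    else:
        raise ValueError("null_method must be 'sample-permutation' or 'rank-shuffle'")
    null = np.sort(null)

    def pfp(log_rp: np.ndarray) -> np.ndarray:
        c = np.searchsorted(null, log_rp, side="right")
        expected = c / n_permutations
        obs_rank = rankdata(log_rp, method="average")
        return expected / obs_rank

    table = pd.DataFrame(
        {
            "rank_product_up": np.exp(log_rp_up),
            "rank_product_down": np.exp(log_rp_down),
            "pfp_up": pfp(log_rp_up),
            "pfp_down": pfp(log_rp_down),
            "mean_log2fc": log2fc.mean(axis=1),
        },
        index=expr.index,
    )
    result = DEResult(
        table=table,
        group_a=group_a,
        group_b=group_b,
        n_comparisons=k,
        n_permutations=n_permutations,
        seed=seed,
        pfp_cutoff=pfp_cutoff,
    )
    result.up_set, result.down_set = extract_gene_sets(result, pfp_cutoff)
    return result


def extract_gene_sets(result: DEResult, pfp_cutoff: float) -> tuple[list[str], list[str]]:
    """Disjoint up/down gene id lists at a pfp cutoff.

    A gene passing the cutoff in both directions (possible at permissive
    cutoffs) is assigned to the direction with the smaller rank product
    (ties go up). Deterministic given the result.
    """
    t = result.table
    up_ok = t["pfp_up"] < pfp_cutoff
    down_ok = t["pfp_down"] < pfp_cutoff
    both = up_ok & down_ok
    up_wins = t["rank_product_up"] <= t["rank_product_down"]
    up = t.index[(up_ok & ~both) | (both & up_wins)]
    down = t.index[(down_ok & ~both) | (both & ~up_wins)]
    return list(up), list(down)
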