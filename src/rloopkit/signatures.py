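"""Metagene signature scoring of cohort expression tables.

Workflow: rescale each gene so its median across samples equals 1, score
each sample by the median rescaled expression of a gene panel (a metagene
score), and correlate the score with a query gene's expression by
Spearman's rho with a two-tailed p-value.

The p-value uses the t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``
with n-2 degrees of freedom for n > 9 and exact enumeration over all rank
permutations for n <= 9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene ids must be unique")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GenePanel":
        with open(path) as fh:
            genes = tuple(line.strip() for line in fh if line.strip())
        return cls(name or str(path), genes)


@dataclass
class SignatureResult:
    spearman_rho: float
    p_two_tailed: float
    n_samples: int
    method: str  # "exact" or "t-approx"
    scores: pd.Series | None = None

    def summary(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "p_two_tailed": self.p_two_tailed,
            "n_samples": self.n_samples,
            "method": self.method,
        }


def median_rescale(expr: pd.DataFrame) -> pd.DataFrame:
    """Rescale each gene (row) so its median across samples is exactly 1.

    Genes whose median is not positive cannot be rescaled and are dropped
    with a warning.
    """
    med = expr.median(axis=1)
    bad = med <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} gene(s) with non-positive median: "
            f"{list(expr.index[bad])[:10]}",
            stacklevel=2,
        )
        expr = expr.loc[~bad]
        med = med[~bad]
    return expr.div(med, axis=0)


def panel_score(rescaled: pd.DataFrame, panel: GenePanel) -> pd.Series:
    """Per-sample metagene score: median of the panel genes' rescaled
    expression. Missing panel members are reported with a warning."""
    present = [g for g in panel.genes if g in rescaled.index]
    missing = [g for g in panel.genes if g not in rescaled.index]
    if not present:
        raise KeyError(f"no panel gene of {panel.name!r} present in the table")
    if missing:
        warnings.warn(f"panel {panel.name!r}: missing genes {missing}", stacklevel=2)
    return rescaled.loc[present].median(axis=0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-tailed exact p by enumerating all n! orderings of one margin."""
    n = rx.size
    perms = np.array(list(permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc**2).sum()) * np.sqrt((pc**2).sum(axis=1))
    rhos = (pc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate(query_values, scores) -> SignatureResult:
    """Spearman correlation between a query gene and per-sample scores."""
    x = np.asarray(query_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValueError("query and scores must be paired (equal length)")
    n = x.size
    if n < 5:
        raise ValueError(f"need >= 5 paired samples, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman's rho is undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        method = "t-approx"
    return SignatureResult(spearman_rho=rho, p_two_tailed=float(p), n_samples=n,
                           method=method)


def signature_correlation(expr: pd.DataFrame, panel: GenePanel,
                          query_gene: str) -> SignatureResult:
    """End-to-end: median-rescale, score the panel, correlate with the
    query gene's rescaled expression."""
    if query_gene not in expr.index:
        raise KeyError(f"query gene {query_gene!r} not in expression table")
    rescaled = median_rescale(expr)
    scores = panel_score(rescaled, panel)
    result = correlate(rescaled.loc[query_gene].values, scores.values)
    result.scores = scores
    return result
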