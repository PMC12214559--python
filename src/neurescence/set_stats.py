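"""Exact set-overlap statistics.

Upper-tail hypergeometric tests (gene-set enrichment, overlap of DE gene
lists, cell-type enrichment of senescent cells) and the exact multi-set
intersection test under independent uniform placement of each set in a
common universe.  Everything is computed in log space with log-gamma
accumulation, so p-values far below floating-point underflow are still
reported as log10(p).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "TailProb",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_pathways",
    "multiset_intersection_test",
]


class TailProb(NamedTuple):
    """An upper-tail probability with its log10, robust to underflow."""

    p: float
    log10p: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.p


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_logpmf(k, K, n, N):
    """log P(X = k) for X ~ Hypergeometric(N, K, n); vectorised over k."""
    return _log_choose(K, k) + _log_choose(N - K, n - k) - _log_choose(N, n)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> TailProb:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of "successes" in the universe,
    n the number drawn, and k the observed overlap.  Accumulated with
    log-gamma terms; ``log10p`` stays meaningful below 1e-300.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent parameters k={k}, K={K}, n={n}, N={N}")
    lo = max(k, 0)
    hi = min(K, n)
    if lo <= max(0, n + K - N):
        return TailProb(1.0, 0.0)
    support = np.arange(lo, hi + 1)
    logp = logsumexp(_hypergeom_logpmf(support, K, n, N))
    return TailProb(float(np.exp(logp)), float(logp / np.log(10.0)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(
    query_genes: Sequence[str],
    pathways: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each pathway in a query list.

    Each pathway is intersected with the universe before testing; the
    query must be a subset of the universe.  Rows are BH-adjusted across
    all tested pathways and flagged significant at padj < ``alpha``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = [g for g in dict.fromkeys(query_genes)]
    outside = [g for g in query if g not in universe_set]
    if outside:
        raise ValueError(f"query genes outside the universe: {outside[:5]}")
    N, n = len(universe_set), len(query)
    qset = set(query)

    rows = []
    for name in pathways:
        members = [g for g in pathways[name] if g in universe_set]
        overlap_genes = [g for g in members if g in qset]
        res = hypergeom_upper_tail(len(overlap_genes), len(members), n, N)
        rows.append(
            {
                "pathway": name,
                "set_size": len(members),
                "overlap": len(overlap_genes),
                "p": res.p,
                "log10p": res.log10p,
                "overlapping_genes": ",".join(overlap_genes),
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["padj"] < alpha
    return table[
        ["pathway", "set_size", "overlap", "p", "padj", "log10p", "significant",
         "overlapping_genes"]
    ]


class MultiSetResult(NamedTuple):
    expected: float
    p: float
    log10p: float
    observed: int


def multiset_intersection_test(
    sets: Sequence[Iterable[str]],
    N: int,
    universe: Iterable[str] | None = None,
) -> MultiSetResult:
    """Exact test for the size of the intersection of k >= 2 sets.

    Under the null, each set is placed uniformly at random in a universe
    of size ``N`` (sizes fixed).  The running-intersection size is then a
    Markov chain whose transitions are hypergeometric: given the current
    intersection has size j, intersecting with a fresh random set of
    size m leaves Hypergeometric(N, j, m) elements.  Convolving these
    conditional laws yields the exact distribution of the k-fold
    intersection; the returned p is P(intersection >= observed).  For
    k = 2 this reduces to the plain upper-tail hypergeometric test.
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if universe is not None:
        uni = set(universe)
        if len(uni) != N:
            raise ValueError("universe size does not match N")
        for i, s in enumerate(sets):
            if not s <= uni:
                raise ValueError(f"set {i} is not contained in the universe")
    sizes = [len(s) for s in sets]
    if any(m > N for m in sizes):
        raise ValueError("a set is larger than the universe")

    observed = len(set.intersection(*sets))
    expected = N * float(np.prod([m / N for m in sizes]))

    # log-space distribution of the running intersection size
    logdist = np.full(sizes[0] + 1, -np.inf)
    logdist[sizes[0]] = 0.0
    for m in sizes[1:]:
        hi = min(len(logdist) - 1, m)
        new = np.full(hi + 1, -np.inf)
        j_support = np.flatnonzero(np.isfinite(logdist))
        for i in range(hi + 1):
            js = j_support[j_support >= i]
            if js.size == 0:
                continue
            valid = js[(m - i) <= (N - js)]  # need N-j >= m-i draws outside
            if valid.size == 0:
                continue
            terms = logdist[valid] + _hypergeom_logpmf(i, valid, m, N)
            new[i] = logsumexp(terms)
        logdist = new

    if observed >= len(logdist):
        logp = -np.inf
    else:
        logp = logsumexp(logdist[observed:])
    logp = min(logp, 0.0)
    return MultiSetResult(
        expected=expected,
        p=float(np.exp(logp)),
        log10p=float(logp / np.log(10.0)),
        observed=observed,
    )
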