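"""Dual differential-expression testing for senescent vs non-senescent cells.

Two independent tests are run on log2-CPM expression of filtered genes
and their significant sets intersected:

* a two-part (hurdle) likelihood-ratio test that jointly models the
  detection rate (binomial G-test) and the positive-expression mean
  (Gaussian LRT on detected cells), summing statistics and degrees of
  freedom;
* a nonparametric Earth Mover's Distance test comparing the two groups'
  binned expression distributions, with a permutation p-value.

Both use Benjamini–Hochberg adjustment; defaults declare a gene DE at
padj < 0.01 with |log2FC| > 6 (hurdle) or EMD > 30 (EMD test).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .io_formats import CountMatrix
from .set_stats import TailProb, bh_adjust, hypergeom_upper_tail

logger = logging.getLogger("neurescence")

__all__ = [
    "filter_genes",
    "log_cpm",
    "upsample_indices",
    "hurdle_test",
    "emd_test",
    "intersect_de",
]


def filter_genes(matrix: CountMatrix, min_count: int = 1, min_cells: int = 200) -> CountMatrix:
    """Keep genes with count >= ``min_count`` in at least ``min_cells`` cells."""
    if min_count < 0 or min_cells < 0:
        raise ValueError("thresholds must be non-negative")
    n_expressing = (matrix.counts >= min_count).sum(axis=1)
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError("no genes survive the expression filter")
    logger.info("gene filter: kept %d of %d genes", int(keep.sum()), matrix.n_genes)
    return CountMatrix(
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        cell_ids=list(matrix.cell_ids),
        counts=matrix.counts[keep, :],
        cell_type=list(matrix.cell_type),
        dataset_tag=matrix.dataset_tag,
    )


def log_cpm(matrix: CountMatrix) -> np.ndarray:
    """log2(1e6 * count / cell_total + 1), genes x cells.

    Each cell's counts are scaled to a library of one million before the
    log2 transform with pseudocount 1.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts: {[matrix.cell_ids[i] for i in zero[:5]]}"
        )
    return np.log2(1e6 * matrix.counts / totals[None, :] + 1.0)


def upsample_indices(labels: Sequence) -> np.ndarray:
    """Indices replicating each minority-class cell r times (majority once).

    r = round(n_majority / n_minority), so the two classes end up
    roughly balanced.  Cells keep their original order; each minority
    cell's copies are adjacent.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    minority = classes[np.argmin(counts)]
    r = int(round(counts.max() / counts.min()))
    reps = np.where(labels == minority, r, 1)
    return np.repeat(np.arange(labels.size), reps)


# ---------------------------------------------------------------------------
# Hurdle (two-part) test
# ---------------------------------------------------------------------------

def hurdle_test(
    expr: np.ndarray,
    labels: Sequence,
    gene_ids: Sequence[str] | None = None,
    fdr: float = 0.01,
    lfc_min: float = 6.0,
) -> pd.DataFrame:
    """Two-part LRT per gene on log-CPM expression.

    Discrete part: 1-df binomial likelihood-ratio (G-) test of the
    detection proportions in the two groups against the pooled
    proportion.  Continuous part: 1-df Gaussian LRT
    n * ln(RSS0 / RSS1) on the positive-expression cells, computed only
    when each group has at least two positive cells.  The parts'
    statistics and degrees of freedom are summed; log2FC is the group
    mean difference over *all* cells (positive = higher in the
    senescent-labeled group, which must be the group encoded truthy).
    """
    expr = np.asarray(expr, dtype=float)
    g1 = np.asarray(labels).astype(bool)
    if expr.ndim != 2 or g1.size != expr.shape[1]:
        raise ValueError("expr must be genes x cells with one label per cell")
    if g1.all() or not g1.any():
        raise ValueError("both groups must be nonempty")
    g0 = ~g1
    n1, n0 = int(g1.sum()), int(g0.sum())

    detected = expr > 0
    k1 = detected[:, g1].sum(axis=1).astype(float)
    k0 = detected[:, g0].sum(axis=1).astype(float)
    k = k1 + k0

    # discrete part: binomial G-test, 0*log0 == 0 via xlogy
    def _binom_ll(kk, nn, p):
        return xlogy(kk, p) + xlogy(nn - kk, 1.0 - p)

    p_pool = k / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_alt = _binom_ll(k1, n1, np.where(n1 > 0, k1 / n1, 0.0)) + _binom_ll(
            k0, n0, np.where(n0 > 0, k0 / n0, 0.0)
        )
        ll_null = _binom_ll(k1, n1, p_pool) + _binom_ll(k0, n0, p_pool)
    stat_disc = 2.0 * (ll_alt - ll_null)
    stat_disc = np.where(np.isfinite(stat_disc), np.maximum(stat_disc, 0.0), 0.0)

    # continuous part on positive cells (expr is 0 exactly where undetected)
    S1 = expr[:, g1].sum(axis=1)
    S0 = expr[:, g0].sum(axis=1)
    Q1 = (expr[:, g1] ** 2).sum(axis=1)
    Q0 = (expr[:, g0] ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_within = (
            np.where(k1 > 0, Q1 - S1**2 / np.maximum(k1, 1), 0.0)
            + np.where(k0 > 0, Q0 - S0**2 / np.maximum(k0, 1), 0.0)
        )
        rss_pooled = np.where(k > 0, (Q1 + Q0) - (S1 + S0) ** 2 / np.maximum(k, 1), 0.0)
    rss_within = np.maximum(rss_within, 0.0)
    rss_pooled = np.maximum(rss_pooled, 0.0)
    cont_ok = (k1 >= 2) & (k0 >= 2) & (rss_pooled > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat_cont = np.where(
            cont_ok,
            k * np.log(np.maximum(rss_pooled, 1e-300) / np.maximum(rss_within, 1e-300)),
            0.0,
        )
    stat_cont = np.maximum(stat_cont, 0.0)

    stat = stat_disc + stat_cont
    df = 1.0 + cont_ok.astype(float)
    pvals = chi2.sf(stat, df)

    log2fc = expr[:, g1].mean(axis=1) - expr[:, g0].mean(axis=1)

    undetected = k == 0
    pvals = np.where(undetected, 1.0, pvals)
    log2fc = np.where(undetected, 0.0, log2fc)
    if undetected.any():
        logger.warning("%d genes have zero detected cells; p set to 1", int(undetected.sum()))

    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "gene": list(gene_ids) if gene_ids is not None else list(range(expr.shape[0])),
            "log2fc": log2fc,
            "hurdle_stat": stat,
            "df": df,
            "p": pvals,
            "padj": padj,
            "degenerate": undetected,
        }
    )
    table["significant"] = (table["padj"] < fdr) & (table["log2fc"].abs() > lfc_min)
    table["method"] = "hurdle"
    return table


# ---------------------------------------------------------------------------
# EMD permutation test
# ---------------------------------------------------------------------------

def _emd_from_hists(h1: np.ndarray, h0: np.ndarray) -> np.ndarray:
    """CDF-L1 Earth Mover's Distance in bin units, rows = genes."""
    c1 = np.cumsum(h1, axis=-1)
    c0 = np.cumsum(h0, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = c1 / c1[..., -1:]
        c0 = c0 / c0[..., -1:]
    return np.abs(c1 - c0).sum(axis=-1)


def emd_test(
    expr: np.ndarray,
    labels: Sequence,
    n_bins: int = 100,
    n_perm: int = 199,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    fdr: float = 0.01,
    emd_min: float = 30.0,
    null: str = "per_gene",
) -> pd.DataFrame:
    """Earth Mover's Distance test with a label-permutation p-value.

    Per gene, both groups are histogrammed on ``n_bins`` equal-width
    bins spanning the pooled range; the EMD is the L1 distance between
    the two normalised CDFs in bin units (the optimal-transport cost for
    equal-mass 1-D histograms).  The permutation p-value is
    (b + 1) / (n_perm + 1) with b the number of label permutations whose
    EMD is at least the observed one; when the number of distinct label
    assignments is small enough the full enumeration is used instead and
    the p-value is exact.  Labels are permuted at the level of original
    cells — uniform upsampling leaves the normalised histograms (hence
    the EMD) unchanged, so replicated cells never straddle groups.

    ``null="pooled"`` compares each observed EMD against the permutation
    EMDs pooled across all genes, giving p-value resolution
    1 / (n_perm * n_genes); the per-gene null caps p at 1 / (n_perm + 1),
    which an FDR threshold of 0.01 over thousands of genes can never
    clear at practical permutation counts.
    """
    if null not in ("per_gene", "pooled"):
        raise ValueError(f"unknown null {null!r}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    expr = np.asarray(expr, dtype=float)
    g1 = np.asarray(labels).astype(bool)
    if g1.all() or not g1.any():
        raise ValueError("both groups must be nonempty")
    n_genes, n = expr.shape
    n1 = int(g1.sum())

    lo = expr.min(axis=1)
    hi = expr.max(axis=1)
    span = hi - lo
    degenerate = span <= 0
    width = np.where(degenerate, 1.0, span / n_bins)
    bins = np.clip(((expr - lo[:, None]) / width[:, None]).astype(int), 0, n_bins - 1)
    offsets = np.arange(n_genes)[:, None] * n_bins
    flat = bins + offsets  # gene-offset bin index per cell

    def _hists(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h1 = np.bincount(flat[:, mask].ravel(), minlength=n_genes * n_bins)
        h0 = np.bincount(flat[:, ~mask].ravel(), minlength=n_genes * n_bins)
        return h1.reshape(n_genes, n_bins), h0.reshape(n_genes, n_bins)

    h1, h0 = _hists(g1)
    observed = _emd_from_hists(h1, h0)
    observed = np.where(degenerate, 0.0, observed)

    tol = 1e-12
    exhaustive = math.comb(n, n1) <= n_perm + 1
    if exhaustive:
        count = np.zeros(n_genes)
        total = 0
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            e = _emd_from_hists(*_hists(mask))
            count += e >= observed - tol
            total += 1
        pvals = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(n_genes)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n1]] = True
            e = _emd_from_hists(*_hists(mask))
            if null == "per_gene":
                count += e >= observed - tol
            else:
                # count pooled null EMDs >= each gene's observed EMD
                e_sorted = np.sort(e)
                count += e_sorted.size - np.searchsorted(
                    e_sorted, observed - tol, side="left"
                )
        if null == "per_gene":
            pvals = (count + 1.0) / (n_perm + 1.0)
        else:
            pvals = (count + 1.0) / (n_perm * n_genes + 1.0)
    pvals = np.where(degenerate, 1.0, pvals)

    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "gene": list(gene_ids) if gene_ids is not None else list(range(n_genes)),
            "emd": observed,
            "p": pvals,
            "padj": padj,
        }
    )
    table["significant"] = (table["padj"] < fdr) & (table["emd"] > emd_min)
    table["method"] = "emd"
    return table


# ---------------------------------------------------------------------------
# Intersection of the two significant sets
# ---------------------------------------------------------------------------

def intersect_de(
    hurdle_table: pd.DataFrame,
    emd_table: pd.DataFrame,
    universe_size: int | None = None,
) -> tuple[list, TailProb]:
    """Intersect the two methods' significant gene sets and test the overlap.

    The overlap p-value is the upper-tail hypergeometric probability of
    drawing at least the observed intersection when the two sets are
    placed independently in a universe of ``universe_size`` genes
    (default: the shared gene universe of the tables).
    """
    genes_h = list(hurdle_table["gene"])
    genes_e = list(emd_table["gene"])
    if set(genes_h) != set(genes_e):
        raise ValueError("the two tables cover different gene universes")
    sig_h = set(hurdle_table.loc[hurdle_table["significant"], "gene"])
    sig_e = set(emd_table.loc[emd_table["significant"], "gene"])
    shared = [g for g in genes_h if g in sig_h and g in sig_e]
    N = int(universe_size) if universe_size is not None else len(genes_h)
    res = hypergeom_upper_tail(len(shared), len(sig_h), len(sig_e), N)
    return shared, res
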