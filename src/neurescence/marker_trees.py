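"""Minimal marker-pair selection with depth-limited decision trees.

Small C4.5-style trees (gain-ratio splits, integer thresholds, depth
<= 2) are fitted to the consensus senescence labels, restricted to at
most two distinct genes by automatically raising the minimum-cases
parameter.  Fitted trees are frozen — thresholds are never refit — and
evaluated on validation datasets against eigengene-derived labels.  An
elimination ledger iteratively removes the selected markers and records
the next-best pair with its metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .de_dual import upsample_indices
from .io_formats import CountMatrix
from .labeling import NON_SENESCENT, SENESCENT

logger = logging.getLogger("neurescence")

__all__ = [
    "TreeNode",
    "TreeModel",
    "EvalMetrics",
    "binarize",
    "fit_two_gene_tree",
    "predict_tree",
    "evaluate_metrics",
    "elimination_analysis",
]


def binarize(matrix: CountMatrix) -> CountMatrix:
    """Entrywise indicator: any count above zero becomes 1."""
    return CountMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        counts=(matrix.counts > 0).astype(np.int64),
        cell_type=list(matrix.cell_type),
        dataset_tag=matrix.dataset_tag,
    )


@dataclass
class TreeNode:
    """One split: cells with value <= threshold go left, others right."""

    gene: str
    threshold: int
    left: "TreeNode | str"
    right: "TreeNode | str"


@dataclass
class TreeModel:
    """A fitted depth-<=2 tree over at most two distinct genes."""

    root: TreeNode | str  # a bare class string is a single-leaf tree
    input_mode: str  # "counts" | "binary"
    min_cases: int  # effective value after the doubling search
    gene_pool: list[str] = field(default_factory=list)

    @property
    def genes_used(self) -> list[str]:
        genes: list[str] = []

        def walk(node):
            if isinstance(node, TreeNode):
                if node.gene not in genes:
                    genes.append(node.gene)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return genes

    @property
    def depth(self) -> int:
        def d(node):
            if not isinstance(node, TreeNode):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def describe(self) -> str:
        def fmt(node, indent=""):
            if not isinstance(node, TreeNode):
                return f"{indent}-> {node}\n"
            out = f"{indent}{node.gene} <= {node.threshold}?\n"
            out += fmt(node.left, indent + "  [yes] ")
            out += fmt(node.right, indent + "  [no]  ")
            return out

        return fmt(self.root)


@dataclass
class EvalMetrics:
    """Confusion counts and derived rates against eigengene labels."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None


def _entropy(pos: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Binary entropy in bits of pos/total, with 0*log0 == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, pos / np.maximum(total, 1), 0.0)
        h = -(np.where(p > 0, p * np.log2(p), 0.0) + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return np.where(total > 0, h, 0.0)


def _best_split_for_gene(x: np.ndarray, y: np.ndarray, min_cases: int):
    """Best (gain_ratio, threshold, gain) for splits x <= t, or None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    # last index of each unique value -> cumulative counts below threshold
    boundaries = np.flatnonzero(xs[:-1] != xs[1:])
    if boundaries.size == 0:
        return None
    cum_pos = np.cumsum(ys)
    n_left = boundaries + 1
    pos_left = cum_pos[boundaries]
    n_right = n - n_left
    pos_right = cum_pos[-1] - pos_left

    ok = (n_left >= min_cases) & (n_right >= min_cases)
    if not ok.any():
        return None
    n_left, n_right = n_left[ok], n_right[ok]
    pos_left, pos_right = pos_left[ok], pos_right[ok]
    thresholds = xs[boundaries][ok]

    h_parent = _entropy(np.array([cum_pos[-1]]), np.array([n]))[0]
    info = (n_left * _entropy(pos_left, n_left) + n_right * _entropy(pos_right, n_right)) / n
    gain = h_parent - info
    split_info = _entropy(n_left, np.full_like(n_left, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(split_info > 0, gain / np.maximum(split_info, 1e-300), 0.0)
    ratio = np.where(gain > 1e-12, ratio, -np.inf)
    best = int(np.argmax(ratio))  # first max -> smallest threshold on ties
    if not np.isfinite(ratio[best]):
        return None
    return float(ratio[best]), int(thresholds[best]), float(gain[best])


def _leaf(y: np.ndarray) -> str:
    n_pos = int(y.sum())
    return SENESCENT if n_pos * 2 > y.size else NON_SENESCENT


def _grow(X: np.ndarray, y: np.ndarray, genes: Sequence[str], min_cases: int, depth: int, max_depth: int):
    if y.size == 0:
        return NON_SENESCENT
    if depth >= max_depth or y.all() or not y.any():
        return _leaf(y)
    best = None
    for j, gene in enumerate(genes):
        cand = _best_split_for_gene(X[:, j], y, min_cases)
        if cand is None:
            continue
        ratio, threshold, gain = cand
        if best is None or ratio > best[0]:
            best = (ratio, j, threshold)
    if best is None:
        return _leaf(y)
    _, j, t = best
    mask = X[:, j] <= t
    return TreeNode(
        gene=genes[j],
        threshold=t,
        left=_grow(X[mask], y[mask], genes, min_cases, depth + 1, max_depth),
        right=_grow(X[~mask], y[~mask], genes, min_cases, depth + 1, max_depth),
    )


def fit_two_gene_tree(
    matrix: CountMatrix,
    labels: Sequence,
    gene_pool: Sequence[str],
    min_cases: int = 20,
    mode: str = "binary",
    max_depth: int = 2,
    max_genes: int = 2,
    upsample: bool = False,
) -> TreeModel:
    """Fit a small gain-ratio tree on consensus labels.

    ``labels`` may contain borderline entries, which are excluded along
    with their cells.  Candidate thresholds are the observed integer
    values (splits ``<= t``); a split needs at least ``min_cases`` cells
    in each branch.  If the grown tree uses more than ``max_genes``
    distinct genes, ``min_cases`` is doubled and the tree refitted until
    the constraint holds.  ``upsample`` optionally trains on the
    class-balanced replicated multiset.
    """
    if mode not in ("counts", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels, dtype=object)
    keep = (labels == SENESCENT) | (labels == NON_SENESCENT)
    if not keep.any():
        raise ValueError("no non-borderline cells to train on")
    data = binarize(matrix) if mode == "binary" else matrix
    pool = list(gene_pool)
    X = data.subset_genes(pool).counts.T[keep]
    y = (labels[keep] == SENESCENT)

    if y.all() or not y.any():
        logger.warning("single-class labels; returning a one-leaf tree")
        return TreeModel(root=_leaf(y), input_mode=mode, min_cases=min_cases, gene_pool=pool)

    if upsample:
        idx = upsample_indices(y)
        X, y = X[idx], y[idx]

    mc = int(min_cases)
    while True:
        root = _grow(X, y, pool, mc, 0, max_depth)
        used = TreeModel(root=root, input_mode=mode, min_cases=mc, gene_pool=pool).genes_used
        if len(used) <= max_genes:
            break
        mc *= 2
        logger.info("tree used %d genes; raising min_cases to %d", len(used), mc)
    return TreeModel(root=root, input_mode=mode, min_cases=mc, gene_pool=pool)


def predict_tree(tree: TreeModel, matrix: CountMatrix) -> np.ndarray:
    """Route each cell through the frozen tree; thresholds are never refit."""
    genes = tree.genes_used
    missing = [g for g in genes if g not in set(matrix.gene_ids)]
    if missing:
        raise KeyError(f"tree genes missing from matrix: {missing}")
    data = binarize(matrix) if tree.input_mode == "binary" else matrix
    if not genes:
        return np.full(matrix.n_cells, tree.root, dtype=object)
    X = data.subset_genes(genes).counts.T
    col = {g: i for i, g in enumerate(genes)}

    out = np.empty(matrix.n_cells, dtype=object)

    def route(node, idx):
        if not isinstance(node, TreeNode):
            out[idx] = node
            return
        mask = X[idx, col[node.gene]] <= node.threshold
        route(node.left, idx[mask])
        route(node.right, idx[~mask])

    route(tree.root, np.arange(matrix.n_cells))
    return out


def evaluate_metrics(
    predicted: Sequence,
    truth_labels: Sequence,
    accuracy_definition: str = "standard",
) -> EvalMetrics:
    """Confusion metrics of tree predictions against eigengene labels.

    Borderline truth cells are excluded from every denominator.  A true
    positive is a cell called senescent by both the tree and the
    eigengene consensus.  ``accuracy_definition="literal"`` uses
    tp / total instead of (tp + tn) / total.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth_labels, dtype=object)
    if predicted.size != truth.size:
        raise ValueError("prediction and truth lengths differ")
    keep = (truth == SENESCENT) | (truth == NON_SENESCENT)
    predicted, truth = predicted[keep], truth[keep]
    pred_pos = predicted == SENESCENT
    true_pos = truth == SENESCENT
    tp = int((pred_pos & true_pos).sum())
    tn = int((~pred_pos & ~true_pos).sum())
    fp = int((pred_pos & ~true_pos).sum())
    fn = int((~pred_pos & true_pos).sum())
    total = tp + tn + fp + fn
    if accuracy_definition == "literal":
        accuracy = tp / total if total else float("nan")
    else:
        accuracy = (tp + tn) / total if total else float("nan")
    if tp + fn == 0:
        logger.warning("no truth-positive cells; sensitivity undefined")
        sensitivity = None
    else:
        sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) else None
    return EvalMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
    )


def elimination_analysis(
    matrix: CountMatrix,
    labels: Sequence,
    gene_pool: Sequence[str],
    validation_sets: Sequence[tuple[str, CountMatrix, Sequence]] = (),
    max_rounds: int = 5,
    min_cases: int = 20,
    mode: str = "binary",
    exclude: Sequence[str] = (),
    upsample: bool = False,
) -> pd.DataFrame:
    """Iteratively remove selected markers and record the next-best pair.

    Round r fits a tree on the pool minus all genes selected in earlier
    rounds (plus user exclusions), evaluates it on the discovery data
    and every validation set, and appends one ledger row.  Stops after
    ``max_rounds`` or when no admissible split remains.
    """
    removed = list(exclude)
    rows = []
    for round_no in range(1, max_rounds + 1):
        pool = [g for g in gene_pool if g not in removed]
        if len(pool) == 0:
            logger.info("gene pool exhausted after %d rounds", round_no - 1)
            break
        tree = fit_two_gene_tree(
            matrix, labels, pool, min_cases=min_cases, mode=mode, upsample=upsample
        )
        selected = tree.genes_used
        if not selected:
            logger.info("no admissible split left at round %d", round_no)
            break
        row = {
            "round": round_no,
            "removed": ",".join(removed) if removed else "-",
            "selected": ",".join(selected),
        }
        evals = [("discovery", matrix, labels)] + list(validation_sets)
        for name, vmat, vlab in evals:
            m = evaluate_metrics(predict_tree(tree, vmat), vlab)
            row[f"accuracy_{name}"] = m.accuracy
            row[f"specificity_{name}"] = m.specificity
            row[f"sensitivity_{name}"] = m.sensitivity
        rows.append(row)
        removed.extend(selected)
    return pd.DataFrame(rows)
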