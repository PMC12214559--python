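"""Cell-type-balanced weighted-PCA eigengenes for gene panels.

An eigengene summarises a gene panel as the first principal component of
the panel's (standardised) expression: a weighted average of member-gene
expression, one score per cell.  Cell-type imbalance is countered by
weighting each cell inversely to its type's frequency, so rare types
contribute equitably to the component.  A model fitted on a discovery
dataset can be projected onto validation datasets using the discovery
loadings, centers and scales, with the projected score vector rescaled
to the discovery score norm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .io_formats import CountMatrix

logger = logging.getLogger("neurescence")

_EPS_SCALE = 1e-12


@dataclass
class EigengeneModel:
    """A fitted single-panel eigengene.

    ``gene_loadings`` is the unit-norm weight vector over
    ``member_genes`` (the panel genes present and non-degenerate in the
    discovery data), oriented so that scores correlate positively with
    member-gene expression on average.  ``mu``/``sigma`` summarise the
    discovery score distribution; ``threshold_high = mu + 3 sigma`` is
    the overexpression cut used for labeling.
    """

    panel_name: str
    member_genes: list[str]
    gene_loadings: np.ndarray
    gene_centers: np.ndarray
    gene_scales: np.ndarray
    orientation_sign: int
    discovery_scores: np.ndarray
    score_norm: float
    mu: float
    sigma: float
    threshold_high: float
    expression: str = "log_cpm"

    def __post_init__(self) -> None:
        self.gene_loadings = np.asarray(self.gene_loadings, dtype=float)
        self.gene_centers = np.asarray(self.gene_centers, dtype=float)
        self.gene_scales = np.asarray(self.gene_scales, dtype=float)
        self.discovery_scores = np.asarray(self.discovery_scores, dtype=float)

    def to_json(self, path: str) -> str:
        payload = asdict(self)
        for key in ("gene_loadings", "gene_centers", "gene_scales", "discovery_scores"):
            payload[key] = [float(v) for v in payload[key]]
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str) -> "EigengeneModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def balance_weights(cell_types: Sequence[str]) -> np.ndarray:
    """Per-cell weights equalising cell-type influence.

    weight(c) = N_total / N_{type(c)}: every type contributes the same
    total weight, so rarer types get larger per-cell weights.  The
    minimum weight is 1 (attained only when a single type is present).
    """
    cell_types = np.asarray(cell_types)
    if cell_types.size == 0:
        raise ValueError("empty cell-type vector")
    types, counts = np.unique(cell_types, return_counts=True)
    per_type = {t: cell_types.size / c for t, c in zip(types, counts)}
    return np.array([per_type[t] for t in cell_types], dtype=float)


def _expression_matrix(matrix: CountMatrix, genes: Sequence[str], expression: str) -> np.ndarray:
    """Panel rows on the configured expression scale (genes x cells)."""
    idx = matrix.gene_index(genes)
    sub = np.asarray(matrix.counts[idx, :], dtype=float)
    if expression == "raw":
        return sub
    if expression == "log_cpm":
        totals = matrix.counts.sum(axis=0).astype(float)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"cells with zero total counts cannot be CPM-normalised: "
                f"{[matrix.cell_ids[i] for i in zero[:5]]}"
            )
        return np.log2(1e6 * sub / totals[None, :] + 1.0)
    raise ValueError(f"unknown expression scale {expression!r}")


def fit_eigengene(
    matrix: CountMatrix,
    panel_genes: Sequence[str],
    weights: np.ndarray | None = None,
    panel_name: str = "panel",
    expression: str = "log_cpm",
) -> EigengeneModel:
    """Fit a weighted-PCA eigengene for one panel on a discovery dataset.

    Per-gene centers and scales are weighted means and standard
    deviations.  The loadings are the leading right-singular vector of
    the standardised matrix with each cell's profile scaled by
    sqrt(weight) — equivalent to the top eigenvector of the weighted
    covariance matrix.  Discovery scores are the *unweighted* projections
    of the standardised data onto those loadings: the weights shape the
    component, not the reported per-cell scores.
    """
    present = [g for g in panel_genes if g in set(matrix.gene_ids)]
    missing = [g for g in panel_genes if g not in set(matrix.gene_ids)]
    if len(present) < 2:
        raise ValueError(
            f"panel {panel_name!r}: need >=2 genes present in the matrix, "
            f"found {len(present)}; missing: {missing}"
        )
    if matrix.n_cells < 3:
        raise ValueError("need at least 3 cells to fit an eigengene")
    if missing:
        logger.warning(
            "panel %s: %d genes absent from discovery data", panel_name, len(missing)
        )

    if weights is None:
        weights = balance_weights(matrix.cell_type)
    w = np.asarray(weights, dtype=float)
    if w.shape != (matrix.n_cells,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per cell")

    X = _expression_matrix(matrix, present, expression)  # genes x cells
    wsum = w.sum()
    centers = (X * w[None, :]).sum(axis=1) / wsum
    var = ((X - centers[:, None]) ** 2 * w[None, :]).sum(axis=1) / wsum
    scales = np.sqrt(var)

    keep = scales > _EPS_SCALE
    if not np.all(keep):
        dropped = [g for g, k in zip(present, keep) if not k]
        logger.warning("panel %s: dropping zero-variance genes %s", panel_name, dropped)
        present = [g for g, k in zip(present, keep) if k]
        if len(present) < 2:
            raise ValueError(
                f"panel {panel_name!r}: fewer than 2 usable genes after "
                f"dropping zero-variance genes {dropped}"
            )
        X, centers, scales = X[keep], centers[keep], scales[keep]

    Z = (X - centers[:, None]) / scales[:, None]  # genes x cells, standardized
    # weighted PCA: SVD of sqrt(w)-scaled cell profiles
    _, _, vt = np.linalg.svd(Z.T * np.sqrt(w)[:, None], full_matrices=False)
    loadings = vt[0]
    loadings = loadings / np.linalg.norm(loadings)

    scores = Z.T @ loadings  # unweighted projections

    # orientation: scores should on average track member-gene expression
    sign = _orientation_sign(scores, Z)
    loadings = sign * loadings
    scores = sign * scores

    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    return EigengeneModel(
        panel_name=panel_name,
        member_genes=present,
        gene_loadings=loadings,
        gene_centers=centers,
        gene_scales=scales,
        orientation_sign=int(sign),
        discovery_scores=scores,
        score_norm=float(np.linalg.norm(scores)),
        mu=mu,
        sigma=sigma,
        threshold_high=mu + 3.0 * sigma,
        expression=expression,
    )


def _orientation_sign(scores: np.ndarray, Z: np.ndarray) -> int:
    """+1 if mean gene-wise correlation with scores is non-negative, else -1."""
    s = scores - scores.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        return 1
    Zc = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Zc, axis=1)
    norms[norms == 0] = 1.0
    corrs = (Zc @ s) / (norms * s_norm)
    return 1 if corrs.mean() >= 0 else -1


def project_eigengene(
    model: EigengeneModel,
    matrix: CountMatrix,
    norm_mode: str = "literal",
) -> np.ndarray:
    """Project a fitted eigengene onto a validation dataset.

    Validation expression is standardised with the *discovery* centers
    and scales, then combined with the discovery loadings over whichever
    model genes are present.  The resulting score vector is rescaled to
    have the same Euclidean norm as the discovery scores
    (``norm_mode="literal"``); ``"per_cell_rms"`` instead matches the
    root-mean-square score, correcting for dataset-size differences.
    """
    if norm_mode not in ("literal", "per_cell_rms"):
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    avail = set(matrix.gene_ids)
    keep = np.array([g in avail for g in model.member_genes])
    if not keep.any():
        raise ValueError(
            f"panel {model.panel_name!r}: no model genes present in validation data"
        )
    if not keep.all():
        logger.warning(
            "panel %s: %d of %d model genes absent from validation data",
            model.panel_name, int((~keep).sum()), keep.size,
        )
    genes = [g for g, k in zip(model.member_genes, keep) if k]
    X = _expression_matrix(matrix, genes, model.expression)
    scales = np.maximum(model.gene_scales[keep], _EPS_SCALE)
    Z = (X - model.gene_centers[keep][:, None]) / scales[:, None]
    raw = Z.T @ model.gene_loadings[keep]

    raw_norm = np.linalg.norm(raw)
    if raw_norm == 0:
        raise ValueError("projected scores have zero norm; cannot rescale")
    if norm_mode == "literal":
        factor = model.score_norm / raw_norm
    else:
        disc_rms = model.score_norm / np.sqrt(model.discovery_scores.size)
        factor = disc_rms / (raw_norm / np.sqrt(raw.size))
    return raw * factor


def weight_correlation(model_a: EigengeneModel, model_b: EigengeneModel) -> float:
    """Pearson correlation of two models' loadings over their shared genes.

    Orientation is aligned before comparing: the eigenvector sign is
    arbitrary up to the orientation rule, so the comparison flips one
    model's loadings if that is the orientation under which they agree.
    """
    pos_b = {g: i for i, g in enumerate(model_b.member_genes)}
    shared = [(i, pos_b[g]) for i, g in enumerate(model_a.member_genes) if g in pos_b]
    if len(shared) < 3:
        raise ValueError(f"models share only {len(shared)} genes; need >=3")
    ia, ib = zip(*shared)
    la = model_a.gene_loadings[list(ia)]
    lb = model_b.gene_loadings[list(ib)]
    r = float(np.corrcoef(la, lb)[0, 1])
    return abs(r) if r < 0 else r
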