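"""Consensus senescence labeling from three panel eigengenes.

A cell is called positive for a panel when its eigengene score exceeds
the discovery mean plus three standard deviations, negative when it
falls below the mean, and borderline otherwise.  The consensus calls a
cell senescent only when all three panels are positive, non-senescent
only when all three are negative; every other cell is borderline and
excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .eigengene import EigengeneModel
from .set_stats import hypergeom_upper_tail

logger = logging.getLogger("neurescence")

POS, NEG, BORDERLINE = "pos", "neg", "borderline"
SENESCENT, NON_SENESCENT = "senescent", "non_senescent"


@dataclass
class CellLabeling:
    """Per-panel statuses and the consensus label for each cell."""

    panel_status: dict[str, np.ndarray]  # panel name -> per-cell pos/neg/borderline
    consensus: np.ndarray  # per-cell senescent / non_senescent / borderline

    @property
    def senescent_mask(self) -> np.ndarray:
        return self.consensus == SENESCENT

    @property
    def non_senescent_mask(self) -> np.ndarray:
        return self.consensus == NON_SENESCENT

    @property
    def borderline_mask(self) -> np.ndarray:
        return self.consensus == BORDERLINE

    def counts(self) -> dict[str, int]:
        return {
            SENESCENT: int(self.senescent_mask.sum()),
            NON_SENESCENT: int(self.non_senescent_mask.sum()),
            BORDERLINE: int(self.borderline_mask.sum()),
        }

    def to_frame(self, cell_ids: Sequence[str] | None = None) -> pd.DataFrame:
        data = {f"status_{k}": v for k, v in self.panel_status.items()}
        data["consensus"] = self.consensus
        df = pd.DataFrame(data)
        if cell_ids is not None:
            df.insert(0, "cell_id", list(cell_ids))
        return df


def panel_status(
    scores: np.ndarray,
    model: EigengeneModel,
    multiplier: float = 3.0,
) -> np.ndarray:
    """Classify each cell against one panel's discovery thresholds.

    Strictly above mu + multiplier*sigma is positive; strictly below mu
    is negative; everything else — including exact ties — is borderline.
    Validation scores are compared against the *discovery* mu/sigma
    carried by the model.
    """
    scores = np.asarray(scores, dtype=float)
    bad = ~np.isfinite(scores)
    if bad.any():
        raise ValueError(f"non-finite scores at cell indices {np.flatnonzero(bad)[:5]}")
    high = model.mu + multiplier * model.sigma
    out = np.full(scores.shape, BORDERLINE, dtype=object)
    out[scores > high] = POS
    out[scores < model.mu] = NEG
    return out


def consensus_label(
    status_csp: np.ndarray,
    status_sip: np.ndarray,
    status_senmayo: np.ndarray,
    panel_names: tuple[str, str, str] = ("CSP", "SIP", "SenMayo"),
) -> CellLabeling:
    """Combine three per-panel statuses into the consensus label."""
    statuses = [np.asarray(s, dtype=object) for s in (status_csp, status_sip, status_senmayo)]
    n = statuses[0].size
    if any(s.size != n for s in statuses):
        raise ValueError("status vectors must have equal length")
    all_pos = np.logical_and.reduce([s == POS for s in statuses])
    all_neg = np.logical_and.reduce([s == NEG for s in statuses])
    consensus = np.full(n, BORDERLINE, dtype=object)
    consensus[all_pos] = SENESCENT
    consensus[all_neg] = NON_SENESCENT
    return CellLabeling(
        panel_status=dict(zip(panel_names, statuses)),
        consensus=consensus,
    )


def celltype_enrichment(
    labeling: CellLabeling,
    cell_types: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of senescent cells per cell type.

    For each type: draw n = type size cells from the N labeled cells, of
    which K are senescent; p = P(X >= observed senescent in the type).
    """
    cell_types = np.asarray(cell_types)
    if cell_types.size != labeling.consensus.size:
        raise ValueError("cell_types length must match labeling")
    N = int(cell_types.size)
    sen = labeling.senescent_mask
    K = int(sen.sum())
    if K == 0:
        logger.warning("no senescent cells; enrichment p-values are all 1")
    rows = []
    for t in np.unique(cell_types):
        mask = cell_types == t
        n = int(mask.sum())
        k = int((sen & mask).sum())
        res = hypergeom_upper_tail(k, K, n, N) if K else None
        rows.append(
            {
                "cell_type": t,
                "n_cells": n,
                "n_senescent": k,
                "p": res.p if res else 1.0,
                "log10p": res.log10p if res else 0.0,
            }
        )
    return pd.DataFrame(rows)
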