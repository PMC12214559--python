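"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as Matrix Market coordinate files with two TSV
sidecars (``genes.tsv`` with a ``gene_id`` column, ``cells.tsv`` with
``cell_id`` and ``cell_type`` columns).  Gene panels and pathway
collections are GMT files or plain one-gene-per-line lists.  All tabular
output is TSV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("neurescence")

#: how the on-disk MTX is oriented; readers transpose "cells_x_genes" input.
DEFAULT_ORIENTATION = "genes_x_cells"


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A genes x cells matrix of non-negative integer counts.

    ``cell_type`` carries one categorical label per cell (e.g. excitatory /
    inhibitory); ``dataset_tag`` is a free-text provenance string.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray  # genes x cells, integer dtype
    cell_type: list[str]
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = len(self.gene_ids), len(self.cell_ids)
        if self.counts.shape != (n_genes, n_cells):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({n_genes} genes, {n_cells} cells)"
            )
        if len(self.cell_type) != n_cells:
            raise ValueError("cell_type must have one label per cell")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    # -- conveniences -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Positions of ``genes`` in this matrix; raises on any miss."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            counts=self.counts[idx, :],
            cell_type=list(self.cell_type),
            dataset_tag=self.dataset_tag,
        )

    def subset_cells(self, mask_or_index: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            cell_type=[self.cell_type[i] for i in idx],
            dataset_tag=self.dataset_tag,
        )


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (senescence panels or pathway databases)."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, present: Sequence[str], name: str) -> list[str]:
        """Members of set ``name`` found in ``present`` (order preserved).

        Genes missing from the data are dropped here, at the use site, with
        a logged count; the collection itself keeps the full panels.
        """
        avail = set(present)
        kept = [g for g in self.sets[name] if g in avail]
        n_drop = len(self.sets[name]) - len(kept)
        if n_drop:
            logger.warning(
                "panel %s: %d of %d genes absent from the dataset; using %d",
                name, n_drop, len(self.sets[name]), len(kept),
            )
        return kept


# ---------------------------------------------------------------------------
# Count-matrix IO
# ---------------------------------------------------------------------------

def read_count_matrix(
    matrix_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    orientation: str = DEFAULT_ORIENTATION,
    dataset_tag: str = "",
) -> CountMatrix:
    """Read a Matrix Market counts file plus its gene/cell TSV sidecars.

    ``orientation`` says how the MTX on disk is laid out; the returned
    matrix is always genes x cells.
    """
    if orientation not in ("genes_x_cells", "cells_x_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = scipy.io.mmread(os.fspath(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if orientation == "cells_x_genes":
        mat = mat.T

    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    if "gene_id" not in genes.columns:
        raise ValueError(f"{genes_path}: missing required column 'gene_id'")
    for col in ("cell_id", "cell_type"):
        if col not in cells.columns:
            raise ValueError(f"{cells_path}: missing required column {col!r}")

    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: {matrix_path} is {mat.shape} (genes x cells "
            f"after orientation) but {genes_path} has {len(genes)} rows and "
            f"{cells_path} has {len(cells)} rows"
        )
    if not np.all(np.equal(np.mod(mat, 1), 0)):
        raise ValueError(f"{matrix_path}: non-integer entries")
    if mat.size and mat.min() < 0:
        raise ValueError(f"{matrix_path}: negative entries")

    return CountMatrix(
        gene_ids=genes["gene_id"].astype(str).tolist(),
        cell_ids=cells["cell_id"].astype(str).tolist(),
        counts=mat.astype(np.int64),
        cell_type=cells["cell_type"].astype(str).tolist(),
        dataset_tag=dataset_tag,
    )


def write_count_matrix(matrix: CountMatrix, out_dir: str | os.PathLike) -> str:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` into ``out_dir``."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.counts)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sparse, field="integer")
    pd.DataFrame({"gene_id": matrix.gene_ids}).to_csv(
        os.path.join(out_dir, "genes.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"cell_id": matrix.cell_ids, "cell_type": matrix.cell_type}).to_csv(
        os.path.join(out_dir, "cells.tsv"), sep="\t", index=False
    )
    return out_dir


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file, or a plain one-gene-per-line list as a single set.

    A line is treated as GMT when it contains tab characters (name,
    description, then member genes); otherwise the whole file is one set
    named after the file stem.  Duplicated genes within a set are dropped
    with a warning.
    """
    path = os.fspath(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty gene-set file")

    sets: dict[str, list[str]] = {}
    if any("\t" in ln for ln in lines):
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {ln!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning(
                    "%s: set %s has %d duplicated genes; deduplicated",
                    path, name, len(genes) - len(uniq),
                )
            if not uniq:
                raise ValueError(f"{path}: set {name!r} is empty")
            sets[name] = uniq
    else:
        name = os.path.splitext(os.path.basename(path))[0]
        uniq = list(dict.fromkeys(lines))
        if len(uniq) != len(lines):
            logger.warning("%s: %d duplicated genes; deduplicated", path, len(lines) - len(uniq))
        sets[name] = uniq
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(rows, path: str | os.PathLike) -> str:
    """Write records as a TSV with header; floats keep full precision.

    ``rows`` may be a DataFrame or an iterable of mappings with homogeneous
    fields; row order is preserved exactly as given.
    """
    path = os.fspath(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
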