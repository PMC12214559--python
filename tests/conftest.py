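import numpy as np
import pytest

from neurescence import CountMatrix, SyntheticConfig


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """3 genes x 4 cells with mixed cell types."""
    counts = np.array(
        [
            [0, 1, 5, 2],
            [3, 0, 0, 1],
            [7, 2, 1, 0],
        ]
    )
    return CountMatrix(
        gene_ids=["gA", "gB", "gC"],
        cell_ids=["c1", "c2", "c3", "c4"],
        counts=counts,
        cell_type=["excitatory", "excitatory", "inhibitory", "excitatory"],
        dataset_tag="toy",
    )


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A fast-to-generate synthetic configuration for unit tests."""
    return SyntheticConfig(
        n_cells=600,
        n_genes=300,
        n_de_genes=20,
        senescent_fraction=0.05,
    )


def random_count_matrix(rng, n_genes=6, n_cells=12) -> CountMatrix:
    counts = rng.integers(0, 20, size=(n_genes, n_cells))
    counts[0, :] = np.maximum(counts[0, :], 1)  # avoid all-zero cells
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        counts=counts,
        cell_type=["A"] * (n_cells // 2) + ["B"] * (n_cells - n_cells // 2),
    )
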