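import numpy as np
import pytest

import divergescan as dv


@pytest.fixture
def two_blob_embedding():
    """500 cells in two well-separated 2D Gaussian blobs."""
    rng = np.random.default_rng(11)
    a = rng.normal(loc=(0, 0), scale=0.5, size=(250, 2))
    b = rng.normal(loc=(10, 0), scale=0.5, size=(250, 2))
    coords = np.vstack([a, b])
    cells = np.array([f"c{i}" for i in range(500)], dtype=object)
    return dv.EmbeddingCoordinates(cells, coords, "blobs")


@pytest.fixture
def uniform_blob_detection():
    """300 cells uniform in 2D plus a detection matrix of null genes."""
    rng = np.random.default_rng(5)
    n_cells, n_genes = 300, 40
    coords = rng.uniform(0, 1, size=(n_cells, 2))
    cells = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    emb = dv.EmbeddingCoordinates(cells, coords, "uniform")
    det = np.zeros((n_genes, n_cells), dtype=bool)
    counts = np.round(np.geomspace(15, 150, n_genes)).astype(int)
    for g, c in enumerate(counts):
        det[g, rng.choice(n_cells, c, replace=False)] = True
    genes = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    return dv.DetectionMatrix(genes, cells, det), emb


@pytest.fixture
def density_setup(uniform_blob_detection):
    """Detection matrix with its grid, kernel weights and Q."""
    det, emb = uniform_blob_detection
    grid = dv.select_grid_2d(emb, 36)
    dm = dv.kernel_weights(emb, grid)
    q = dv.reference_distribution(dm)
    return det, emb, grid, dm, q
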