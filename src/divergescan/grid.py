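"""Grid points, Gaussian kernel densities and distribution profiles.

Local cell density is evaluated at a fixed set of grid points in the input
space. For 2D spaces the grid is a regular lattice spanning the data range;
for higher-dimensional spaces grid points are seeded k-means centroids of the
cell cloud, which keeps them inside the occupied subspace instead of the
mostly empty corners of the bounding box.

Every density profile (the reference Q and the per-gene class profiles
P(G=T), P(G=F)) is a probability vector over grid points: kernel mass summed
per grid point, a small pseudocount added, then normalized to sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .detection import DetectionMatrix
from .io import EmbeddingCoordinates

#: pseudocount added to every grid point before normalization, as a fraction
#: spread over the grid; keeps Q strictly positive so log(P/Q) is defined.
EPSILON_TOTAL = 1e-9


@dataclass
class GridSet:
    """Grid point coordinates plus the Gaussian kernel bandwidth h."""

    points: np.ndarray
    bandwidth_h: float
    space_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise ValueError("need at least 2 grid points")
        if not self.bandwidth_h > 0:
            raise ValueError("bandwidth must be positive")

    @property
    def n_grid(self) -> int:
        return len(self.points)


@dataclass
class DensityMatrix:
    """Kernel weight of every cell at every grid point (n_cells x n_grid)."""

    weights: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_grid(self) -> int:
        return self.weights.shape[1]


def scale_coordinates(emb: EmbeddingCoordinates) -> EmbeddingCoordinates:
    """Standardize each dimension to unit standard deviation.

    An isotropic kernel on raw principal components would be dominated by
    PC1; standardization puts all dimensions on one footing. Skip this for
    physical spatial coordinates, where axes share units.
    """
    sd = emb.coords.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("cannot scale: a coordinate dimension has zero variance")
    return EmbeddingCoordinates(emb.cell_ids, emb.coords / sd, emb.space_label)


def default_bandwidth(emb: EmbeddingCoordinates, points: np.ndarray) -> float:
    """Median over cells of the distance to the nearest grid point.

    Scale-adaptive: doubling all coordinates doubles h. If every cell sits
    exactly on a grid point the median is 0 and the mean nearest-neighbor
    distance among grid points is used instead.
    """
    d = cdist(emb.coords, points)
    h = float(np.median(d.min(axis=1)))
    if h == 0:
        dg = cdist(points, points)
        np.fill_diagonal(dg, np.inf)
        h = float(np.mean(dg.min(axis=1)))
    if not h > 0:
        raise ValueError("cannot derive a positive bandwidth for this grid")
    return h


def select_grid_2d(emb: EmbeddingCoordinates, n_grid: int = 100,
                   bandwidth: float | None = None) -> GridSet:
    """Lattice grid for 2D spaces: ceil(sqrt(n_grid)) levels per axis.

    Levels span [min, max] of each axis inclusive; all k^2 intersection
    points are kept, so the realized grid size may exceed the request.
    """
    if emb.n_dims != 2:
        raise ValueError("select_grid_2d requires exactly 2 dimensions")
    if n_grid < 4:
        raise ValueError("need n_grid >= 4 for a 2D lattice")
    lo, hi = emb.coords.min(axis=0), emb.coords.max(axis=0)
    if np.any(hi - lo == 0):
        raise ValueError("degenerate axis: all cells share one coordinate value")
    k = math.ceil(math.sqrt(n_grid))
    xs = np.linspace(lo[0], hi[0], k)
    ys = np.linspace(lo[1], hi[1], k)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    h = bandwidth if bandwidth is not None else default_bandwidth(emb, pts)
    return GridSet(pts, h, emb.space_label)


def select_grid_highd(emb: EmbeddingCoordinates, n_grid: int = 100, seed: int = 0,
                      bandwidth: float | None = None) -> GridSet:
    """Grid points for >= 2D spaces: seeded k-means centroids of the cells.

    Centroids track the occupied region of the space, so no grid point lands
    far from all cells. Deterministic for a fixed seed.
    """
    if n_grid > emb.n_cells:
        raise ValueError("n_grid cannot exceed the number of cells")
    if n_grid < 2:
        raise ValueError("need n_grid >= 2")
    km = KMeans(n_clusters=n_grid, n_init=1, max_iter=50, random_state=seed)
    km.fit(emb.coords)
    pts = km.cluster_centers_.astype(float)
    h = bandwidth if bandwidth is not None else default_bandwidth(emb, pts)
    return GridSet(pts, h, emb.space_label)


def kernel_weights(emb: EmbeddingCoordinates, grid: GridSet) -> DensityMatrix:
    """Untruncated Gaussian kernel: w(c, x) = exp(-d(c,x)^2 / (2 h^2))."""
    d2 = cdist(emb.coords, grid.points, metric="sqeuclidean")
    return DensityMatrix(np.exp(-d2 / (2.0 * grid.bandwidth_h**2)))


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Pseudocount and normalization shared by all profiles.

    The raw mass is normalized first, so the pseudocount is a fixed total of
    EPSILON_TOTAL spread over grid points and the result is invariant to any
    positive rescaling of the input (e.g. of cell weights). Works on one
    profile (1-D) or a stack of profiles (rows of a 2-D array).
    """
    raw = np.asarray(raw, dtype=float)
    n_grid = raw.shape[-1]
    p = raw / raw.sum(axis=-1, keepdims=True)
    p = p + EPSILON_TOTAL / n_grid
    return p / p.sum(axis=-1, keepdims=True)


def reference_distribution(dm: DensityMatrix, weights: np.ndarray | None = None) -> np.ndarray:
    """Reference distribution Q: (weighted) kernel mass of all cells.

    ``weights`` are per-cell weights (advanced mode: proportional to each
    cell's number of detected genes); None means uniform.
    """
    if weights is None:
        raw = dm.weights.sum(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (dm.n_cells,):
            raise ValueError("weights length must equal n_cells")
        raw = w @ dm.weights
    return _normalize(raw)


def class_distributions(dm: DensityMatrix, detected_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Profiles of detecting (P_T) and non-detecting (P_F) cells for one gene."""
    det = np.asarray(detected_row, dtype=bool)
    if det.shape != (dm.n_cells,):
        raise ValueError("detection vector length must equal n_cells")
    if det.all() or not det.any():
        raise ValueError("gene detected in all or no cells; filter such genes first")
    p_t = _normalize(det.astype(float) @ dm.weights)
    p_f = _normalize((~det).astype(float) @ dm.weights)
    return p_t, p_f


def compute_cell_weights(det: DetectionMatrix) -> np.ndarray:
    """Per-cell weights proportional to the number of genes detected in the cell.

    Cells detecting zero genes receive the minimum positive count so that all
    weights stay strictly positive. Normalized to sum to 1.
    """
    counts = det.detected.sum(axis=0).astype(float)
    if np.all(counts == 0):
        counts = np.ones_like(counts)
    elif np.any(counts == 0):
        counts[counts == 0] = counts[counts > 0].min()
    return counts / counts.sum()
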