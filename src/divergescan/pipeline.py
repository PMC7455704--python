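"""End-to-end runs: expression + coordinates in, result table out."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import detection as det_mod
from . import grid as grid_mod
from . import significance as sig_mod
from .detection import DetectionConfig, DetectionMatrix
from .divergence import score_all_genes
from .io import EmbeddingCoordinates, ExpressionMatrix, align_cells
from .significance import RandomizationConfig

logger = logging.getLogger("divergescan")


def run(
    expr: ExpressionMatrix,
    emb: EmbeddingCoordinates,
    method: str = "highd",
    mode: str = "default",
    grid_points: int = 100,
    bandwidth: float | None = None,
    detection: str = "median",
    detection_threshold: float = 1.0,
    min_detected: int = 10,
    randomizations: int = 100,
    count_levels: int = 20,
    spline_df: int = 6,
    seed: int = 42,
    scale_coords: bool = True,
) -> pd.DataFrame:
    """Score every gene for non-random placement of its detecting cells.

    Parameters
    ----------
    method
        ``"highd"`` (k-means grid points, any >= 2D space) or ``"2d"``
        (lattice grid, exactly 2 dimensions, e.g. t-SNE or spatial).
    mode
        ``"default"``, or ``"advanced"`` to weight cells by their number of
        detected genes in the reference distribution and the randomizations,
        discounting genes that merely track overall detection depth.
    scale_coords
        Standardize each input dimension before distances; turn off for
        physical spatial coordinates.

    Returns
    -------
    DataFrame with columns gene, d_kl, n_detected, log10_pval,
    log10_pval_adj, rank, sorted by rank.
    """
    t0 = time.perf_counter()
    expr, emb = align_cells(expr, emb)

    dcfg = DetectionConfig(method=detection, threshold=detection_threshold)
    det = det_mod.binarize(expr, dcfg)
    det = det_mod.filter_genes(det, min_detected=min_detected)
    logger.info("detection: %d of %d genes pass filtering [%.2fs]",
                det.n_genes, expr.n_genes, time.perf_counter() - t0)

    return run_from_detection(
        det, emb, method=method, mode=mode, grid_points=grid_points,
        bandwidth=bandwidth, randomizations=randomizations,
        count_levels=count_levels, spline_df=spline_df, seed=seed,
        scale_coords=scale_coords,
    )


def run_from_detection(
    det: DetectionMatrix,
    emb: EmbeddingCoordinates,
    method: str = "highd",
    mode: str = "default",
    grid_points: int = 100,
    bandwidth: float | None = None,
    randomizations: int = 100,
    count_levels: int = 20,
    spline_df: int = 6,
    seed: int = 42,
    scale_coords: bool = True,
) -> pd.DataFrame:
    """As :func:`run`, starting from a pre-built (filtered) detection matrix."""
    t0 = time.perf_counter()
    if not np.array_equal(det.cell_ids, emb.cell_ids):
        raise ValueError("detection matrix and coordinates must list the same cells in order")
    if scale_coords:
        emb = grid_mod.scale_coordinates(emb)

    if method == "2d":
        grid = grid_mod.select_grid_2d(emb, grid_points, bandwidth=bandwidth)
    elif method == "highd":
        grid = grid_mod.select_grid_highd(emb, grid_points, seed=seed, bandwidth=bandwidth)
    else:
        raise ValueError(f"unknown method {method!r}")
    dm = grid_mod.kernel_weights(emb, grid)
    logger.info("grid: %d points, bandwidth h=%.4g [%.2fs]",
                grid.n_grid, grid.bandwidth_h, time.perf_counter() - t0)

    if mode == "advanced":
        weights = grid_mod.compute_cell_weights(det)
    elif mode == "default":
        weights = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    q = grid_mod.reference_distribution(dm, weights)
    scores = score_all_genes(det, dm, q)
    logger.info("divergence: scored %d genes [%.2fs]", len(scores), time.perf_counter() - t0)

    cfg = RandomizationConfig(
        n_randomizations=randomizations, n_count_levels=count_levels,
        spline_df=spline_df, seed=seed, weighted=(mode == "advanced"),
    )
    model = sig_mod.build_null_model(dm, q, det.n_detected, cfg, weights)
    res = sig_mod.p_values(scores, model)
    logger.info("significance: null fitted on %d levels, table ready [%.2fs]",
                len(model.levels), time.perf_counter() - t0)
    return res
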