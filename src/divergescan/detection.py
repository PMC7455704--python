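"""Binarization of expression into detection, and gene prefiltering.

The divergence statistic operates on binary detection: a gene is either
detected or not in each cell. Two cutoff rules are supported:

* ``median`` — per-gene cutoff at the median of that gene's values across
  cells (the default for scRNA-seq);
* ``threshold`` — a single global cutoff, e.g. 1 raw count for spatial data.

Both use a strict comparison (value > cutoff): with a ">=" rule the median
cutoff would mark at least half of all cells detected for every gene,
including all-zero genes. For integer counts whose median is 0, the median
rule reduces to "counts > 0" detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger("divergescan")


@dataclass
class DetectionConfig:
    method: str = "median"  # {"median", "threshold"}
    threshold: float = 1.0  # used when method == "threshold"

    def __post_init__(self) -> None:
        if self.method not in ("median", "threshold"):
            raise ValueError(f"unknown detection method {self.method!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")


@dataclass
class DetectionMatrix:
    """Boolean gene x cell matrix: gene detected in cell or not."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.detected.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("detection matrix shape mismatch")

    @property
    def n_detected(self) -> np.ndarray:
        """Number of cells detecting each gene."""
        return self.detected.sum(axis=1)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def binarize(expr: ExpressionMatrix, cfg: DetectionConfig | None = None) -> DetectionMatrix:
    """Convert expression values to a binary detection matrix."""
    cfg = cfg or DetectionConfig()
    if cfg.method == "median":
        cutoff = np.median(expr.values, axis=1, keepdims=True)
    else:
        cutoff = np.full((expr.n_genes, 1), float(cfg.threshold))
    return DetectionMatrix(expr.gene_ids, expr.cell_ids, expr.values > cutoff)


def filter_genes(det: DetectionMatrix, min_detected: int = 10) -> DetectionMatrix:
    """Drop genes whose detection pattern carries no usable signal.

    Keeps genes with ``min_detected <= n_detected <= n_cells - 1``. Genes
    detected in very few cells are unstable under the randomization null;
    genes detected in every cell have P(G=T) identical to the reference
    distribution by construction and score ~0.
    """
    if min_detected < 0:
        raise ValueError("min_detected must be >= 0")
    nd = det.n_detected
    keep = (nd >= max(min_detected, 1)) & (nd <= det.n_cells - 1)
    n_low = int((nd < max(min_detected, 1)).sum())
    n_all = int((nd > det.n_cells - 1).sum())
    if n_low or n_all:
        logger.warning(
            "filter_genes: removed %d genes below min_detected=%d and %d detected in all cells",
            n_low, min_detected, n_all,
        )
    if not keep.any():
        raise ValueError("all genes removed by detection filtering")
    return DetectionMatrix(det.gene_ids[keep], det.cell_ids, det.detected[keep])
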