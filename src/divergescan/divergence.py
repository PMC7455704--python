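"""The divergence statistic D_KL(G).

For each gene G the statistic sums, over the two detection classes
s in {T, F} and over all grid points x,

    D_KL(G) = sum_s sum_x P(G=s, x) * log( P(G=s, x) / Q(x) )

with natural logarithm, where P(G=s) is the class profile normalized to 1
and Q is the reference profile. Each class term is a Kullback-Leibler
divergence, so the statistic is non-negative, and it is symmetric under
complementing the detection vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import DetectionMatrix
from .grid import DensityMatrix, _normalize


@dataclass
class DivergenceScore:
    gene_id: str
    d_kl: float
    n_detected: int


def kl_divergence(p_t: np.ndarray, p_f: np.ndarray, q: np.ndarray) -> float:
    """Evaluate the statistic for one gene from its three profiles."""
    p_t, p_f, q = (np.asarray(a, dtype=float) for a in (p_t, p_f, q))
    if not (p_t.shape == p_f.shape == q.shape):
        raise ValueError("profiles must share one grid")
    return float(_kl_term(p_t, q) + _kl_term(p_f, q))


def _kl_term(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """sum_x p * log(p/q) along the last axis, with 0*log(0/q) := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log(p / q)
    return np.where(p > 0, t, 0.0).sum(axis=-1)


def divergences_from_raw(t_raw: np.ndarray, f_raw: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized statistic for stacked unnormalized class masses.

    ``t_raw``/``f_raw`` are (n, n_grid) kernel-mass rows before pseudocount
    and normalization; returns n divergence values.
    """
    return _kl_term(_normalize(t_raw), q) + _kl_term(_normalize(f_raw), q)


def score_all_genes(det: DetectionMatrix, dm: DensityMatrix, q: np.ndarray) -> list[DivergenceScore]:
    """Score every (pre-filtered) gene of a detection matrix.

    Class masses for all genes come from one matrix product: detecting-cell
    mass is D @ W and non-detecting mass is the column-sum complement, where
    D is the boolean detection matrix and W the cell x grid kernel weights.
    """
    nd = det.n_detected
    if np.any(nd < 1) or np.any(nd > det.n_cells - 1):
        raise ValueError("detection matrix contains unfiltered all/none genes")
    d = det.detected.astype(float)
    t_raw = d @ dm.weights
    f_raw = dm.weights.sum(axis=0) - t_raw
    dkl = divergences_from_raw(t_raw, f_raw, q)
    return [
        DivergenceScore(gene_id=g, d_kl=float(v), n_detected=int(n))
        for g, v, n in zip(det.gene_ids, dkl, nd)
    ]
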