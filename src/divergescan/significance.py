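"""Randomization null model and p-values.

The null distribution of the statistic depends almost exclusively on the
number of cells in which a gene is detected, so instead of shuffling every
gene individually, the model randomizes detection at a small set of
detection-count levels and smooths the resulting mean and standard deviation
of log D_KL across counts with cubic B-splines. A gene's p-value is then the
upper tail of a standard normal at

    z = (ln D_KL - mean_curve(ln n_detected)) / sd_curve(ln n_detected),

computed in log space so that extreme genes do not underflow. Only excess
divergence is of interest, hence the one-sided test. Benjamini-Hochberg
adjusted values are reported alongside, but gene ranking - the primary
output - uses the raw p-values with ties broken by the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import log_ndtr

from .detection import DetectionMatrix
from .divergence import DivergenceScore, divergences_from_raw
from .grid import DensityMatrix
from .io import RESULT_COLUMNS

logger = logging.getLogger("divergescan")

LN10 = np.log(10.0)
SD_FLOOR = 1e-6


@dataclass
class RandomizationConfig:
    n_randomizations: int = 100
    n_count_levels: int = 20
    spline_df: int = 6
    seed: int = 42
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.n_randomizations < 10:
            raise ValueError("need at least 10 randomizations")
        if self.n_count_levels < 4:
            raise ValueError("need at least 4 count levels")


@dataclass
class NullModel:
    """Fitted mean/sd of log D_KL as functions of log detection count."""

    mean_curve: Callable[[np.ndarray], np.ndarray]
    sd_curve: Callable[[np.ndarray], np.ndarray]
    fit_domain: tuple[float, float]
    levels: np.ndarray = field(default=None, repr=False)
    level_means: np.ndarray = field(default=None, repr=False)
    level_sds: np.ndarray = field(default=None, repr=False)

    def diagnostics(self) -> pd.DataFrame:
        """Per-level empirical and fitted values, for plotting/inspection."""
        x = np.log(self.levels.astype(float))
        return pd.DataFrame({
            "level": self.levels,
            "mean_log_dkl": self.level_means,
            "sd_log_dkl": self.level_sds,
            "fitted_mean": self.mean_curve(x),
            "fitted_sd": self.sd_curve(x),
        })


def choose_count_levels(n_cells: int, n_detected: np.ndarray,
                        n_levels: int = 20) -> np.ndarray:
    """Approximately log-spaced detection counts covering the observed range."""
    nd = np.asarray(n_detected, dtype=int)
    lo = max(int(nd.min()), 1)
    hi = min(int(nd.max()), n_cells - 1)
    if hi <= lo:
        return np.array([lo])
    levels = np.unique(np.round(np.geomspace(lo, hi, n_levels)).astype(int))
    levels = levels[(levels >= 1) & (levels <= n_cells - 1)]
    return levels


def sample_detection_indices(level: int, n_cells: int, n_draws: int,
                             rng: np.random.Generator,
                             weights: np.ndarray | None = None) -> np.ndarray:
    """Draw ``n_draws`` detection sets of size ``level`` without replacement.

    Uses Gumbel-perturbed log-weights (top-k of log w + Gumbel noise), which
    is equivalent to sequentially drawing cells with probability proportional
    to the remaining weights; uniform weights give plain uniform sampling.
    """
    keys = rng.gumbel(size=(n_draws, n_cells))
    if weights is not None:
        keys = keys + np.log(np.asarray(weights, dtype=float))
    return np.argpartition(keys, n_cells - level, axis=1)[:, n_cells - level:]


def randomized_divergences(level: int, dm: DensityMatrix, q: np.ndarray,
                           cfg: RandomizationConfig, rng: np.random.Generator,
                           weights: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and sd (ddof=1) of ln D_KL over random detection sets of one size."""
    if not 1 <= level <= dm.n_cells - 1:
        raise ValueError("level must lie in [1, n_cells - 1]")
    idx = sample_detection_indices(level, dm.n_cells, cfg.n_randomizations, rng, weights)
    sel = np.zeros((cfg.n_randomizations, dm.n_cells))
    np.put_along_axis(sel, idx, 1.0, axis=1)
    t_raw = sel @ dm.weights
    f_raw = dm.weights.sum(axis=0) - t_raw
    log_dkl = np.log(divergences_from_raw(t_raw, f_raw, q))
    mean = float(log_dkl.mean())
    sd = float(log_dkl.std(ddof=1))
    if sd < SD_FLOOR:
        logger.warning("randomized divergences at level %d have ~zero spread; "
                       "flooring sd at %g", level, SD_FLOOR)
        sd = SD_FLOOR
    return mean, sd


def _spline_fit(x: np.ndarray, y: np.ndarray, n_basis: int) -> Callable[[np.ndarray], np.ndarray]:
    """Least-squares cubic B-spline of y on x with quantile interior knots."""
    k = 3
    n_interior = n_basis - (k + 1)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[x[0]] * (k + 1), interior, [x[-1]] * (k + 1)])
    design = BSpline.design_matrix(x, t, k).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return BSpline(t, coef, k, extrapolate=False)


def fit_null_model(levels: np.ndarray, means: np.ndarray, sds: np.ndarray,
                   spline_df: int = 6) -> NullModel:
    """Smooth per-level null moments into continuous curves of log count.

    ``spline_df`` counts basis columns beyond the intercept, as in R's
    ``bs()``: the fit has spline_df + 1 parameters, capped at the number of
    levels (a saturated fit interpolates). Fewer than 4 distinct levels fall
    back to a constant model; queries outside the fitted count range are
    clamped to its endpoints, because polynomial spline tails diverge.
    """
    levels = np.asarray(levels, dtype=int)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
        raise ValueError("non-finite null moments")
    if np.any(sds <= 0):
        raise ValueError("null sds must be positive")
    order = np.argsort(levels)
    levels, means, sds = levels[order], means[order], sds[order]
    x = np.log(levels.astype(float))
    lo, hi = float(x[0]), float(x[-1])

    if len(levels) < 4:
        m_const, s_const = float(means.mean()), float(np.exp(np.log(sds).mean()))
        mean_fn = lambda xs: np.full_like(np.asarray(xs, dtype=float), m_const)
        sd_fn = lambda xs: np.full_like(np.asarray(xs, dtype=float), s_const)
        return NullModel(mean_fn, sd_fn, (lo, hi), levels, means, sds)

    n_basis = max(4, min(spline_df + 1, len(levels)))
    mean_spl = _spline_fit(x, means, n_basis)
    # sd is fitted on the log scale; exponentiation keeps the curve positive
    logsd_spl = _spline_fit(x, np.log(sds), n_basis)

    def mean_fn(xs: np.ndarray) -> np.ndarray:
        return mean_spl(np.clip(np.asarray(xs, dtype=float), lo, hi))

    def sd_fn(xs: np.ndarray) -> np.ndarray:
        return np.maximum(np.exp(logsd_spl(np.clip(np.asarray(xs, dtype=float), lo, hi))), SD_FLOOR)

    return NullModel(mean_fn, sd_fn, (lo, hi), levels, means, sds)


def build_null_model(dm: DensityMatrix, q: np.ndarray, n_detected: np.ndarray,
                     cfg: RandomizationConfig,
                     weights: np.ndarray | None = None) -> NullModel:
    """Randomize at chosen count levels and fit the spline null."""
    rng = np.random.default_rng(cfg.seed)
    levels = choose_count_levels(dm.n_cells, n_detected, cfg.n_count_levels)
    moments = [randomized_divergences(int(lv), dm, q, cfg, rng, weights) for lv in levels]
    means = np.array([m for m, _ in moments])
    sds = np.array([s for _, s in moments])
    if len(levels) < 4:
        logger.warning("only %d distinct count levels; using constant null model", len(levels))
    return fit_null_model(levels, means, sds, cfg.spline_df)


def adjust_bh(log10_pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up executed on log10 p-values.

    Equivalent to adjusting the raw p-values (adj_i = min over j >= i of
    p_(j) * m / j, capped at 1) but immune to underflow.
    """
    lp = np.asarray(log10_pvals, dtype=float)
    m = len(lp)
    if m == 0:
        return lp.copy()
    order = np.argsort(lp, kind="stable")
    ranked = lp[order] + np.log10(m / np.arange(1, m + 1))
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 0.0)
    out = np.empty(m)
    out[order] = adj
    return out


def p_values(scores: list[DivergenceScore], model: NullModel) -> pd.DataFrame:
    """Result table with log10 p-values, BH adjustment and ranks."""
    genes = np.array([s.gene_id for s in scores], dtype=object)
    dkl = np.array([s.d_kl for s in scores], dtype=float)
    nd = np.array([s.n_detected for s in scores], dtype=int)
    ln_n = np.log(nd.astype(float))
    z = (np.log(dkl) - model.mean_curve(ln_n)) / model.sd_curve(ln_n)
    log10_p = log_ndtr(-z) / LN10
    log10_adj = adjust_bh(log10_p)
    order = np.lexsort((-dkl, log10_p))
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    res = pd.DataFrame({
        "gene": genes,
        "d_kl": dkl,
        "n_detected": nd,
        "log10_pval": log10_p,
        "log10_pval_adj": log10_adj,
        "rank": rank,
    })[RESULT_COLUMNS]
    return res.sort_values("rank").reset_index(drop=True)
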