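"""Synthetic scRNA-seq benchmark: cluster/path datasets with known DEGs.

The generator emulates the Splatter family of simulations: log-normal gene
baseline means, multiplicative per-cluster differential-expression factors
for a chosen subset of genes, per-cell library-size factors, and negative
binomial counts. In path mode, cluster mean vectors are connected by
randomly wired paths and each cell sits at a uniform pseudotime along its
cluster's incoming path, yielding gradual rather than discrete structure.

Ground truth follows the benchmark convention for such data: each gene's DE
score is the sum over clusters of |log2(DE factor)|, and the ``n_deg`` genes
with the highest score (ties broken by gene index) are the true DEGs.
Rankings are evaluated by ROC AUC in the Mann-Whitney form: the probability
that a random true DEG outranks a random non-DEG, ties counting one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix
from scipy.stats import rankdata

from .io import EmbeddingCoordinates, ExpressionMatrix

#: (n_cells, n_clusters) pairs of the standard benchmark series, from small
#: and simple to large and complex.
BENCHMARK_SIZES = [
    (1000, 2), (2000, 3), (3000, 4), (4000, 5), (5000, 6),
    (6000, 8), (7000, 10), (8000, 15), (9000, 20), (10000, 25),
]


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    cluster_of_cell: np.ndarray
    de_factor: np.ndarray  # (n_genes, n_clusters), 1 = no effect
    de_score: np.ndarray
    truth: np.ndarray  # boolean per gene

    @property
    def gene_ids(self) -> np.ndarray:
        return self.counts.gene_ids


def simulate_dataset(
    n_cells: int,
    n_clusters: int,
    n_genes: int = 5000,
    n_deg: int = 100,
    de_strength: float = 1.0,
    paths: bool = False,
    seed: int = 0,
    de_prob: float = 0.1,
    dispersion: float = 0.5,
    libsize_sigma: float = 0.25,
) -> SyntheticDataset:
    """Simulate a cluster (or path) dataset with ground-truth DEGs.

    Parameters
    ----------
    de_strength
        Scale of log DE factors: affected (gene, cluster) pairs receive a
        multiplicative factor exp(+-de_strength * |N(0,1)|) with random
        sign. 0 disables all differential expression.
    de_prob
        Probability that a given gene is differentially expressed in a given
        cluster (each gene x cluster pair selected independently, as in the
        Splatter family). The truth set is the ``n_deg`` genes with the
        highest DE score among this pool, so truth genes carry the strongest
        effects rather than arbitrary ones.
    paths
        Interpolate cluster means along randomly wired paths (cluster k > 0
        branches off a uniformly chosen earlier cluster) with per-cell
        uniform pseudotime, emulating differentiation trajectories.
    dispersion
        Negative binomial dispersion; variance = mu + dispersion * mu^2.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if not 0 <= n_deg <= n_genes:
        raise ValueError("n_deg must lie in [0, n_genes]")
    if n_cells < n_clusters:
        raise ValueError("need at least one cell per cluster")
    if not 0 <= de_prob <= 1:
        raise ValueError("de_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    base_mean = rng.lognormal(mean=-1.0, sigma=1.0, size=n_genes)

    de_factor = np.ones((n_genes, n_clusters))
    affected = rng.random((n_genes, n_clusters)) < de_prob
    n_aff = int(affected.sum())
    signs = rng.choice([-1.0, 1.0], size=n_aff)
    de_factor[affected] = np.exp(signs * de_strength * np.abs(rng.standard_normal(n_aff)))

    cluster_of_cell = rng.integers(0, n_clusters, size=n_cells)
    libsize = rng.lognormal(mean=0.0, sigma=libsize_sigma, size=n_cells)
    cluster_mean = base_mean[:, None] * de_factor  # (n_genes, n_clusters)

    if paths:
        path_from = np.zeros(n_clusters, dtype=int)
        for k in range(1, n_clusters):
            path_from[k] = rng.integers(0, k)
        u = rng.random(n_cells)
        mu = ((1 - u) * cluster_mean[:, path_from[cluster_of_cell]]
              + u * cluster_mean[:, cluster_of_cell])
    else:
        mu = cluster_mean[:, cluster_of_cell]
    mu = mu * libsize

    shape = 1.0 / dispersion
    counts = rng.negative_binomial(shape, shape / (shape + mu)).astype(float)

    de_score = np.abs(np.log2(de_factor)).sum(axis=1)
    order = np.lexsort((np.arange(n_genes), -de_score))
    truth = np.zeros(n_genes, dtype=bool)
    truth[order[:n_deg]] = True

    genes = np.array([f"gene{i + 1}" for i in range(n_genes)], dtype=object)
    cells = np.array([f"cell{i + 1}" for i in range(n_cells)], dtype=object)
    expr = ExpressionMatrix(genes, cells, counts)
    return SyntheticDataset(expr, cluster_of_cell, de_factor, de_score, truth)


def embed_for_test(ds: SyntheticDataset, n_dims: int = 10, seed: int = 0) -> EmbeddingCoordinates:
    """PCA embedding of log1p counts, standing in for a toolkit's PC space.

    Genes are centered and cells projected onto the top ``n_dims``
    components; the sign of each component is fixed so that its
    largest-magnitude gene loading is positive, making the output
    deterministic for a given seed.
    """
    from sklearn.decomposition import PCA

    if n_dims > min(ds.counts.n_genes, ds.counts.n_cells):
        raise ValueError("n_dims too large for this dataset")
    x = np.log1p(ds.counts.values.T)  # cells x genes
    pca = PCA(n_components=n_dims, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(x)
    for j in range(n_dims):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1
    return EmbeddingCoordinates(ds.counts.cell_ids, scores, f"pca{n_dims}")


def evaluate_auc(result: pd.DataFrame, truth: pd.Series) -> float:
    """ROC AUC of a gene ranking against boolean truth labels.

    ``truth`` is indexed by gene id and covers the full simulated gene set;
    genes missing from ``result`` (e.g. dropped by detection filtering) are
    assigned a shared worst rank, so discarding true DEGs is penalized.
    """
    truth = truth.astype(bool)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == len(truth):
        raise ValueError("truth must contain both classes")
    worst = len(truth) + 1
    rank_of = pd.Series(result["rank"].to_numpy(), index=result["gene"]).reindex(
        truth.index, fill_value=worst)
    # higher score = better rank; average ranks handle the shared worst rank
    r = rankdata(-rank_of.to_numpy())
    pos = truth.to_numpy()
    n_neg = len(truth) - n_pos
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def simulate_depth_gradient(
    n_cells: int = 1500,
    n_background: int = 400,
    n_special: int = 100,
    seed: int = 7,
):
    """2D dataset whose per-cell detected-gene totals form a spatial gradient.

    Background genes are detected per cell with probability following a
    linear gradient along x, so total detection depth varies smoothly across
    the space. Two probe genes are added, each detected in ``n_special``
    cells: ``"track"`` samples its cells proportionally to the depth
    gradient (its pattern merely mirrors detection depth) and ``"anti"``
    samples against it. The advanced mode should discount "track" and
    sharpen "anti" relative to the default mode.

    Returns
    -------
    (DetectionMatrix, EmbeddingCoordinates) with gene ids ``bg*``,
    ``track`` and ``anti``.
    """
    from .detection import DetectionMatrix

    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n_cells)
    y = rng.uniform(0, 1, n_cells)
    cells = np.array([f"cell{i + 1}" for i in range(n_cells)], dtype=object)
    emb = EmbeddingCoordinates(cells, np.column_stack([x, y]), "spatial")

    grad = 0.15 + 0.7 * x
    det = rng.random((n_background, n_cells)) < grad[None, :]
    track = np.zeros(n_cells, dtype=bool)
    track[rng.choice(n_cells, n_special, replace=False, p=grad / grad.sum())] = True
    inv = 1.0 - grad
    anti = np.zeros(n_cells, dtype=bool)
    anti[rng.choice(n_cells, n_special, replace=False, p=inv / inv.sum())] = True

    det = np.vstack([det, track[None], anti[None]])
    genes = np.array([f"bg{i + 1}" for i in range(n_background)] + ["track", "anti"],
                     dtype=object)
    return DetectionMatrix(genes, cells, det), emb


def write_dataset(ds: SyntheticDataset, out_prefix: str | Path) -> dict[str, Path]:
    """Write counts (mtx triplet + label files), clusters, truth and DE scores."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": prefix.with_suffix(".mtx"),
        "genes": prefix.with_suffix(".genes.txt"),
        "cells": prefix.with_suffix(".cells.txt"),
        "clusters": Path(str(prefix) + ".clusters.tsv"),
        "truth": Path(str(prefix) + ".truth.tsv"),
        "de_score": Path(str(prefix) + ".de_score.tsv"),
    }
    mmwrite(paths["mtx"], coo_matrix(ds.counts.values), field="integer")
    paths["genes"].write_text("\n".join(map(str, ds.counts.gene_ids)) + "\n")
    paths["cells"].write_text("\n".join(map(str, ds.counts.cell_ids)) + "\n")
    pd.DataFrame({"cell": ds.counts.cell_ids, "cluster": ds.cluster_of_cell + 1}).to_csv(
        paths["clusters"], sep="\t", index=False)
    pd.DataFrame({"gene": ds.gene_ids, "is_deg": ds.truth.astype(int)}).to_csv(
        paths["truth"], sep="\t", index=False)
    pd.DataFrame({"gene": ds.gene_ids, "de_score": ds.de_score}).to_csv(
        paths["de_score"], sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> pd.Series:
    """Read a truth TSV (columns gene, is_deg) into a boolean Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["is_deg"].astype(bool).to_numpy(), index=df["gene"])
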