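"""Grouping of significant genes by their expression-distribution profiles.

Genes picked up by the divergence scan often fall into a handful of broad
expression patterns (e.g. restricted to one region of the embedding, or
excluded from it). Clustering the per-gene P(G=T) profiles over grid points
summarizes these patterns and supports a "most significant gene per group"
style report.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .detection import DetectionMatrix
from .grid import DensityMatrix, _normalize

logger = logging.getLogger("divergescan")


def gene_profiles(gene_ids, det: DetectionMatrix, dm: DensityMatrix,
                  q: np.ndarray | None = None) -> pd.DataFrame:
    """Normalized P(G=T) profile of each requested gene over grid points.

    When ``q`` is given, a companion ratio table P(G=T)/Q - the quantity
    used to color grid points in expression-distribution plots - can be
    derived by dividing rows by q; here rows are the normalized profiles.
    """
    pos = {g: i for i, g in enumerate(det.gene_ids)}
    missing = [g for g in gene_ids if g not in pos]
    if missing:
        raise KeyError(f"unknown gene ids: {missing[:5]}")
    idx = np.array([pos[g] for g in gene_ids])
    t_raw = det.detected[idx].astype(float) @ dm.weights
    profiles = _normalize(t_raw)
    df = pd.DataFrame(profiles, index=list(gene_ids))
    if q is not None:
        df.attrs["ratio"] = profiles / np.asarray(q, dtype=float)
    return df


def cluster_genes(profiles: pd.DataFrame, k: int, method: str = "hierarchical",
                  seed: int = 0) -> pd.DataFrame:
    """Cluster gene profiles into k groups.

    hierarchical: average linkage on correlation distance (1 - Pearson over
    grid points); zero-variance rows force a Euclidean fallback with a
    warning. kmeans: seeded k-means on the raw profiles. Labels are renumbered
    so cluster 1 is the largest.
    """
    x = profiles.to_numpy(dtype=float)
    if k > len(x):
        raise ValueError("k cannot exceed the number of genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if method == "hierarchical":
        metric = "correlation"
        if np.any(x.std(axis=1) == 0):
            logger.warning("constant profile rows: falling back to Euclidean distance")
            metric = "euclidean"
        labels = fcluster(linkage(pdist(x, metric=metric), method="average"),
                          t=k, criterion="maxclust")
    elif method == "kmeans":
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # relabel to decreasing cluster size, ties by original label
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    labels = np.array([remap[l] for l in labels])
    return pd.DataFrame({"gene": profiles.index, "cluster": labels})
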