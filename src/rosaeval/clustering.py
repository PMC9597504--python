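"""Hierarchical clustering of accessions and K-means trend classification.

Accession tables (morphological characters, fragrance panel contents) are
clustered on Euclidean distances with Ward's minimum-variance criterion,
the convention for germplasm phenograms. Stage profiles of differential
compounds are classified into trend classes with K-means on row-
standardized four-stage profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ValidationError


def standardize_mixed(table: pd.DataFrame, exclude: tuple[str, ...] = ("accession_id", "group")) -> pd.DataFrame:
    """Standardize a mixed-type trait table for Euclidean distances.

    Continuous and ordinal columns are z-scored (sample sd); binary
    columns (values within {0, 1}) are left on their natural 0/1 scale.
    Constant columns become all-zero.
    """
    numeric = table.drop(columns=[c for c in exclude if c in table.columns])
    out = {}
    for col in numeric.columns:
        v = numeric[col].to_numpy(dtype=float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            out[col] = v
        else:
            sd = v.std(ddof=1)
            out[col] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    return pd.DataFrame(out, index=table.index)


def distance_matrix(table: pd.DataFrame, variables: list[str] | None = None) -> np.ndarray:
    """Symmetric Euclidean distance matrix over the given numeric columns."""
    data = table[variables] if variables is not None else table
    try:
        x = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric column in distance computation: {exc}") from exc
    if np.isnan(x).any():
        raise ValidationError("distance computation requires complete numeric data")
    return squareform(pdist(x, metric="euclidean"))


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: a linkage table plus leaf labels.

    ``merges`` follows the SciPy convention: row ``i`` merges clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` (ids < n are leaves, id n+i is
    the cluster formed at step i) at height ``merges[i, 2]`` into a
    cluster of ``merges[i, 3]`` members. Under Ward linkage on Euclidean
    input the heights are non-decreasing.
    """

    merges: np.ndarray  # (n-1) x 4 linkage matrix
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ward_hclust(dist: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Ward minimum-variance agglomeration of a Euclidean distance matrix.

    Uses the Ward.D2 criterion (the merge height is the square root of
    twice the increase in within-cluster sum of squares), which matches
    the "sums of squared deviations" reading of Ward's method on
    Euclidean distances.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("label count does not match matrix size")
    z = sch.linkage(squareform(d, checks=False), method="ward")
    return Dendrogram(merges=z, labels=tuple(labels))


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels (1..k) at the k-cluster level of the tree."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    return sch.fcluster(dendrogram.merges, t=k, criterion="maxclust")


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch heights."""
    tree = sch.to_tree(dendrogram.merges)
    labels = dendrogram.labels

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# K-means trend classification


@dataclass(frozen=True)
class TrendClassification:
    """Per-compound trend classes over the four flower-development stages."""

    classes: pd.Series  # compound -> class id (1..k)
    centroids: np.ndarray  # k x 4 standardized centroid profiles
    sse: float  # total within-cluster sum of squares


def stage_profiles(voc: pd.DataFrame, compounds: list[str] | None = None) -> pd.DataFrame:
    """Compound x stage mean-concentration profiles, row-standardized.

    Concentrations are averaged over cultivars and replicates per stage,
    then each compound's profile is z-scored across stages (population
    sd), matching the usual standardized relative-content display.
    Constant profiles become all-zero rows.
    """
    sub = voc if compounds is None else voc[voc["compound"].isin(compounds)]
    if sub.empty:
        raise ValidationError("no records to profile")
    prof = sub.pivot_table(index="compound", columns="stage", values="concentration", aggfunc="mean")
    x = prof.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=prof.index, columns=prof.columns)


def kmeans_trends(profiles: pd.DataFrame, k: int = 9, seed: int = 0, n_init: int = 50) -> TrendClassification:
    """Classify standardized stage profiles into ``k`` trend classes.

    Lloyd's algorithm, best of ``n_init`` seeded restarts by SSE;
    deterministic given ``seed``. The default ``k = 9`` mirrors the nine
    trend classes typically distinguished over four stages (rises, falls,
    single-stage peaks, plateaus); it is a display choice, not an
    estimate, and should be overridden when fewer shapes are expected.
    """
    x = profiles.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of profiles ({x.shape[0]})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed), algorithm="lloyd")
    assign = km.fit_predict(x)
    return TrendClassification(
        classes=pd.Series(assign + 1, index=profiles.index, name="trend_class"),
        centroids=km.cluster_centers_,
        sse=float(km.inertia_),
    )
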