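"""Row z-normalization, k-means clustering, and PCA.

Clustering operates on the filter-passing significant features: each feature
row is z-normalized across samples, (x - row mean) / row SD, and Euclidean
k-means with k-means++ seeding groups features with a shared tissue/group
abundance pattern.  PCA is applied to the full (unscaled, column-centered)
matrix for a sample-level overview; in this design tissue identity, not
colonization status, is expected to dominate the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import InputError


@dataclass
class NormalizedMatrix:
    """Row z-scores plus the rows excluded for zero spread.

    ``matrix`` holds only the retained rows; ``excluded`` lists the row
    labels whose standard deviation was zero (a constant row carries no
    pattern and cannot be z-scored).
    """

    matrix: pd.DataFrame
    excluded: list
    ddof: int = 1


def z_normalize_rows(matrix: pd.DataFrame | np.ndarray, ddof: int = 1) -> NormalizedMatrix:
    """Z-score each row: (x - row mean) / row SD.

    ``ddof=1`` (sample SD) is the default convention; ``ddof=0`` switches to
    the population SD, which rescales every row by the same factor
    sqrt(n/(n-1)).  Rows with zero SD are excluded and reported.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise InputError("z-normalization needs at least 2 columns")
    vals = df.to_numpy()
    if not np.isfinite(vals).all():
        raise InputError("matrix must be finite for z-normalization")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    keep = (sd > 0).ravel()
    z = (vals[keep] - mean[keep]) / sd[keep]
    out = pd.DataFrame(z, index=df.index[keep], columns=df.columns)
    return NormalizedMatrix(out, list(df.index[~keep]), ddof=ddof)


@dataclass
class ClusterModel:
    """Fitted k-means model: one assignment per clustered feature.

    Cluster ids run 1..k; ids that ended up empty are listed rather than
    silently dropped.
    """

    k: int
    assignments: pd.Series
    centroids: np.ndarray
    inertia: float
    seed: int
    n_restarts: int
    empty_clusters: list[int] = field(default_factory=list)


def kmeans_clusters(
    normalized: NormalizedMatrix | pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterModel:
    """Euclidean k-means over z-normalized feature rows.

    Uses k-means++ initialization with ``n_restarts`` restarts, keeping the
    solution with the smallest within-cluster sum of squares; the seed makes
    the fit deterministic.
    """
    df = normalized.matrix if isinstance(normalized, NormalizedMatrix) else pd.DataFrame(normalized)
    if k < 1:
        raise InputError("k must be at least 1")
    if df.shape[0] < k:
        raise InputError(f"cannot form {k} clusters from {df.shape[0]} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(df.to_numpy())
    assignments = pd.Series(labels + 1, index=df.index, name="cluster")
    present = set(assignments.unique())
    empty = [c for c in range(1, k + 1) if c not in present]
    return ClusterModel(
        k=k,
        assignments=assignments,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
        empty_clusters=empty,
    )


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the principal axes of the column-centered matrix.

    ``matrix`` is features x samples (the pipeline's native orientation);
    samples are the observations, so the input is transposed and each
    feature column is mean-centered but not variance-scaled (unscaled PCA).
    Returns the sample scores and the explained-variance fractions.
    """
    df = pd.DataFrame(matrix).astype(float)
    vals = df.to_numpy().T  # samples x features
    if not np.isfinite(vals).all():
        raise InputError("matrix must be finite for PCA")
    n_components = int(n_components)
    if n_components < 1 or n_components > min(vals.shape):
        raise InputError("n_components must be in [1, min(n_samples, n_features)]")
    if np.allclose(vals.std(axis=0), 0):
        raise InputError("matrix is constant; PCA is undefined")
    model = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    scores = model.fit_transform(vals)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=df.columns, columns=cols), model.explained_variance_ratio_
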