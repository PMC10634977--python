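"""Embedding, density-based clustering, silhouette audit and cluster profiles.

Cells are embedded into 2-D with UMAP or t-SNE from their pruned, 0-1
rescaled marker intensities (counterstain channels excluded — the nuclear
stain is a reference, not a phenotype), then clustered with HDBSCAN on the
embedding; the label -1 marks unclustered (ambiguous) cells. Per-cell
silhouette scores in embedding space flag under-clustered populations
(negative scores). Cluster-mean marker profiles, row-normalized per marker
across clusters to [0, 1], feed agglomerative meta-clustering
(average linkage, Euclidean distance — the conventional clustermap defaults)
and downstream thumbnail galleries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import HDBSCAN
from sklearn.metrics import silhouette_samples

from .errors import InsufficientDataError, ParameterError
from .model import RedactionLog, SpatialFeatureTable

__all__ = [
    "ClusterResult",
    "ClusterProfile",
    "embed_cells",
    "cluster_cells",
    "silhouette_by_cell",
    "cluster_profile",
    "meta_cluster",
    "run_clustering",
]


@dataclass
class ClusterResult:
    """Per-cell clustering output for the retained cells."""

    keys: list[tuple[str, int]]
    labels: np.ndarray  # int, -1 = unclustered
    embedding: np.ndarray  # (n, 2)
    silhouette: np.ndarray  # per cell; 0 for unclustered / degenerate cases
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int((np.unique(self.labels) >= 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [k[0] for k in self.keys],
                "cell_id": [k[1] for k in self.keys],
                "cluster": self.labels,
                "umap_x": self.embedding[:, 0],
                "umap_y": self.embedding[:, 1],
                "silhouette": self.silhouette,
            }
        )


@dataclass
class ClusterProfile:
    """Cluster x marker mean-intensity matrix and its row-normalized form."""

    means: pd.DataFrame  # index: cluster label, columns: markers
    normalized: pd.DataFrame  # per marker min-max across clusters, in [0, 1]
    meta_labels: pd.Series | None = None  # per cluster
    linkage_matrix: np.ndarray | None = None


def embed_cells(
    features: np.ndarray | pd.DataFrame,
    method: str = "umap",
    seed: int = 0,
    n_neighbors: int = 15,
    perplexity: float = 30.0,
) -> np.ndarray:
    """2-D embedding of the feature matrix; deterministic under a fixed seed."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ParameterError("features must be a 2-D matrix")
    n = X.shape[0]
    if n < 10:
        raise InsufficientDataError(f"embedding needs >= 10 cells, got {n}")
    if method == "umap":
        import umap  # deferred: numba compilation is slow at import

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*n_jobs.*")
            warnings.filterwarnings("ignore", message=".*random_state.*")
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=min(n_neighbors, n - 1),
                random_state=int(seed),
            )
            return np.asarray(reducer.fit_transform(X), dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        tsne = TSNE(
            n_components=2,
            perplexity=min(perplexity, max(2.0, (n - 1) / 3)),
            random_state=int(seed),
            init="pca",
        )
        return np.asarray(tsne.fit_transform(X), dtype=float)
    raise ParameterError(f"unknown embedding method: {method}")


def cluster_cells(embedding: np.ndarray, min_cluster_size: int = 20) -> np.ndarray:
    """HDBSCAN on the 2-D embedding; labels -1 (unclustered) and 0..K-1."""
    if min_cluster_size < 2:
        raise ParameterError("min_cluster_size must be >= 2")
    emb = np.asarray(embedding, dtype=float)
    raw = HDBSCAN(min_cluster_size=int(min_cluster_size), copy=True).fit_predict(emb)
    # remap to contiguous labels ordered by first appearance (determinism)
    out = np.full(raw.shape, -1, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab < 0:
            continue
        if lab not in seen:
            seen[lab] = next_label
            next_label += 1
        out[i] = seen[lab]
    return out


def silhouette_by_cell(embedding: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Standard silhouette s(i) = (b - a) / max(a, b) in embedding space.

    Unclustered cells (-1) are excluded from the computation and reported as
    0, as are cells in singleton clusters. With fewer than two clusters all
    scores are 0 and a warning is issued.
    """
    labels = np.asarray(labels)
    emb = np.asarray(embedding, dtype=float)
    scores = np.zeros(len(labels), dtype=float)
    clustered = labels >= 0
    uniq = np.unique(labels[clustered])
    if uniq.size < 2:
        warnings.warn(
            "silhouette undefined with fewer than 2 clusters; reporting 0",
            stacklevel=2,
        )
        return scores
    scores[clustered] = silhouette_samples(emb[clustered], labels[clustered])
    # singleton clusters: convention 0 (sklearn already returns 0 for these)
    counts = pd.Series(labels[clustered]).value_counts()
    singletons = set(counts[counts < 2].index)
    if singletons:
        scores[np.isin(labels, list(singletons))] = 0.0
    return scores


def run_clustering(
    table: SpatialFeatureTable,
    log: RedactionLog,
    method: str = "umap",
    seed: int = 0,
    n_neighbors: int = 15,
    perplexity: float = 30.0,
    min_cluster_size: int = 20,
) -> ClusterResult:
    """Embed -> cluster -> silhouette on the retained cells' marker features."""
    retained = log.retained_mask(table)
    feats = table.data.loc[retained, table.feature_marker_names]
    keys = [k for k, r in zip(table.keys(), retained) if r]
    emb = embed_cells(
        feats, method=method, seed=seed,
        n_neighbors=n_neighbors, perplexity=perplexity,
    )
    labels = cluster_cells(emb, min_cluster_size=min_cluster_size)
    sil = silhouette_by_cell(emb, labels)
    return ClusterResult(
        keys=keys,
        labels=labels,
        embedding=emb,
        silhouette=sil,
        params={
            "method": method,
            "seed": seed,
            "min_cluster_size": min_cluster_size,
            "n_neighbors": n_neighbors,
        },
    )


def cluster_profile(
    features: pd.DataFrame, labels: np.ndarray, markers: list[str] | None = None
) -> ClusterProfile:
    """Cluster-mean intensities and their per-marker min-max normalization.

    Only clustered cells (label >= 0) contribute. Normalization maps, for
    each marker, the minimum cluster mean to 0 and the maximum to 1; a marker
    constant across clusters maps to all zeros.
    """
    labels = np.asarray(labels)
    cols = markers if markers is not None else list(features.columns)
    clustered = labels >= 0
    if not clustered.any():
        raise ParameterError("no clustered cells (all labels are -1)")
    sub = features.loc[clustered, cols].copy()
    sub["_cluster"] = labels[clustered]
    means = sub.groupby("_cluster").mean()
    means.index.name = "cluster"
    norm = means.copy()
    for c in cols:
        lo, hi = means[c].min(), means[c].max()
        norm[c] = 0.0 if hi == lo else (means[c] - lo) / (hi - lo)
    return ClusterProfile(means=means, normalized=norm)


def meta_cluster(profile: ClusterProfile, k: int) -> ClusterProfile:
    """Agglomerative meta-clustering of the normalized cluster profiles.

    Average linkage on Euclidean distances; cutting the dendrogram at ``k``
    yields ``k`` meta-clusters, labelled 0..k-1 in order of first appearance
    along the cluster index.
    """
    n = len(profile.normalized)
    if k < 1 or k > n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    if n == 1 or k == 1:
        profile.meta_labels = pd.Series(
            0, index=profile.normalized.index, name="meta"
        )
        profile.linkage_matrix = (
            linkage(profile.normalized.to_numpy(), method="average") if n > 1 else None
        )
        return profile
    Z = linkage(profile.normalized.to_numpy(), method="average", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    profile.meta_labels = pd.Series(out, index=profile.normalized.index, name="meta")
    profile.linkage_matrix = Z
    return profile
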