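"""Discrete regions of origin from individual assignment surfaces.

Two complementary routes are provided.  The non-spatial route compares
individuals directly: Schoener's D (1 − ½ Σ|p_a − p_b|) measures the
similarity of two normalized probability surfaces, a cell-resampling
bootstrap attaches uncertainty to the pairwise similarity matrix, and
average-linkage hierarchical clustering on correlation distances between
similarity profiles — with the dendrogram cut at a fixed height — groups
individuals with similar likely origins.  The spatial route clusters the
raster cells themselves: each valid cell is described by the (z-scored,
optionally PCA-reduced) per-individual likelihoods plus its planar
coordinates scaled by a geographic weight between 1 and 100, and k-means
partitions the map into contiguous candidate molt regions.  Zonal maximum
likelihood then allocates each individual to the region where its surface
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .assignment import AssignmentSurface
from .raster import RasterGrid

__all__ = [
    "SimilarityMatrix",
    "ClusterMap",
    "schoeners_d",
    "similarity_matrix",
    "hclust_cut",
    "spatial_kmeans",
    "zonal_max_membership",
    "population_cluster_proportions",
]

#: Dendrogram cut height on correlation distance; 0.5 trades off too many
#: vs. too few candidate regions of origin.
DEFAULT_CUT_HEIGHT = 0.5

#: Geographic weighting default, middle of the 10–20 range used in practice.
DEFAULT_GEO_WEIGHT = 15.0


@dataclass
class SimilarityMatrix:
    """Pairwise Schoener's D between individuals, with bootstrap SDs."""

    ids: list[str]
    values: np.ndarray          # n×n, symmetric, unit diagonal, in [0, 1]
    boot_sd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ClusterMap:
    """Raster of integer cluster labels (1..k on valid cells, 0 elsewhere)."""

    labels: RasterGrid
    k: int

    def __post_init__(self) -> None:
        lab = self.labels.values[self.labels.mask]
        present = np.unique(lab.astype(int))
        if not np.all((present >= 1) & (present <= self.k)):
            raise ValueError("labels on valid cells must lie in 1..k")
        if len(present) != self.k:
            raise ValueError("every cluster 1..k must be nonempty")

    def zone_indices(self, cluster_id: int) -> np.ndarray:
        """Flat indices of the cells belonging to one cluster."""
        flat = np.nan_to_num(self.labels.values, nan=0.0).astype(int).ravel()
        return np.flatnonzero(flat == cluster_id)


def _prob_matrix(surfaces: Sequence[AssignmentSurface]) -> tuple[np.ndarray, np.ndarray]:
    """Stack surfaces into an (n_surfaces, n_valid_cells) matrix."""
    first = surfaces[0].prob
    for s in surfaces[1:]:
        first.require_same_geometry(s.prob, check_mask=True)
    idx = np.flatnonzero(first.mask.ravel())
    P = np.stack([s.prob.values.ravel()[idx] for s in surfaces])
    return P, idx


def schoeners_d(a: AssignmentSurface, b: AssignmentSurface) -> float:
    """Schoener's D between two normalized surfaces: 1 − ½ Σ|p_a − p_b|.

    1 means identical surfaces, 0 means spatially disjoint ones.
    """
    a.prob.require_same_geometry(b.prob, check_mask=True)
    pa = a.prob.values[a.prob.mask]
    pb = b.prob.values[b.prob.mask]
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def similarity_matrix(
    surfaces: Sequence[AssignmentSurface],
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> SimilarityMatrix:
    """Pairwise Schoener's D with a cell-resampling bootstrap.

    The point estimate is D on the full surfaces.  Each bootstrap replicate
    resamples the valid cells with replacement, renormalizes every surface
    over the resampled cells, and recomputes all pairwise D; ``boot_sd`` is
    the elementwise SD over replicates.  Deterministic under a fixed seed.
    """
    if len(surfaces) < 2:
        raise ValueError("similarity_matrix requires at least two surfaces")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    P, _ = _prob_matrix(surfaces)
    ids = [s.individual_id for s in surfaces]

    def _pairwise_d(mat: np.ndarray) -> np.ndarray:
        d = 1.0 - 0.5 * cdist(mat, mat, metric="cityblock")
        np.fill_diagonal(d, 1.0)
        return np.clip(d, 0.0, 1.0)

    point = _pairwise_d(P)
    rng = np.random.default_rng(seed)
    m = P.shape[1]
    boots = np.empty((n_boot, len(ids), len(ids)))
    for b in range(n_boot):
        cells = rng.integers(0, m, size=m)
        Pb = P[:, cells]
        sums = Pb.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        boots[b] = _pairwise_d(Pb / sums)
    return SimilarityMatrix(ids=ids, values=point, boot_sd=boots.std(axis=0))


def hclust_cut(
    sim: SimilarityMatrix,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    linkage: str = "average",
) -> dict[str, int]:
    """Cluster individuals from their similarity profiles.

    Distance between individuals i and j is one minus the Pearson
    correlation of their rows of the similarity matrix; rows with zero
    variance (undefined correlation) get distance 1 to everything.  An
    agglomerative tree (average linkage by default) is cut so that all
    merges above ``cut_height`` are broken.  Returns id → cluster label
    (labels 1..k by first appearance in input order).
    """
    n = len(sim.ids)
    if n < 2:
        raise ValueError("hclust_cut requires at least two individuals")
    rows = sim.values - sim.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    constant = norms == 0
    safe_norms = np.where(constant, 1.0, norms)
    corr = (rows / safe_norms[:, None]) @ (rows / safe_norms[:, None]).T
    dist = 1.0 - corr
    # undefined correlations (constant profiles) → maximal distance
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    # relabel deterministically by first appearance
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for ident, lab in zip(sim.ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels[ident] = relabel[lab]
    return labels


def spatial_kmeans(
    surfaces: Sequence[AssignmentSurface],
    k: int,
    geo_weight: float = DEFAULT_GEO_WEIGHT,
    seed: int | None = 0,
    max_components: int = 10,
) -> ClusterMap:
    """Partition the map into k spatially coherent candidate regions.

    Each valid cell is described by the per-individual likelihoods at that
    cell (z-scored per individual across cells, PCA-reduced to at most
    ``max_components``) concatenated with its z-scored planar coordinates
    scaled by ``geo_weight/100 · √(feature dimension)``.  ``geo_weight`` runs
    from 1 (geography barely matters) to 100 (maximally spatially
    constrained clusters).  Labels are renumbered 1..k by descending
    cluster size; deterministic under a fixed seed.
    """
    if not surfaces:
        raise ValueError("spatial_kmeans requires at least one surface")
    if not 1 <= geo_weight <= 100:
        raise ValueError("geo_weight must be between 1 and 100")
    P, idx = _prob_matrix(surfaces)
    n_cells = P.shape[1]
    if k < 1 or k > n_cells:
        raise ValueError(f"k must be in 1..{n_cells}")

    feats = P.T  # cells × individuals
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    feats = (feats - mean) / std
    if feats.shape[1] > max_components:
        feats = PCA(n_components=max_components, random_state=seed).fit_transform(feats)

    grid = surfaces[0].prob
    xs, ys = grid.cell_centers()
    coords = np.column_stack([xs.ravel()[idx], ys.ravel()[idx]])
    cmean = coords.mean(axis=0)
    cstd = coords.std(axis=0)
    cstd[cstd == 0] = 1.0
    coords = (coords - cmean) / cstd
    coords *= (geo_weight / 100.0) * np.sqrt(feats.shape[1])

    X = np.hstack([feats, coords])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # relabel 1..k by descending cluster size (ties by original label)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels_flat = np.zeros(grid.shape[0] * grid.shape[1])
    labels_flat[idx] = remap[raw]
    labels = grid.copy_with(values=labels_flat.reshape(grid.shape))
    return ClusterMap(labels=labels, k=k)


def zonal_max_membership(
    surfaces: Sequence[AssignmentSurface],
    clusters: ClusterMap,
) -> pd.DataFrame:
    """Allocate individuals to clusters by zonal maximum likelihood.

    For each individual and cluster, the maximum of the probability surface
    within the cluster's cells is taken; the individual is assigned to the
    argmax cluster (ties go to the lowest cluster id).  Returns a DataFrame
    with one row per individual: ``id``, ``cluster``, and ``max_c{j}``
    columns with the per-cluster maxima.
    """
    if not surfaces:
        raise ValueError("zonal_max_membership requires at least one surface")
    clusters.labels.require_same_geometry(surfaces[0].prob)
    zone_idx = [clusters.zone_indices(j) for j in range(1, clusters.k + 1)]
    if all(len(z) == 0 for z in zone_idx):
        raise ValueError("cluster map has no labelled cells")
    rows = []
    for s in surfaces:
        flat = np.nan_to_num(s.prob.values, nan=0.0).ravel()
        maxima = np.array([flat[z].max() if len(z) else 0.0 for z in zone_idx])
        assigned = int(np.argmax(maxima)) + 1  # argmax takes lowest index on ties
        rows.append({"id": s.individual_id, "cluster": assigned,
                     **{f"max_c{j + 1}": maxima[j] for j in range(clusters.k)}})
    return pd.DataFrame(rows)


def population_cluster_proportions(
    id_to_population: Mapping[str, str],
    memberships: pd.DataFrame,
) -> pd.DataFrame:
    """Share of each population assigned to each cluster (rows sum to 1)."""
    df = memberships.copy()
    missing = sorted(set(df["id"]) - set(id_to_population))
    if missing:
        raise ValueError(f"ids missing from population mapping: {missing}")
    df["population"] = df["id"].map(id_to_population)
    counts = df.groupby(["population", "cluster"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
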