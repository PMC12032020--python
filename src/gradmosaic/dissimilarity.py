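"""Cosine-distance dissimilarity statistics on gradient profiles.

Inter-areal dissimilarity is the mean cosine distance between one area's
gradient profile and every other area's; intra-areal dissimilarity is the
cosine distance between each vertex's multimodal gradient vector and its
own area's mean profile. The complementary similarity (1 - cosine
distance) feeds hierarchical clustering of areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .arealization import AreaLabeling, GradientProfileMatrix
from .embedding import MultimodalGradients

__all__ = [
    "DissimilarityResult",
    "IntraArealResult",
    "cosine_distance",
    "inter_areal_dissimilarity",
    "intra_areal_dissimilarity",
    "similarity_affinity",
    "cluster_areas",
]

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityResult:
    """Area-by-area cosine distance matrix with per-area row means."""

    matrix: np.ndarray
    per_area: np.ndarray
    area_ids: np.ndarray
    kind: str = "inter"


@dataclass
class IntraArealResult:
    """Vertex-to-own-area-profile cosine distances and area summaries.

    ``per_area_size_adjusted`` holds residuals of a rank-based (Spearman
    style) linear fit of the per-area mean on area vertex count, exposed
    alongside the raw means because area size correlates positively with
    intra-areal dissimilarity.
    """

    per_vertex: np.ndarray          # NaN at unassigned vertices
    per_area_mean: np.ndarray
    per_area_size_adjusted: np.ndarray
    area_ids: np.ndarray
    singleton_areas: list


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """``1 - cos(a, b)``, in [0, 2]. Raises on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(a, b) / (na * nb))


def _pairwise_cosine(x: np.ndarray) -> np.ndarray:
    d = squareform(pdist(x, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return d


def inter_areal_dissimilarity(
    profiles: GradientProfileMatrix,
) -> DissimilarityResult:
    """Pairwise cosine distances between area profiles and their row means."""
    x = profiles.profiles
    if x.shape[0] < 2:
        raise ValueError("need at least 2 areas")
    zero = np.flatnonzero(np.linalg.norm(x, axis=1) == 0)
    if len(zero):
        bad = profiles.area_ids[zero].tolist()
        raise ValueError(f"zero-vector profiles for areas {bad}")
    d = _pairwise_cosine(x)
    n = d.shape[0]
    per_area = d.sum(axis=1) / (n - 1)
    return DissimilarityResult(
        matrix=d, per_area=per_area, area_ids=profiles.area_ids
    )


def size_adjust(per_area: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Residuals of a rank-based linear fit of a per-area statistic on size."""
    ry = rankdata(per_area)
    rx = rankdata(sizes)
    if len(ry) < 3 or np.ptp(rx) == 0:
        return ry - ry.mean()
    a = np.column_stack([rx, np.ones_like(rx)])
    beta, *_ = np.linalg.lstsq(a, ry, rcond=None)
    return ry - a @ beta


def intra_areal_dissimilarity(
    gradients: MultimodalGradients, labeling: AreaLabeling
) -> IntraArealResult:
    """Cosine distance of each vertex's gradients to its area's mean profile.

    Singleton areas trivially score 0 (a vertex equals its own mean) and
    are flagged. Unassigned vertices are NaN in ``per_vertex``.
    """
    v = gradients.values
    per_vertex = np.full(v.shape[0], np.nan)
    area_ids, means, adj_sizes, singletons = [], [], [], []
    for a in labeling.area_ids:
        idx = labeling.vertices_of(int(a))
        if len(idx) == 0:
            continue
        centroid = v[idx].mean(axis=0)
        if np.linalg.norm(centroid) == 0:
            raise ValueError(f"area {a}: zero mean profile")
        for i in idx:
            per_vertex[i] = cosine_distance(v[i], centroid)
        if len(idx) == 1:
            singletons.append(int(a))
        area_ids.append(a)
        means.append(per_vertex[idx].mean())
        adj_sizes.append(len(idx))
    per_area_mean = np.array(means)
    return IntraArealResult(
        per_vertex=per_vertex,
        per_area_mean=per_area_mean,
        per_area_size_adjusted=size_adjust(per_area_mean, np.array(adj_sizes)),
        area_ids=np.array(area_ids),
        singleton_areas=singletons,
    )


def similarity_affinity(profiles: GradientProfileMatrix) -> np.ndarray:
    """Entrywise ``1 - cosine distance`` between area profiles; diagonal 1."""
    d = inter_areal_dissimilarity(profiles).matrix
    return 1.0 - d


def cluster_areas(similarity: np.ndarray, k_min: int = 2, k_max: int = 10):
    """Average-linkage hierarchical clustering on ``1 - similarity``.

    The number of clusters is chosen by the maximum silhouette over
    ``[k_min, k_max]``; exact ties resolve to the smaller k.

    Returns
    -------
    labels : int array per area
    chosen_k : int
    criterion : dict k -> silhouette value
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n_areas")
    dist = 1.0 - s
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if np.ptp(dist[~np.eye(n, dtype=bool)]) == 0 and dist.max() == 0:
        raise ValueError("degenerate similarity: all areas identical")
    criterion, labelings = {}, {}
    for k in range(k_min, k_max + 1):
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        )
        lab = model.fit_predict(dist)
        try:
            criterion[k] = float(silhouette_score(dist, lab, metric="precomputed"))
        except ValueError:
            criterion[k] = -1.0
        labelings[k] = lab
    best = max(criterion.values())
    chosen_k = min(k for k, v in criterion.items() if v == best)
    return labelings[chosen_k], chosen_k, criterion
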