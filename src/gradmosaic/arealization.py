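"""From vertex gradients to area-wise gradient profiles.

Vertices are assigned to the highest-probability area of a probabilistic
atlas; vertex-wise multimodal gradients are then averaged within each area
to give the area-by-(3k) gradient profile matrix, and areas can be ordered
by the principal component of those profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embedding import MultimodalGradients
from .synthcortex import ProbabilisticAtlas

__all__ = [
    "AreaLabeling",
    "GradientProfileMatrix",
    "assign_area_labels",
    "compute_area_profiles",
    "pca_reorder",
]

logger = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class AreaLabeling:
    """Per-vertex area ids (``-1`` = unassigned) with area sizes."""

    label: np.ndarray
    area_ids: np.ndarray

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label)
        self.area_ids = np.asarray(self.area_ids)

    @property
    def area_sizes(self) -> dict:
        return {int(a): int((self.label == a).sum()) for a in self.area_ids}

    def vertices_of(self, area_id: int) -> np.ndarray:
        return np.flatnonzero(self.label == area_id)


@dataclass
class GradientProfileMatrix:
    """Area-by-(3k) mean gradient profiles."""

    profiles: np.ndarray
    area_ids: np.ndarray
    k_per_modality: int
    column_names: list

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.area_ids = np.asarray(self.area_ids)
        if not np.isfinite(self.profiles).all():
            raise ValueError("non-finite profile entries")
        if self.profiles.shape[0] != len(self.area_ids):
            raise ValueError("row count inconsistent with area_ids")


def assign_area_labels(atlas: ProbabilisticAtlas) -> AreaLabeling:
    """Argmax labeling of a probabilistic atlas.

    Each vertex gets the area with the highest probability; all-zero
    columns (mid-wall) are unassigned; exact ties go to the lowest area
    index.
    """
    return AreaLabeling(label=atlas.argmax_labels(), area_ids=atlas.area_ids)


def compute_area_profiles(
    gradients: MultimodalGradients, labeling: AreaLabeling
) -> GradientProfileMatrix:
    """Mean multimodal gradient vector per area.

    Unassigned vertices are excluded; areas left without any assigned
    vertex are dropped with a warning.
    """
    if gradients.values.shape[0] != len(labeling.label):
        raise ValueError("gradients and labeling disagree on vertex count")
    kept_ids, rows = [], []
    for a in labeling.area_ids:
        idx = labeling.vertices_of(int(a))
        if len(idx) == 0:
            logger.warning("area %s has no assigned vertices; dropped", a)
            continue
        kept_ids.append(a)
        rows.append(gradients.values[idx].mean(axis=0))
    return GradientProfileMatrix(
        profiles=np.array(rows),
        area_ids=np.array(kept_ids),
        k_per_modality=gradients.k_per_modality,
        column_names=gradients.column_names,
    )


def pca_reorder(profiles: GradientProfileMatrix):
    """Order areas along the principal component of their profiles.

    Columns are centered, PCA is taken via SVD, areas are sorted by
    ascending PC1 score, and the PC1 sign is fixed so the largest-|score|
    area scores positive.

    Returns
    -------
    ordering : int array
        Row indices into ``profiles.profiles`` sorted by PC1 score.
    pc1_scores : float array
        Per-area PC1 scores in the original area order.
    variance_explained : float array
        Variance fraction of every component (sums to 1).
    """
    x = profiles.profiles
    if x.shape[0] < 2:
        raise ValueError("need at least 2 areas")
    xc = x - x.mean(axis=0)
    if not np.any(xc):
        raise ValueError("all profiles identical; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    variance_explained = var / var.sum()
    pc1 = u[:, 0] * s[0]
    if pc1[int(np.argmax(np.abs(pc1)))] < 0:
        pc1 = -pc1
    ordering = np.argsort(pc1, kind="stable")
    return ordering, pc1, variance_explained
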