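"""Diffusion-map gradients, Procrustes alignment and multimodal stacking.

A connectome's normalized-angle affinity is embedded with anisotropic
diffusion maps (exponent ``alpha``, default 0.5; diffusion time 0, so
component i is the non-trivial eigenvector i scaled by ``lambda_i /
(1 - lambda_i)``). Per modality the leading k gradients are max-abs
normalized to [-1, 1] and concatenated into one vertex-by-(3k) array in
the fixed order MPC, SC, FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components

from .connectomes import AffinityMatrix, Connectome, normalized_angle_affinity, sparsify_rows

__all__ = [
    "GradientSet",
    "MultimodalGradients",
    "diffusion_map",
    "procrustes_align",
    "normalize_and_stack",
    "group_template",
    "split_hemisphere_embedding",
]

MODALITY_ORDER = ("MPC", "SC", "FC")


@dataclass
class GradientSet:
    """Vertex-by-k eigenvector set for one modality."""

    components: np.ndarray
    eigenvalues: np.ndarray
    modality: str
    alpha: float

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")
        if not np.isfinite(self.components).all():
            raise ValueError("non-finite gradient components")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class MultimodalGradients:
    """Stacked, per-column max-abs-normalized gradients of all modalities.

    Column order is [MPC 1..k, SC 1..k, FC 1..k]; every column's maximum
    absolute value is 1, so each gradient spans [-1, 1].
    """

    values: np.ndarray
    k_per_modality: int
    modalities: tuple = MODALITY_ORDER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.modalities) * self.k_per_modality:
            raise ValueError("column count inconsistent with k_per_modality")
        colmax = np.abs(self.values).max(axis=0)
        if not np.allclose(colmax, 1.0, atol=1e-9):
            raise ValueError("columns must be max-abs normalized to 1")

    @property
    def column_names(self) -> list:
        return [
            f"{m}_G{i + 1}"
            for m in self.modalities
            for i in range(self.k_per_modality)
        ]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make the maximum-|value| entry of each component positive.

    Removes eigensolver sign nondeterminism so downstream alignment and
    reports are reproducible.
    """
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] *= -1.0
    return out


def diffusion_map(
    affinity: AffinityMatrix, n_components: int = 10, alpha: float = 0.5
) -> GradientSet:
    """Anisotropic diffusion-map embedding of an affinity matrix.

    With D the row-sum diagonal: ``W' = D^-alpha W D^-alpha`` and
    ``M = D'^-1 W'``; the eigenvectors of M (computed through the
    symmetrically conjugated form) drop the trivial constant vector and
    are scaled by ``lambda / (1 - lambda)``.
    """
    w = np.asarray(affinity.values, dtype=float)
    n = w.shape[0]
    if n_components >= n:
        raise ValueError("n_components must be smaller than the vertex count")
    ncomp, labels = connected_components(w > 0, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes}")

    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    s = w1 * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    # top n_components + 1 eigenpairs of the symmetric conjugate of M
    evals, evecs = linalg.eigh(
        s, subset_by_index=[n - n_components - 1, n - 1]
    )
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = inv_sqrt[:, None] * evecs
    # drop the trivial (lambda = 1) constant eigenvector
    lam = np.clip(evals[1:], None, 1.0 - 1e-9)
    comps = psi[:, 1:]
    comps = comps / np.linalg.norm(comps, axis=0, keepdims=True)
    comps = comps * (lam / (1.0 - lam))[None, :]
    return GradientSet(
        components=_fix_signs(comps),
        eigenvalues=lam,
        modality=affinity.source_modality,
        alpha=alpha,
    )


def procrustes_align(source: GradientSet, reference: GradientSet) -> GradientSet:
    """Align one gradient set to a reference by a single orthogonal map.

    Both component matrices are column-centered, the orthogonal transform
    minimizing the Frobenius distance is found by SVD, and the reference
    column means are restored. No scaling and no iterative refinement.
    """
    src, ref = source.components, reference.components
    if src.shape != ref.shape:
        raise ValueError(f"shape mismatch {src.shape} vs {ref.shape}")
    src_c = src - src.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    ref_c = ref - ref_mean
    r, _ = linalg.orthogonal_procrustes(src_c, ref_c)
    return GradientSet(
        components=src_c @ r + ref_mean,
        eigenvalues=source.eigenvalues,
        modality=source.modality,
        alpha=source.alpha,
    )


def normalize_and_stack(
    gradsets: list, k_per_modality: int = 5
) -> MultimodalGradients:
    """Per-modality max-abs normalization and stacking of the first k
    gradients of each modality (supported range 3..7, default 5)."""
    if not 3 <= k_per_modality <= 7:
        raise ValueError("k_per_modality must be in 3..7")
    if len(gradsets) != len(MODALITY_ORDER):
        raise ValueError(f"expected {len(MODALITY_ORDER)} gradient sets")
    by_mod = {g.modality: g for g in gradsets}
    if set(by_mod) != set(MODALITY_ORDER):
        raise ValueError(f"need one gradient set per modality {MODALITY_ORDER}")
    blocks = []
    for m in MODALITY_ORDER:
        g = by_mod[m]
        if g.n_components < k_per_modality:
            raise ValueError(f"{m}: only {g.n_components} components available")
        block = g.components[:, :k_per_modality]
        blocks.append(block / np.abs(block).max(axis=0, keepdims=True))
    return MultimodalGradients(
        values=np.hstack(blocks), k_per_modality=k_per_modality
    )


def split_hemisphere_embedding(
    conn: Connectome,
    hemisphere: np.ndarray,
    keep_fraction: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
) -> GradientSet:
    """Embed each hemisphere separately and align right to left.

    Alternative to the default joint embedding: the connectome is split
    into within-hemisphere blocks, each block is sparsified, converted to
    a normalized-angle affinity and embedded on its own, and the right
    hemisphere's gradients are Procrustes-aligned to the left's before the
    rows are recombined in the original vertex order.
    """
    hemisphere = np.asarray(hemisphere)
    names = []
    for h in hemisphere:
        if h not in names:
            names.append(h)
    if len(names) != 2:
        raise ValueError("expected exactly two hemisphere labels")
    sets, indices = [], []
    for h in names:
        idx = np.flatnonzero(hemisphere == h)
        block = Connectome(
            weights=conn.weights[np.ix_(idx, idx)], modality=conn.modality,
            task_tag=conn.task_tag,
        )
        aff = normalized_angle_affinity(sparsify_rows(block, keep_fraction))
        sets.append(diffusion_map(aff, n_components=n_components, alpha=alpha))
        indices.append(idx)
    left, right = sets
    right = procrustes_align(right, left)
    out = np.empty((conn.n_vertices, left.n_components))
    out[indices[0]] = left.components
    out[indices[1]] = right.components
    return GradientSet(
        components=out, eigenvalues=left.eigenvalues,
        modality=conn.modality, alpha=alpha,
    )


def group_template(
    connectomes: list,
    keep_fraction: float = 0.10,
    n_components: int = 10,
    alpha: float = 0.5,
) -> GradientSet:
    """Embedding of the entrywise group-average connectome.

    Serves as the Procrustes reference for subject-level gradients.
    """
    if not connectomes:
        raise ValueError("need at least one connectome")
    shapes = {c.weights.shape for c in connectomes}
    if len(shapes) > 1:
        raise ValueError(f"connectome shape mismatch: {sorted(shapes)}")
    modality = connectomes[0].modality
    mean_w = np.mean([c.weights for c in connectomes], axis=0)
    avg = Connectome(weights=mean_w, modality=modality)
    aff = normalized_angle_affinity(sparsify_rows(avg, keep_fraction))
    return diffusion_map(aff, n_components=n_components, alpha=alpha)
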