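"""Vertex-wise connectome construction and embedding preparation.

Three modalities share one container: microstructural profile covariance
(MPC, partial correlations of depth-intensity profiles controlling for the
cortex-average profile), functional connectivity (FC, Fisher-z Pearson
correlation of timeseries) and structural connectivity (SC, consumed as a
precomputed matrix). Any modality is prepared for diffusion-map embedding
by per-row top-fraction sparsification followed by a normalized-angle
affinity kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Connectome",
    "AffinityMatrix",
    "build_mpc",
    "build_fc",
    "sparsify_rows",
    "normalized_angle_affinity",
    "fisher_z",
]

_CLIP = 1.0 - 1e-6


@dataclass
class Connectome:
    """Square vertex-by-vertex connectivity matrix tagged with a modality."""

    weights: np.ndarray
    modality: str                      # "MPC" | "SC" | "FC"
    task_tag: str | None = None        # FC only
    excluded: list = field(default_factory=list)  # vertices zeroed at build

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be square")
        if not np.isfinite(w).all():
            raise ValueError("connectome contains non-finite entries")
        if self.modality not in ("MPC", "SC", "FC"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


@dataclass
class AffinityMatrix:
    """Normalized-angle similarity in [0, 1]; the embedding input."""

    values: np.ndarray
    source_modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("affinity entries outside [0, 1]")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("affinity not symmetric")


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher r-to-z with correlations clipped to +/-(1 - 1e-6).

    Clipping bounds the transform for duplicated series without changing
    the ordering of any finite correlations.
    """
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def _flag_constant(x: np.ndarray, axis: int) -> np.ndarray:
    return np.flatnonzero(np.ptp(x, axis=axis) == 0)


def build_mpc(profiles: np.ndarray) -> Connectome:
    """Microstructural profile covariance from depth-by-vertex intensities.

    Per vertex pair the Pearson correlation of depth profiles is partialed
    on the cortex-average profile m:
    ``r_ij|m = (r_ij - r_im r_jm) / sqrt((1 - r_im^2)(1 - r_jm^2))``,
    then Fisher r-to-z transformed; non-positive similarities are floored
    at 0 and the diagonal is 0. Vertices with a constant profile are zeroed
    and reported in ``excluded``.
    """
    profiles = np.asarray(profiles, dtype=float)
    n_depths, n_vertices = profiles.shape
    if n_depths < 3:
        raise ValueError("need at least 3 depths")
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    excluded = _flag_constant(profiles, axis=0)
    work = profiles.copy()
    # constant profiles would produce NaN correlations; give them unit noise
    # placeholders and zero their rows afterwards
    if len(excluded):
        work[:, excluded] = np.linspace(0, 1, n_depths)[:, None]

    m = profiles.mean(axis=1)
    x = np.column_stack([work, m])
    r = np.corrcoef(x, rowvar=False)
    r_vm = r[:-1, -1]
    r_vv = r[:-1, :-1]
    denom = np.sqrt(np.clip(1 - r_vm**2, 1e-12, None))
    partial = (r_vv - np.outer(r_vm, r_vm)) / np.outer(denom, denom)
    z = fisher_z(partial)
    z[z < 0] = 0.0
    np.fill_diagonal(z, 0.0)
    if len(excluded):
        z[excluded, :] = 0.0
        z[:, excluded] = 0.0
    z = (z + z.T) / 2.0
    return Connectome(weights=z, modality="MPC", excluded=list(map(int, excluded)))


def build_fc(timeseries: np.ndarray, task_tag: str | None = None) -> Connectome:
    """Functional connectivity: Fisher-z Pearson correlation of columns.

    ``timeseries`` is timepoint-by-vertex. Constant columns are zeroed and
    reported in ``excluded``.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    excluded = _flag_constant(ts, axis=0)
    work = ts.copy()
    if len(excluded):
        work[:, excluded] = np.arange(ts.shape[0])[:, None]
    r = np.corrcoef(work, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    if len(excluded):
        z[excluded, :] = 0.0
        z[:, excluded] = 0.0
    z = (z + z.T) / 2.0
    return Connectome(
        weights=z, modality="FC", task_tag=task_tag,
        excluded=list(map(int, excluded)),
    )


def sparsify_rows(conn: Connectome, keep_fraction: float) -> Connectome:
    """Keep the top ``keep_fraction`` of each row's off-diagonal weights.

    Retains the ``ceil(keep_fraction * (n - 1))`` largest off-diagonal
    entries per row (ties at the cutoff go to the lower column index) and
    zeroes the rest. The result is generally asymmetric; the input is not
    modified. The study default keeps the top 10%.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    w = conn.weights.copy()
    n = w.shape[0]
    k = int(np.ceil(keep_fraction * (n - 1)))
    if k >= n - 1:
        return Connectome(weights=w, modality=conn.modality,
                          task_tag=conn.task_tag, excluded=list(conn.excluded))
    masked = w.astype(float).copy()
    np.fill_diagonal(masked, -np.inf)
    # stable descending sort keeps lower column index first among ties
    order = np.argsort(-masked, axis=1, kind="stable")
    keep_cols = order[:, :k]
    out = np.zeros_like(w)
    rows = np.repeat(np.arange(n), k)
    out[rows, keep_cols.ravel()] = w[rows, keep_cols.ravel()]
    return Connectome(weights=out, modality=conn.modality,
                      task_tag=conn.task_tag, excluded=list(conn.excluded))


def normalized_angle_affinity(conn: Connectome) -> AffinityMatrix:
    """Normalized-angle affinity of connectome rows.

    ``A_ij = 1 - arccos(cos_sim(row_i, row_j)) / pi`` maps cosine row
    similarity into [0, 1]; the diagonal is forced to 1 and the result is
    symmetrized. Raises if any row is all zero (such a row has no
    connectivity fingerprint).
    """
    w = conn.weights
    norms = np.linalg.norm(w, axis=1)
    dead = np.flatnonzero(norms == 0)
    if len(dead):
        raise ValueError(f"all-zero connectome rows for vertices {dead.tolist()}")
    unit = w / norms[:, None]
    c = np.clip(unit @ unit.T, -1.0, 1.0)
    a = 1.0 - np.arccos(c) / np.pi
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=np.clip(a, 0.0, 1.0),
                          source_modality=conn.modality)
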