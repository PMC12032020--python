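"""Cross-task functional diversity from task-tagged FC stacks.

For every vertex, its whole-brain FC row is a connectivity fingerprint per
task; cosine distances between a vertex's fingerprints across tasks give
per-task and overall diversity maps, averaged into areas. Intra-areal
cross-task variability is the per-vertex SD across tasks of the mean FC to
the other vertices of the same area, averaged over the area's vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .arealization import AreaLabeling
from .connectomes import Connectome

__all__ = [
    "TaskFCStack",
    "DiversityMaps",
    "cross_task_diversity",
    "intra_areal_task_sd",
]

logger = logging.getLogger(__name__)


@dataclass
class TaskFCStack:
    """Ordered collection of same-shape FC matrices, one per task."""

    fc: dict                      # task name -> Connectome or array
    task_names: list

    def __post_init__(self) -> None:
        if len(self.task_names) < 2:
            raise ValueError("need at least 2 tasks")
        shapes = {self.matrix(t).shape for t in self.task_names}
        if len(shapes) > 1:
            raise ValueError(f"task FC shapes differ: {sorted(shapes)}")

    def matrix(self, task: str) -> np.ndarray:
        m = self.fc[task]
        return m.weights if isinstance(m, Connectome) else np.asarray(m, float)

    @property
    def n_tasks(self) -> int:
        return len(self.task_names)

    @property
    def n_vertices(self) -> int:
        return self.matrix(self.task_names[0]).shape[0]


@dataclass
class DiversityMaps:
    """Vertex- and area-level cross-task diversity."""

    per_vertex_overall: np.ndarray
    per_vertex_per_task: dict
    per_area: np.ndarray
    area_ids: np.ndarray
    excluded_vertices: list


def _stacked_rows(stack: TaskFCStack) -> np.ndarray:
    """(T, V, V-1) array of FC rows with each vertex's own diagonal entry
    removed, so the structural zero at self does not inflate similarity."""
    t, v = stack.n_tasks, stack.n_vertices
    rows = np.empty((t, v, v - 1))
    off = ~np.eye(v, dtype=bool)
    for k, name in enumerate(stack.task_names):
        m = stack.matrix(name)
        rows[k] = m[off].reshape(v, v - 1)
    return rows


def cross_task_diversity(
    stack: TaskFCStack, labeling: AreaLabeling
) -> DiversityMaps:
    """Mean cosine distance between a vertex's FC fingerprints across tasks.

    Per vertex, the T-by-T cosine distance matrix between its whole-brain
    FC rows (diagonal 0) is summarized as the mean over the other T - 1
    tasks per task, and the mean over tasks overall; area values average
    the overall map over assigned vertices. Vertices with a zero FC row in
    any task are excluded from area means.
    """
    rows = _stacked_rows(stack)                       # T x V x (V-1)
    t, v, _ = rows.shape
    norms = np.linalg.norm(rows, axis=2)              # T x V
    bad = np.flatnonzero((norms == 0).any(axis=0))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    unit = rows / safe[:, :, None]
    # for unit vectors 1 - cos(u, v) = ||u - v||^2 / 2; the difference form
    # is exactly 0 for bit-identical task rows
    dist = np.zeros((t, t, v))
    for i in range(t):
        for j in range(i + 1, t):
            d = 0.5 * np.sum((unit[i] - unit[j]) ** 2, axis=1)
            dist[i, j] = dist[j, i] = np.clip(d, 0.0, 2.0)
    per_task = dist.sum(axis=1) / (t - 1)             # T x V
    overall = per_task.mean(axis=0)
    overall[bad] = np.nan
    per_task[:, bad] = np.nan
    per_vertex_per_task = {
        name: per_task[i] for i, name in enumerate(stack.task_names)
    }
    area_ids, per_area = [], []
    for a in labeling.area_ids:
        idx = labeling.vertices_of(int(a))
        vals = overall[idx]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        area_ids.append(a)
        per_area.append(vals.mean())
    if len(bad):
        logger.warning("excluded %d zero-FC-row vertices", len(bad))
    return DiversityMaps(
        per_vertex_overall=overall,
        per_vertex_per_task=per_vertex_per_task,
        per_area=np.array(per_area),
        area_ids=np.array(area_ids),
        excluded_vertices=bad.tolist(),
    )


def intra_areal_task_sd(
    stack: TaskFCStack, labeling: AreaLabeling
) -> tuple[np.ndarray, np.ndarray]:
    """Per-area mean of the vertex-wise SD across tasks of within-area FC.

    For each vertex v in area a and each task, the mean FC from v to the
    other vertices of a is computed; the sample SD (ddof=1) across tasks
    is then averaged over the area's vertices (the sum of vertex SDs
    divided by the vertex count, controlling for parcel size). Singleton
    areas are excluded.

    Returns ``(area_ids, values)``.
    """
    mats = np.stack([stack.matrix(t) for t in stack.task_names])  # T x V x V
    area_ids, values = [], []
    for a in labeling.area_ids:
        idx = labeling.vertices_of(int(a))
        if len(idx) < 2:
            if len(idx) == 1:
                logger.warning("area %s is a singleton; excluded", a)
            continue
        sub = mats[:, idx[:, None], idx[None, :]]     # T x n x n
        n = len(idx)
        diag = np.diagonal(sub, axis1=1, axis2=2)
        within_mean = (sub.sum(axis=2) - diag) / (n - 1)   # T x n
        # SD is shift-invariant; anchoring on task 0 keeps identical task
        # stacks at exactly zero
        sd = (within_mean - within_mean[0]).std(axis=0, ddof=1)
        area_ids.append(a)
        values.append(sd.sum() / n)
    return np.array(area_ids), np.array(values)
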