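"""Spherical cortical surface meshes.

Analyses operate on registration-sphere geometry: each hemisphere is a full
triangulated sphere centered at the origin, so left and right vertex
coordinates overlap in space but are kept apart by a per-vertex hemisphere
label. A boolean mid-wall mask marks vertices (the medial-wall analogue)
that are excluded from all cortical statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull

__all__ = [
    "SurfaceMesh",
    "make_sphere_mesh",
    "make_fibonacci_mesh",
    "paper_scale_mesh",
]

# icosahedron with circumradius 1, deterministic vertex order
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


@dataclass
class SurfaceMesh:
    """Triangle mesh with spherical topology per hemisphere.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Vertex positions; every vertex lies on a sphere of radius ``radius``.
    triangles : (F, 3) int array
        Vertex-index triples.
    hemisphere : (V,) array of {"left", "right"}
        Hemisphere membership per vertex.
    midwall_mask : (V,) bool array
        True where a vertex is excluded from cortical analysis.
    radius : float
        Radius of the sphere the vertices lie on, in mm-like units.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray
    midwall_mask: np.ndarray
    radius: float = 100.0

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere)
        self.midwall_mask = np.asarray(self.midwall_mask, dtype=bool)
        if self.triangles.size and self.triangles.max() >= self.n_vertices:
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def cortex_mask(self) -> np.ndarray:
        """Boolean mask of analyzable (non-midwall) vertices."""
        return ~self.midwall_mask

    @property
    def hemispheres(self) -> list[str]:
        seen = []
        for h in self.hemisphere:
            if h not in seen:
                seen.append(str(h))
        return seen

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    # ---- topology ------------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges, each as a sorted (i, j) pair."""
        tri = self.triangles
        e = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self, hemi: str | None = None) -> int:
        """V - E + F, restricted to one hemisphere if given (2 for a sphere)."""
        if hemi is None:
            v_idx = np.arange(self.n_vertices)
        else:
            v_idx = self.hemi_indices(hemi)
        in_hemi = np.zeros(self.n_vertices, dtype=bool)
        in_hemi[v_idx] = True
        tri = self.triangles[in_hemi[self.triangles].all(axis=1)]
        e = np.unique(
            np.sort(
                np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]),
                axis=1,
            ),
            axis=0,
        )
        return len(v_idx) - len(e) + len(tri)

    def adjacency(self, weighted: bool = False) -> sparse.csr_matrix:
        """Sparse vertex adjacency; Euclidean edge lengths if ``weighted``."""
        e = self.edges()
        if weighted:
            w = np.linalg.norm(
                self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]], axis=1
            )
        else:
            w = np.ones(len(e))
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                      np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return a.tocsr()

    def geodesic_distances(self, sources: np.ndarray) -> np.ndarray:
        """Graph-geodesic distances (Dijkstra on edge lengths) from sources.

        Returns an (n_sources, V) array; vertices in a different connected
        component (the other hemisphere) are at ``inf``.
        """
        g = self.adjacency(weighted=True)
        return dijkstra(g, directed=False, indices=np.asarray(sources))

    def n_components(self) -> int:
        return connected_components(self.adjacency(), directed=False)[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Raise if the sphere-radius or closed-manifold invariants fail."""
        norms = np.linalg.norm(self.vertex_coords, axis=1)
        if not np.allclose(norms, self.radius, atol=atol):
            raise ValueError("vertex norms deviate from the stated radius")
        for h in self.hemispheres:
            chi = self.euler_characteristic(h)
            if chi != 2:
                raise ValueError(f"hemisphere {h}: Euler characteristic {chi} != 2")


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One loop of edge-midpoint subdivision with deterministic ordering."""
    edge_key = {}
    new_verts = [verts]
    next_idx = len(verts)
    # enumerate unique edges in sorted order so midpoint indices are reproducible
    e = np.unique(
        np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
            axis=1,
        ),
        axis=0,
    )
    mids = (verts[e[:, 0]] + verts[e[:, 1]]) / 2.0
    for k, (i, j) in enumerate(e):
        edge_key[(int(i), int(j))] = next_idx + k
    new_verts.append(mids)
    next_idx += len(e)

    def mid(i: int, j: int) -> int:
        return edge_key[(i, j) if i < j else (j, i)]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return np.vstack(new_verts), np.array(new_faces, dtype=np.int64)


def _polar_cap_mask(coords: np.ndarray, radius: float, fraction: float) -> np.ndarray:
    # spherical cap of given area fraction at the +z pole: cos(theta) = 1 - 2f
    if fraction <= 0:
        return np.zeros(len(coords), dtype=bool)
    return coords[:, 2] / radius > 1.0 - 2.0 * fraction


def _assemble(verts: np.ndarray, faces: np.ndarray, radius: float,
              hemispheres: int, midwall_fraction: float) -> SurfaceMesh:
    verts = verts * (radius / np.linalg.norm(verts, axis=1, keepdims=True))
    mask = _polar_cap_mask(verts, radius, midwall_fraction)
    names = ["left", "right"][:hemispheres]
    all_v, all_f, all_h, all_m = [], [], [], []
    off = 0
    for name in names:
        all_v.append(verts)
        all_f.append(faces + off)
        all_h.append(np.full(len(verts), name, dtype=object))
        all_m.append(mask)
        off += len(verts)
    return SurfaceMesh(
        vertex_coords=np.vstack(all_v),
        triangles=np.vstack(all_f),
        hemisphere=np.concatenate(all_h),
        midwall_mask=np.concatenate(all_m),
        radius=radius,
    )


def make_sphere_mesh(
    subdivision_level: int,
    radius: float = 100.0,
    hemispheres: int = 2,
    midwall_fraction: float = 0.02,
) -> SurfaceMesh:
    """Icosphere mesh with ``10 * 4**L + 2`` vertices per hemisphere.

    The mid-wall mask marks a polar cap at the +z pole covering
    ``midwall_fraction`` of the sphere's area (default 2%). Both hemispheres
    share identical sphere geometry; vertex order is left block then right.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if hemispheres not in (1, 2):
        raise ValueError("hemispheres must be 1 or 2")
    verts, faces = _ICO_VERTS.copy(), _ICO_FACES.copy()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return _assemble(verts, faces, radius, hemispheres, midwall_fraction)


def make_fibonacci_mesh(
    n_vertices: int,
    radius: float = 100.0,
    hemispheres: int = 2,
    midwall_fraction: float = 0.02,
) -> SurfaceMesh:
    """Sphere mesh with an exact per-hemisphere vertex count.

    Places ``n_vertices`` points on a Fibonacci lattice and triangulates
    them with the convex hull, giving a closed genus-0 mesh for counts the
    icosphere formula cannot hit.
    """
    if n_vertices < 4:
        raise ValueError("need at least 4 vertices")
    i = np.arange(n_vertices, dtype=float)
    ga = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    verts = np.column_stack([r * np.cos(ga * i), r * np.sin(ga * i), z])
    faces = ConvexHull(verts).simplices.astype(np.int64)
    return _assemble(verts, faces, radius, hemispheres, midwall_fraction)


def paper_scale_mesh(radius: float = 100.0) -> SurfaceMesh:
    """Preset matching the study-scale surface: 4432 vertices per hemisphere."""
    return make_fibonacci_mesh(4432, radius=radius, hemispheres=2)
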