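"""Readers and writers: delimited matrices with JSON sidecars, GIFTI maps.

Matrices travel as tab-separated text using 17-significant-digit floats
(which round-trip IEEE doubles exactly) next to a JSON sidecar recording
shape, modality and vertex ordering. Surfaces and per-vertex maps can also
be written as GIFTI through nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib
from nibabel import gifti

from .connectomes import Connectome
from .mesh import SurfaceMesh
from .synthcortex import ProbabilisticAtlas, SyntheticDataset

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_connectome",
    "read_connectome",
    "write_dataset",
    "read_dataset",
    "write_mesh_gifti",
    "write_map_gifti",
    "write_label_gifti",
]

_FMT = "%.17g"


def write_matrix(path, arr: np.ndarray, **sidecar) -> None:
    """Write a 2-D array as TSV plus a ``.json`` sidecar with its shape."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(arr))
    np.savetxt(path, arr, fmt=_FMT, delimiter="\t")
    meta = {"shape": list(arr.shape), **sidecar}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=1) + "\n"
    )


def read_matrix(path) -> tuple[np.ndarray, dict]:
    """Read a TSV matrix, checking it against its sidecar's shape."""
    path = Path(path)
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        expect = tuple(meta.get("shape", arr.shape))
        if tuple(arr.shape) != expect:
            raise ValueError(
                f"{path.name}: expected shape {expect}, found {tuple(arr.shape)}"
            )
    return arr, meta


def write_connectome(path, conn: Connectome) -> None:
    write_matrix(path, conn.weights, modality=conn.modality,
                 task_tag=conn.task_tag, excluded=conn.excluded)


def read_connectome(path) -> Connectome:
    arr, meta = read_matrix(path)
    return Connectome(weights=arr, modality=meta.get("modality", "FC"),
                      task_tag=meta.get("task_tag"),
                      excluded=meta.get("excluded", []))


# ---------------------------------------------------------------------------
# GIFTI

def write_mesh_gifti(mesh: SurfaceMesh, out_dir, stem: str = "surface") -> list:
    """One GIFTI surface file per hemisphere; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for h in mesh.hemispheres:
        idx = mesh.hemi_indices(h)
        remap = {int(v): i for i, v in enumerate(idx)}
        in_h = np.isin(mesh.triangles, idx).all(axis=1)
        tri = np.vectorize(remap.get)(mesh.triangles[in_h])
        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    mesh.vertex_coords[idx].astype(np.float32),
                    intent="NIFTI_INTENT_POINTSET",
                ),
                gifti.GiftiDataArray(
                    tri.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        p = out_dir / f"{stem}.{h}.surf.gii"
        nib.save(img, p)
        paths.append(p)
    return paths


def write_map_gifti(values: np.ndarray, path) -> None:
    """Per-vertex scalar map as a GIFTI functional file."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                np.asarray(values, dtype=np.float32),
                intent="NIFTI_INTENT_NONE",
            )
        ]
    )
    nib.save(img, Path(path))


def write_label_gifti(labels: np.ndarray, path, names: dict | None = None) -> None:
    """Per-vertex integer labels as a GIFTI label file with a label table."""
    labels = np.asarray(labels, dtype=np.int32)
    img = gifti.GiftiImage(
        darrays=[gifti.GiftiDataArray(labels, intent="NIFTI_INTENT_LABEL")]
    )
    table = gifti.GiftiLabelTable()
    for key in np.unique(labels):
        lab = gifti.GiftiLabel(key=int(key))
        lab.label = (names or {}).get(int(key), str(int(key)))
        table.labels.append(lab)
    img.labeltable = table
    nib.save(img, Path(path))


def read_label_gifti(path) -> tuple[np.ndarray, dict]:
    img = nib.load(str(path))
    labels = img.darrays[0].data
    names = {int(l.key): l.label for l in img.labeltable.labels}
    return np.asarray(labels), names


# ---------------------------------------------------------------------------
# dataset bundles

def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write a full synthetic dataset as delimited text + JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = ds.mesh
    write_matrix(out / "mesh_coords.tsv", m.vertex_coords, radius=m.radius)
    write_matrix(out / "mesh_triangles.tsv", m.triangles)
    (out / "mesh_vertex_info.json").write_text(
        json.dumps(
            {
                "hemisphere": [str(h) for h in m.hemisphere],
                "midwall_mask": m.midwall_mask.astype(int).tolist(),
                "radius": m.radius,
            },
            sort_keys=True,
        )
        + "\n"
    )
    write_matrix(out / "atlas_prob.tsv", ds.atlas.prob,
                 area_ids=[int(a) for a in ds.atlas.area_ids])
    write_matrix(out / "profiles.tsv", ds.profiles)
    write_matrix(out / "sc.tsv", ds.sc)
    write_matrix(out / "planted.tsv", ds.planted)
    write_matrix(out / "histological_gradient.tsv",
                 ds.histological_gradient[None, :])
    write_matrix(out / "flexibility.tsv", ds.flexibility[None, :])
    for name, ts in ds.timeseries.items():
        write_matrix(out / f"timeseries_{name}.tsv", ts, scan=name)
    (out / "annotations.json").write_text(
        json.dumps(
            {
                "hierarchy": {str(k): v for k, v in ds.hierarchy.items()},
                "covariates": {k: list(map(float, v))
                               for k, v in ds.covariates.items()},
                "task_names": ds.task_names,
            },
            sort_keys=True,
        )
        + "\n"
    )


def read_dataset(in_dir) -> SyntheticDataset:
    """Read back a dataset bundle written by :func:`write_dataset`."""
    src = Path(in_dir)
    if not src.exists():
        raise FileNotFoundError(src)
    coords, cmeta = read_matrix(src / "mesh_coords.tsv")
    tri, _ = read_matrix(src / "mesh_triangles.tsv")
    vinfo = json.loads((src / "mesh_vertex_info.json").read_text())
    mesh = SurfaceMesh(
        vertex_coords=coords,
        triangles=tri.astype(np.int64),
        hemisphere=np.array(vinfo["hemisphere"], dtype=object),
        midwall_mask=np.array(vinfo["midwall_mask"], dtype=bool),
        radius=float(vinfo["radius"]),
    )
    prob, pmeta = read_matrix(src / "atlas_prob.tsv")
    atlas = ProbabilisticAtlas(
        prob=prob, area_ids=np.array(pmeta["area_ids"], dtype=int)
    )
    ann = json.loads((src / "annotations.json").read_text())
    timeseries = {}
    for f in sorted(src.glob("timeseries_*.tsv")):
        name = f.stem.replace("timeseries_", "", 1)
        timeseries[name], _ = read_matrix(f)
    hist, _ = read_matrix(src / "histological_gradient.tsv")
    flex, _ = read_matrix(src / "flexibility.tsv")
    return SyntheticDataset(
        mesh=mesh,
        atlas=atlas,
        profiles=read_matrix(src / "profiles.tsv")[0],
        timeseries=timeseries,
        sc=read_matrix(src / "sc.tsv")[0],
        planted=read_matrix(src / "planted.tsv")[0],
        hierarchy={int(k): v for k, v in ann["hierarchy"].items()},
        histological_gradient=hist[0],
        covariates={k: np.array(v) for k, v in ann["covariates"].items()},
        flexibility=flex[0],
        task_names=ann["task_names"],
    )
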