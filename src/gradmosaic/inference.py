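"""Spin-permutation spatial nulls and statistical tests.

All spatial p-values rest on the spherical spin test: an area-level map is
projected to vertices, the sphere is randomly rotated (mirrored rotation
on the opposite hemisphere), values are resampled by nearest rotated
vertex and re-aggregated into areas, which preserves the map's spatial
autocorrelation while breaking its alignment with any other map. On top of
that sit extreme-area detection with FDR, spin-corrected (partial)
Spearman correlations, pairwise hierarchy-level t-tests with Cohen's d and
confidence intervals, the participation coefficient, and global FC
strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .arealization import AreaLabeling
from .connectomes import Connectome
from .mesh import SurfaceMesh

__all__ = [
    "SpinNullStore",
    "bh_reject",
    "spin_nulls",
    "extreme_area_test",
    "spin_spearman",
    "hierarchy_ttests",
    "participation_coefficient",
    "global_strength",
    "HIERARCHY_PAIRS",
]

HIERARCHY_PAIRS = list(
    combinations(("idiotypic", "unimodal", "heteromodal", "paralimbic"), 2)
)


def bh_reject(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level q."""
    reject, _, _, _ = multipletests(np.asarray(pvals, float), alpha=q,
                                    method="fdr_bh")
    return reject


@dataclass
class SpinNullStore:
    """Permuted area-level realizations of a map under sphere rotations."""

    null_values: np.ndarray        # n_perm x n_areas (NaN = area lost)
    area_ids: np.ndarray
    rotations_seed: int
    n_perm: int
    includes_identity: bool = False


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation: QR of a Gaussian matrix, det forced to +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _project_to_vertices(
    values: np.ndarray, labeling: AreaLabeling, area_ids: np.ndarray
) -> np.ndarray:
    vert = np.full(len(labeling.label), np.nan)
    for val, a in zip(values, area_ids):
        vert[labeling.label == a] = val
    return vert


def spin_nulls(
    map_values: np.ndarray,
    labeling: AreaLabeling,
    mesh: SurfaceMesh,
    n_perm: int = 1000,
    seed: int = 0,
    area_ids: np.ndarray | None = None,
    include_identity: bool = False,
    rotate_labels: bool = False,
) -> SpinNullStore:
    """Spin-permutation null realizations of an area-level map.

    Per permutation a uniform rotation is applied to right-hemisphere
    vertex coordinates and its x-mirrored counterpart to the left
    hemisphere, every vertex takes the value of its nearest rotated
    same-hemisphere vertex, and values are re-aggregated to areas under
    the fixed labeling. With ``rotate_labels`` the labeling is rotated
    instead and the observed vertex map re-aggregated under it (areas that
    lose every vertex yield NaN for that permutation). With
    ``include_identity`` row 0 is the un-rotated map.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    norms = np.linalg.norm(mesh.vertex_coords, axis=1)
    if not np.allclose(norms, mesh.radius, rtol=1e-6):
        raise ValueError("spin test requires a spherical mesh")
    if area_ids is None:
        area_ids = np.asarray(labeling.area_ids)
    map_values = np.asarray(map_values, dtype=float)
    if len(map_values) != len(area_ids):
        raise ValueError("map length does not match area count")

    vert_val = _project_to_vertices(map_values, labeling, area_ids)
    mirror = np.diag([-1.0, 1.0, 1.0])
    hemi_idx = {h: mesh.hemi_indices(h) for h in mesh.hemispheres}
    # one KD-tree per hemisphere on the un-rotated coordinates; the nearest
    # rotated vertex to x equals the nearest original vertex to R^T x
    trees = {h: cKDTree(mesh.vertex_coords[idx]) for h, idx in hemi_idx.items()}
    label = labeling.label
    # integer area index per vertex (-1 = not aggregated)
    area_pos = {int(a): i for i, a in enumerate(area_ids)}
    vert_area = np.array([area_pos.get(int(l), -1) for l in label])

    rng = np.random.default_rng(seed)
    rows = []
    if include_identity:
        rows.append(_aggregate(vert_val, vert_area, len(area_ids)))
        n_draw = n_perm - 1
    else:
        n_draw = n_perm
    for _ in range(n_draw):
        rot = _random_rotation(rng)
        source = np.empty(mesh.n_vertices, dtype=int)
        for h, idx in hemi_idx.items():
            r_h = rot if h == "right" else mirror @ rot @ mirror
            query = mesh.vertex_coords[idx] @ r_h
            _, nn = trees[h].query(query)
            source[idx] = idx[nn]
        if rotate_labels:
            rows.append(
                _aggregate(vert_val, vert_area[source], len(area_ids))
            )
        else:
            rows.append(
                _aggregate(vert_val[source], vert_area, len(area_ids))
            )
    return SpinNullStore(
        null_values=np.array(rows),
        area_ids=np.asarray(area_ids),
        rotations_seed=seed,
        n_perm=n_perm,
        includes_identity=include_identity,
    )


def _aggregate(vert_val: np.ndarray, vert_area: np.ndarray, n_areas: int) -> np.ndarray:
    ok = (vert_area >= 0) & np.isfinite(vert_val)
    sums = np.bincount(vert_area[ok], weights=vert_val[ok], minlength=n_areas)
    counts = np.bincount(vert_area[ok], minlength=n_areas)
    out = np.full(n_areas, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def extreme_area_test(
    observed: np.ndarray, nulls: SpinNullStore, q: float = 0.05
) -> pd.DataFrame:
    """Two-sided spin test per area with Benjamini-Hochberg FDR.

    ``p_high = (1 + #{null >= obs}) / (n_valid + 1)`` per area (``p_low``
    analogous), two-sided p is twice the smaller side capped at 1, and BH
    at level ``q`` runs across areas. ``flag_high``/``flag_low`` mark areas
    whose winning side survives FDR.
    """
    obs = np.asarray(observed, dtype=float)
    nv = nulls.null_values
    if nv.shape[1] != len(obs):
        raise ValueError("null store does not cover the observed areas")
    n_valid = np.isfinite(nv).sum(axis=0)
    p_high = (1 + np.nansum(nv >= obs[None, :], axis=0)) / (n_valid + 1)
    p_low = (1 + np.nansum(nv <= obs[None, :], axis=0)) / (n_valid + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_high, p_low))
    reject, p_fdr, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    high_side = p_high < p_low
    return pd.DataFrame(
        {
            "area_id": nulls.area_ids,
            "observed": obs,
            "p_high": p_high,
            "p_low": p_low,
            "p_two_sided": p,
            "p_fdr": p_fdr,
            "flag_high": reject & high_side,
            "flag_low": reject & ~high_side,
        }
    )


def _rank_residuals(r: np.ndarray, rc: np.ndarray) -> np.ndarray:
    a = np.column_stack([rc, np.ones_like(rc)])
    coef, *_ = np.linalg.lstsq(a, r, rcond=None)
    return r - a @ coef


def _spearman(x: np.ndarray, y: np.ndarray, covariate: np.ndarray | None) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if covariate is not None:
        ok &= np.isfinite(covariate)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    rx, ry = rankdata(x), rankdata(y)
    if covariate is None:
        return float(stats.pearsonr(rx, ry).statistic)
    rc = rankdata(covariate[ok])
    ex = _rank_residuals(rx, rc)
    ey = _rank_residuals(ry, rc)
    # a map fully explained by the covariate has no partial association left
    tol = 1e-10 * len(x)
    if np.ptp(ex) < tol or np.ptp(ey) < tol:
        return 0.0
    return float(stats.pearsonr(ex, ey).statistic)


def spin_spearman(
    x: np.ndarray,
    y: np.ndarray,
    nulls_of_x: SpinNullStore,
    covariate: np.ndarray | None = None,
) -> tuple[float, float]:
    """(Partial) Spearman correlation with a spin-permutation p-value.

    The observed rho correlates the ranks of x and y (rank-residualized on
    the ranked covariate if given); the null distribution recomputes rho
    with each spin realization of x against the fixed y. By convention x
    is the rotated map.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 areas")
    if np.ptp(x[np.isfinite(x)]) == 0 or np.ptp(y[np.isfinite(y)]) == 0:
        raise ValueError("constant input vector")
    rho = _spearman(x, y, covariate)
    null_rho = np.array(
        [_spearman(row, y, covariate) for row in nulls_of_x.null_values]
    )
    valid = np.isfinite(null_rho)
    p = (1 + np.sum(np.abs(null_rho[valid]) >= abs(rho))) / (valid.sum() + 1)
    return rho, float(p)


def _pooled_t(a: np.ndarray, b: np.ndarray):
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if df > 0
        else 0.0
    )
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return np.nan, diff, 0.0, df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    return diff / se, diff, np.sqrt(sp2), df


def hierarchy_ttests(
    values: np.ndarray,
    labels: np.ndarray,
    nulls: SpinNullStore,
    q: float = 0.05,
) -> pd.DataFrame:
    """Pairwise hierarchy-level contrasts with spin-corrected p-values.

    For each of the six pairs of the four cortical hierarchy levels a
    two-sided pooled-variance Student t-test compares per-unit values,
    with Cohen's d (pooled SD), the t-based 95% CI of the mean difference,
    ``p_spin`` from the null t distribution under spin realizations of the
    value map with fixed labels, and BH-FDR across the six pairs. A zero
    pooled variance flags the contrast and reports d as signed infinity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    rows = []
    for lv_a, lv_b in HIERARCHY_PAIRS:
        a = values[(labels == lv_a) & np.isfinite(values)]
        b = values[(labels == lv_b) & np.isfinite(values)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"level {lv_a!r} or {lv_b!r} has fewer than 2 units")
        t, diff, sp, df = _pooled_t(a, b)
        degenerate = not np.isfinite(t)
        if degenerate:
            d = np.inf * np.sign(diff) if diff != 0 else 0.0
            ci = (diff, diff)
        else:
            d = diff / sp
            se = sp * np.sqrt(1 / len(a) + 1 / len(b))
            tcrit = stats.t.ppf(0.975, df)
            ci = (diff - tcrit * se, diff + tcrit * se)
        # null t's from spin realizations of the value map
        null_t = []
        for row in nulls.null_values:
            na = row[(labels == lv_a) & np.isfinite(row)]
            nb = row[(labels == lv_b) & np.isfinite(row)]
            if len(na) < 2 or len(nb) < 2:
                continue
            nt, _, _, _ = _pooled_t(na, nb)
            if np.isfinite(nt):
                null_t.append(nt)
        null_t = np.array(null_t)
        if degenerate or len(null_t) == 0:
            p_spin = np.nan
        else:
            p_spin = (1 + np.sum(np.abs(null_t) >= abs(t))) / (len(null_t) + 1)
        rows.append(
            {
                "level_a": lv_a,
                "level_b": lv_b,
                "t": t,
                "cohens_d": d,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_spin": p_spin,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    ok = np.isfinite(out["p_spin"].to_numpy())
    p_fdr = np.full(len(out), np.nan)
    rej = np.zeros(len(out), dtype=bool)
    if ok.any():
        rej[ok], p_fdr[ok], _, _ = multipletests(
            out.loc[ok, "p_spin"], alpha=q, method="fdr_bh"
        )
    out["p_fdr"] = p_fdr
    out["significant"] = rej
    return out


def participation_coefficient(
    fc: Connectome | np.ndarray, communities: np.ndarray
) -> np.ndarray:
    """``PC_i = 1 - sum_s (k_is / k_i)^2`` over positive weights.

    ``communities`` assigns each unit a community label (here the four
    hierarchy levels). Units with zero positive strength get PC 0.
    """
    w = fc.weights if isinstance(fc, Connectome) else np.asarray(fc, float)
    w = np.clip(w, 0.0, None).copy()
    np.fill_diagonal(w, 0.0)
    communities = np.asarray(communities)
    if len(communities) != w.shape[0]:
        raise ValueError("communities must cover all units")
    k = w.sum(axis=1)
    pc = np.zeros_like(k)
    nz = k > 0
    for s in np.unique(communities):
        ks = w[:, communities == s].sum(axis=1)
        pc[nz] += (ks[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - pc[nz]
    return pc


def global_strength(fc: Connectome | np.ndarray) -> np.ndarray:
    """Mean off-diagonal connectivity per unit."""
    w = fc.weights if isinstance(fc, Connectome) else np.asarray(fc, float)
    n = w.shape[0]
    return (w.sum(axis=1) - np.diag(w)) / (n - 1)
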