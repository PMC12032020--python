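"""End-to-end orchestration: config, staged seeds, report, robustness sweep.

The pipeline runs connectome construction, diffusion-map embedding,
arealization, dissimilarity statistics, cross-task diversity and spin
inference from a single validated config, with a master seed fanned out to
per-stage child seeds by stable hashing so any stage can be rerun in
isolation with the same randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arealization, connectomes, dissimilarity, embedding, inference, taskdiversity
from .mesh import make_sphere_mesh
from .synthcortex import (
    HIERARCHY_LEVELS,
    PlantedGradientSpec,
    SyntheticDataset,
    make_multimodal_dataset,
)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_pipeline",
    "robustness_sweep",
    "derive_seed",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed: sha256 of ``"{master}:{stage}"``, < 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Validated parameters for a full run.

    Defaults follow the study conventions: top 10% row sparsity, 10
    diffusion components with alpha = 0.5, the first 5 gradients per
    modality, 1000 spin permutations and FDR at q = 0.05.
    """

    # synthetic-input parameters (used unless input_dir is given)
    mesh_level: int = 3
    n_areas: int = 40
    n_tasks: int = 9
    n_depths: int = 12
    n_timepoints: int = 200
    correlation_length: float = 40.0
    atlas_softness: float = 0.0
    snr: dict = field(default_factory=lambda: {"mpc": 5.0, "sc": 5.0, "fc": 5.0})
    task_amplitude: float = 0.5
    # analysis parameters
    keep_fraction: dict = field(
        default_factory=lambda: {"MPC": 0.10, "SC": 0.10, "FC": 0.10}
    )
    n_components: int = 10
    alpha: float = 0.5
    k_per_modality: int = 5
    n_perm: int = 1000
    fdr_q: float = 0.05
    cluster_k_range: tuple = (2, 8)
    # bookkeeping
    seed: int = 0
    input_dir: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for m, f in self.keep_fraction.items():
            if not 0 < f <= 1:
                raise ValueError(f"keep_fraction[{m}]={f} outside (0, 1]")
        if not 3 <= self.k_per_modality <= 7:
            raise ValueError("k_per_modality must be in 3..7")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.n_components < self.k_per_modality:
            raise ValueError("n_components must be >= k_per_modality")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "cluster_k_range" in raw:
            raw["cluster_k_range"] = tuple(raw["cluster_k_range"])
        return cls(**raw)

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str | None = None) -> "PipelineConfig":
        """Small fast configuration: level-3 mesh, 40 areas, 3 tasks,
        200 permutations."""
        return cls(mesh_level=3, n_areas=40, n_tasks=3, n_timepoints=150,
                   n_perm=200, seed=seed, out_dir=out_dir)

    def canonical_json(self) -> str:
        # out_dir does not affect any computed value and is excluded so
        # reports written to different locations remain identical
        d = asdict(self)
        d.pop("out_dir")
        d["cluster_k_range"] = list(d["cluster_k_range"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All pipeline outputs: scalar summary + per-area tables."""

    summary: dict
    tables: dict          # name -> DataFrame
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"summary": self.summary, "provenance": self.provenance}
        (out / "report.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1, default=_jsonable)
            + "\n"
        )
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.12g")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def simulate_dataset(config: PipelineConfig) -> SyntheticDataset:
    """Generate the synthetic dataset a config describes."""
    mesh = make_sphere_mesh(config.mesh_level, hemispheres=2)
    spec = PlantedGradientSpec(
        n_axes=2,
        correlation_length=config.correlation_length,
        snr_per_modality=dict(config.snr),
        seed=derive_seed(config.seed, "simulate"),
        task_amplitude=config.task_amplitude,
    )
    return make_multimodal_dataset(
        mesh,
        spec,
        n_depths=config.n_depths,
        n_timepoints=config.n_timepoints,
        n_tasks=config.n_tasks,
        n_areas=config.n_areas,
        atlas_softness=config.atlas_softness,
    )


def embed_modality(
    conn: connectomes.Connectome,
    keep_fraction: float,
    n_components: int,
    alpha: float,
) -> embedding.GradientSet:
    """Sparsify -> normalized-angle affinity -> diffusion map."""
    sparse_c = connectomes.sparsify_rows(conn, keep_fraction)
    aff = connectomes.normalized_angle_affinity(sparse_c)
    return embedding.diffusion_map(aff, n_components=n_components, alpha=alpha)


def _area_fc(fc: np.ndarray, labeling, area_ids) -> np.ndarray:
    """Area-by-area FC: mean of vertex-pair FC between (and within) areas."""
    groups = [labeling.vertices_of(int(a)) for a in area_ids]
    n = len(groups)
    out = np.zeros((n, n))
    sums = np.array([fc[:, g].sum(axis=1) for g in groups]).T  # V x n
    for i, gi in enumerate(groups):
        block = sums[gi]                  # n_i x n
        out[i] = block.mean(axis=0) / [len(g) for g in groups]
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def run_pipeline(
    config: PipelineConfig, dataset: SyntheticDataset | None = None
) -> AnalysisReport:
    """Execute the full analysis and return (optionally write) the report."""
    t0 = time.time()
    if dataset is None:
        if config.input_dir is not None:
            from .io import read_dataset
            dataset = read_dataset(config.input_dir)
        else:
            dataset = simulate_dataset(config)
    ds = dataset
    stage = "simulate/load"
    summary: dict = {}
    tables: dict = {}
    try:
        # --- connectomes --------------------------------------------------
        stage = "connectomes"
        mpc = connectomes.build_mpc(ds.profiles)
        fc_rest = connectomes.build_fc(ds.timeseries["rest"], task_tag="rest")
        sc = connectomes.Connectome(weights=ds.sc, modality="SC")

        # --- embedding ----------------------------------------------------
        stage = "embedding"
        gradsets = []
        for conn in (mpc, sc, fc_rest):
            g = embed_modality(
                conn,
                config.keep_fraction[conn.modality],
                config.n_components,
                config.alpha,
            )
            gradsets.append(g)
            lam = g.eigenvalues
            summary[f"{conn.modality.lower()}_variance_explained_first_k"] = float(
                lam[: config.k_per_modality].sum() / lam.sum()
            )
        multimodal = embedding.normalize_and_stack(
            gradsets, k_per_modality=config.k_per_modality
        )

        # --- arealization -------------------------------------------------
        stage = "arealization"
        labeling = arealization.assign_area_labels(ds.atlas)
        profiles = arealization.compute_area_profiles(multimodal, labeling)
        ordering, pc1, var_exp = arealization.pca_reorder(profiles)
        summary["pca_pc1_variance_explained"] = float(var_exp[0])
        tables["gradient_profiles"] = pd.DataFrame(
            profiles.profiles, columns=profiles.column_names
        ).assign(area_id=profiles.area_ids, pc1_score=pc1)

        # planted-axis recovery diagnostics (synthetic ground truth)
        if ds.planted is not None:
            from scipy.stats import spearmanr
            c = ds.mesh.cortex_mask
            for m, g in zip(("mpc", "sc", "fc"), gradsets):
                rho = spearmanr(g.components[c, 0], ds.planted[c, 0]).statistic
                summary[f"{m}_g1_planted_axis_abs_rho"] = float(abs(rho))

        # --- dissimilarity ------------------------------------------------
        stage = "dissimilarity"
        inter = dissimilarity.inter_areal_dissimilarity(profiles)
        intra = dissimilarity.intra_areal_dissimilarity(multimodal, labeling)
        sim = dissimilarity.similarity_affinity(profiles)
        k_lo, k_hi = config.cluster_k_range
        clab, chosen_k, criterion = dissimilarity.cluster_areas(
            sim, k_min=k_lo, k_max=min(k_hi, len(profiles.area_ids) - 1)
        )
        summary["mean_inter_areal_dissimilarity"] = float(inter.per_area.mean())
        summary["mean_intra_areal_dissimilarity"] = float(
            np.nanmean(intra.per_vertex)
        )
        summary["clustering_chosen_k"] = int(chosen_k)
        summary["clustering_criterion"] = {
            int(k): float(v) for k, v in criterion.items()
        }

        # --- task diversity -----------------------------------------------
        stage = "taskdiversity"
        task_fc = {
            t: connectomes.build_fc(ds.timeseries[t], task_tag=t)
            for t in ds.task_names
        }
        stack = taskdiversity.TaskFCStack(fc=task_fc, task_names=ds.task_names)
        diversity = taskdiversity.cross_task_diversity(stack, labeling)
        sd_ids, sd_vals = taskdiversity.intra_areal_task_sd(stack, labeling)
        summary["mean_cross_task_diversity"] = float(
            np.nanmean(diversity.per_vertex_overall)
        )

        # --- inference ----------------------------------------------------
        stage = "inference"
        spin_seed = derive_seed(config.seed, "spin")
        area_ids = inter.area_ids
        nulls_inter = inference.spin_nulls(
            inter.per_area, labeling, ds.mesh,
            n_perm=config.n_perm, seed=spin_seed, area_ids=area_ids,
        )
        extreme = inference.extreme_area_test(
            inter.per_area, nulls_inter, q=config.fdr_q
        )
        summary["n_flag_high_dissimilarity"] = int(extreme["flag_high"].sum())
        summary["n_flag_low_dissimilarity"] = int(extreme["flag_low"].sum())

        hier = np.array([ds.hierarchy[int(a)] for a in area_ids])
        ttests = inference.hierarchy_ttests(
            inter.per_area, hier, nulls_inter, q=config.fdr_q
        )

        hist = _align(ds.histological_gradient, ds.atlas.area_ids, area_ids)
        tsnr = _align(ds.covariates["tsnr"], ds.atlas.area_ids, area_ids)
        rho_h, p_h = inference.spin_spearman(inter.per_area, hist, nulls_inter)
        summary["rho_inter_vs_histological"] = float(rho_h)
        summary["p_spin_inter_vs_histological"] = float(p_h)

        div_area = _align(diversity.per_area, diversity.area_ids, area_ids)
        rho_d, p_d = inference.spin_spearman(inter.per_area, div_area, nulls_inter)
        summary["rho_diversity_vs_inter"] = float(rho_d)
        summary["p_spin_diversity_vs_inter"] = float(p_d)

        intra_aligned = _align(intra.per_area_mean, intra.area_ids, area_ids)
        rho_i, p_i = inference.spin_spearman(
            inter.per_area, intra_aligned, nulls_inter
        )
        summary["rho_intra_vs_inter"] = float(rho_i)

        sd_aligned = _align(sd_vals, sd_ids, area_ids)
        nulls_sd = inference.spin_nulls(
            np.nan_to_num(sd_aligned, nan=np.nanmean(sd_aligned)),
            labeling, ds.mesh, n_perm=config.n_perm,
            seed=derive_seed(config.seed, "spin-sd"), area_ids=area_ids,
        )
        rho_sd, p_sd = inference.spin_spearman(
            sd_aligned, div_area, nulls_sd, covariate=tsnr
        )
        summary["rho_intra_task_sd_vs_diversity_partial_tsnr"] = float(rho_sd)
        summary["p_spin_intra_task_sd_vs_diversity_partial_tsnr"] = float(p_sd)

        afc = _area_fc(fc_rest.weights, labeling, area_ids)
        pc_coef = inference.participation_coefficient(afc, hier)
        gs = inference.global_strength(afc)
        rho_pc, _ = inference.spin_spearman(inter.per_area, pc_coef, nulls_inter)
        rho_gs, _ = inference.spin_spearman(inter.per_area, gs, nulls_inter)
        summary["rho_inter_vs_participation"] = float(rho_pc)
        summary["rho_inter_vs_global_strength"] = float(rho_gs)

        # --- tables --------------------------------------------------------
        per_area = pd.DataFrame(
            {
                "area_id": area_ids,
                "hierarchy": hier,
                "inter_areal_dissimilarity": inter.per_area,
                "intra_areal_dissimilarity": intra_aligned,
                "intra_size_adjusted": _align(
                    intra.per_area_size_adjusted, intra.area_ids, area_ids
                ),
                "cross_task_diversity": div_area,
                "intra_areal_task_sd": sd_aligned,
                "participation_coefficient": pc_coef,
                "global_fc_strength": gs,
                "cluster": clab,
                "histological_gradient": hist,
                "tsnr": tsnr,
            }
        )
        tables["per_area"] = per_area
        tables["extreme_area_test"] = extreme
        tables["hierarchy_ttests"] = ttests
        tables["pca_variance_explained"] = pd.DataFrame(
            {"component": np.arange(1, len(var_exp) + 1),
             "variance_fraction": var_exp}
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    provenance = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
    }
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    report = AnalysisReport(summary=summary, tables=tables,
                            provenance=provenance)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def _align(values, ids, target_ids) -> np.ndarray:
    """Reindex per-area values onto a target area ordering (NaN where absent)."""
    lookup = {int(a): float(v) for a, v in zip(ids, values)}
    return np.array([lookup.get(int(a), np.nan) for a in target_ids])


def _versions() -> dict:
    import scipy
    import sklearn
    from . import __version__
    return {
        "gradmosaic": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


def robustness_sweep(
    config: PipelineConfig,
    keep_fractions: list,
    k_values: list,
    dataset: SyntheticDataset | None = None,
) -> dict:
    """Stability of the dissimilarity maps across analysis settings.

    Re-embeds and re-derives the inter- and intra-areal dissimilarity maps
    for every (keep_fraction, k) combination and reports the pairwise
    Pearson correlation matrix of the resulting per-area maps.
    """
    if not keep_fractions or not k_values:
        raise ValueError("keep_fractions and k_values must be nonempty")
    ds = dataset if dataset is not None else simulate_dataset(config)
    mpc = connectomes.build_mpc(ds.profiles)
    fc_rest = connectomes.build_fc(ds.timeseries["rest"], task_tag="rest")
    sc = connectomes.Connectome(weights=ds.sc, modality="SC")
    labeling = arealization.assign_area_labels(ds.atlas)

    settings, inter_maps, intra_maps = [], [], []
    for kf in keep_fractions:
        gradsets = [
            embed_modality(c, kf, config.n_components, config.alpha)
            for c in (mpc, sc, fc_rest)
        ]
        for k in k_values:
            multimodal = embedding.normalize_and_stack(gradsets, k_per_modality=k)
            profiles = arealization.compute_area_profiles(multimodal, labeling)
            inter = dissimilarity.inter_areal_dissimilarity(profiles)
            intra = dissimilarity.intra_areal_dissimilarity(multimodal, labeling)
            settings.append({"keep_fraction": kf, "k_per_modality": k})
            inter_maps.append(inter.per_area)
            intra_maps.append(intra.per_area_mean)
    return {
        "settings": settings,
        "inter_correlation": np.atleast_2d(np.corrcoef(np.array(inter_maps))),
        "intra_correlation": np.atleast_2d(np.corrcoef(np.array(intra_maps))),
    }
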