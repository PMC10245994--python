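"""End-to-end analysis pipeline on synthetic data.

Stage order: simulate -> group connectomes -> gradients -> intermodal
tethering -> cortical projection -> surface geodesics -> covariate
correlations with spatial nulls -> composite map.  Every stochastic stage
derives its RNG stream from the single config seed, so a rerun with the same
config is bit-identical; outputs carry the config hash as provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import synthetic
from .connectome import average_connectomes, rescale01
from .cortical import (
    cortical_residual_map,
    gradient_weighted_cortical_map,
    network_decomposition,
)
from .datatypes import ParcelMap
from .gradients import DiffusionGradients, select_components
from .nulls import (
    bootstrap_correlation_difference,
    spin_test,
    variogram_surrogates,
)
from .surface import (
    geodesic_distance,
    parcellate_vertex_map,
    seed_label_from_probability,
)
from .tethering import (
    make_pair_residuals,
    pairwise_r2,
    subregion_contrast,
    weighted_residual_map,
)

logger = logging.getLogger("seedgrad.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "correlate_maps"]


@dataclass
class RunConfig:
    """All pipeline parameters with validated defaults.

    Sizes default to the package's reference synthetic study (125 seed
    voxels, 100 parcels, 173 subjects); permutation counts default to the
    standard choices for this analysis family (1000 variogram surrogates,
    10000 spins, 10000 bootstrap draws).
    """

    # synthetic data
    n_subdivisions: int = 4
    n_parcels: int = 100
    medial_wall_fraction: float = 0.05
    grid_shape: Tuple[int, int, int] = (5, 5, 5)
    subregion_split: float = 0.5
    intermodal_coupling: float = 0.5
    noise_sd: float = 0.3
    n_subjects: int = 173
    n_timepoints: int = 3840
    n_networks: int = 7
    # gradients
    sparsity: float = 0.9
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    max_structural_components: int = 6
    max_functional_components: int = 4
    # surface
    seed_threshold: float = 0.5
    seed_cap_sigma: float = 0.35
    # nulls
    n_surrogates: int = 1000
    surrogate_pv: float = 60.0
    n_spins: int = 10000
    n_boot: int = 10000
    # misc
    normalize_weights: bool = False
    invert_for_composite: Tuple[str, ...] = ("geodesic_distance", "myelin_analog")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.intermodal_coupling <= 1.0):
            raise ValueError("intermodal_coupling must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must lie in [0, 1)")
        if not (0.0 < self.seed_threshold <= 1.0):
            raise ValueError("seed_threshold must lie in (0, 1]")
        for name in ("n_parcels", "n_subjects", "n_timepoints", "n_surrogates",
                     "n_spins", "n_boot", "n_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if int(np.prod(self.grid_shape)) < 10:
            raise ValueError("grid_shape must yield at least 10 voxels")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["invert_for_composite"] = list(d["invert_for_composite"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "invert_for_composite" in d:
            d["invert_for_composite"] = tuple(d["invert_for_composite"])
        return cls(**d)


@dataclass
class RunReport:
    """Tables and maps from one pipeline run, with provenance."""

    config: RunConfig
    stages: Dict[str, object] = field(default_factory=dict)
    seeds: Dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.stages[key]


def correlate_maps(
    map_a: ParcelMap,
    map_b: ParcelMap,
    null_kind: str = "none",
    centroids: Optional[np.ndarray] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, Optional[float]]:
    """Pearson correlation of two parcel maps on their rescaled values.

    ``null_kind='spin'`` adds a spin-permutation p-value (requires parcel
    centroids on the sphere); ``'none'`` returns p = None.
    """
    if not np.array_equal(map_a.parcel_ids, map_b.parcel_ids):
        raise ValueError("maps must share parcels")
    a, b = rescale01(map_a.values), rescale01(map_b.values)
    r = float(np.corrcoef(a, b)[0, 1])
    if null_kind == "none":
        return r, None
    if null_kind != "spin":
        raise ValueError("null_kind must be 'spin' or 'none'")
    if centroids is None:
        raise ValueError("spin null needs parcel centroids")
    nd = spin_test(a, b, centroids, n_perm=n_perm, seed=seed)
    return r, nd.p_value


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig, outdir: Optional[Union[str, Path]] = None) -> RunReport:
    """Run the full analysis; returns a RunReport and optionally writes CSVs."""
    report = RunReport(config=config)
    rng = np.random.default_rng(config.seed)
    sub = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in (
            "parcellation", "seed_region", "truth", "networks", "myelin",
            "surrogates", "spins", "bootstrap", "r2_nulls",
        )
    }
    report.seeds = sub
    try:
        # 1 -- simulate ------------------------------------------------------
        _stage("simulate")
        surf = synthetic.make_sphere_surface(
            config.n_subdivisions, config.medial_wall_fraction
        )
        parc = synthetic.make_parcellation(surf, config.n_parcels, seed=sub["parcellation"])
        seed_region = synthetic.make_seed_region(
            config.grid_shape, config.subregion_split, seed=sub["seed_region"]
        )
        truth = synthetic.make_truth(
            seed_region, parc, config.intermodal_coupling, seed=sub["truth"]
        )
        networks = synthetic.make_network_labels(
            parc, config.n_networks, seed=sub["networks"]
        )
        s_list, f_list, truth = synthetic.simulate_connectomes(
            seed_region, parc, truth,
            noise_sd=config.noise_sd,
            n_subjects=config.n_subjects,
            n_timepoints=config.n_timepoints,
        )
        conn_s = average_connectomes(s_list)
        conn_f = average_connectomes(f_list)
        report.stages["surface"] = surf
        report.stages["parcellation"] = parc
        report.stages["seed_region"] = seed_region
        report.stages["truth"] = truth
        report.stages["connectomes"] = {"structural": conn_s, "functional": conn_f}

        # 2 -- gradients -----------------------------------------------------
        _stage("gradients")
        orient = seed_region.coords_mm[:, 0]
        dg_s = DiffusionGradients(
            n_components=config.n_components, sparsity=config.sparsity,
            alpha=config.alpha, diffusion_time=config.diffusion_time,
        ).fit(conn_s.values, orient_reference=orient)
        dg_f = DiffusionGradients(
            n_components=config.n_components, sparsity=config.sparsity,
            alpha=config.alpha, diffusion_time=config.diffusion_time,
        ).fit(conn_f.values, orient_reference=orient)
        grads_s = dg_s.to_gradient_set("structural")
        grads_f = dg_f.to_gradient_set("functional")
        ks = min(
            select_components(grads_s.explained_variance),
            config.max_structural_components,
        )
        kf = min(
            select_components(grads_f.explained_variance),
            config.max_functional_components,
        )
        scree = pd.DataFrame(
            {
                "component": np.arange(1, config.n_components + 1),
                "structural": grads_s.explained_variance,
                "functional": grads_f.explained_variance,
            }
        )
        voxel_maps = pd.DataFrame(
            {
                "voxel_id": seed_region.voxel_ids,
                "subregion": seed_region.subregion_labels,
                "planted_gradient": truth.planted_gradient,
                "sG1": grads_s.component(0),
                "fG1": grads_f.component(0),
            }
        )
        report.stages["gradients"] = {
            "structural": grads_s, "functional": grads_f,
            "n_structural": ks, "n_functional": kf,
            "scree": scree, "voxel_maps": voxel_maps,
        }

        # 3 -- tethering -----------------------------------------------------
        _stage("tethering")
        coords = seed_region.coords_mm
        dist_vox = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        labels = seed_region.subregion_labels
        r2 = pairwise_r2(grads_s.scores[:, :ks], grads_f.scores[:, :kf])
        # per-pair significance: variogram surrogates of the structural
        # component correlated with the fixed functional component
        r2_p = np.empty_like(r2)
        for i in range(ks):
            ens_i = variogram_surrogates(
                grads_s.component(i), dist_vox, n=config.n_surrogates,
                pv=config.surrogate_pv, seed=sub["r2_nulls"] + i,
            )
            for j in range(kf):
                obs = np.corrcoef(grads_s.component(i), grads_f.component(j))[0, 1]
                null_r = np.array(
                    [
                        np.corrcoef(s, grads_f.component(j))[0, 1]
                        for s in ens_i.surrogates
                    ]
                )
                r2_p[i, j] = (1 + np.sum(np.abs(null_r) >= abs(obs))) / (
                    1 + len(null_r)
                )
        pairs = make_pair_residuals(grads_s, grads_f, ks, kf)
        wrm = weighted_residual_map(pairs, normalize_weights=config.normalize_weights)

        contrasts = []
        contrast_inputs = {
            "sG1": grads_s.component(0),
            "fG1": grads_f.component(0),
            "weighted_residual": wrm.values,
        }
        for offset, (name, vals) in enumerate(contrast_inputs.items()):
            ens = variogram_surrogates(
                rescale01(vals), dist_vox, n=config.n_surrogates,
                pv=config.surrogate_pv, seed=sub["surrogates"] + offset,
            )
            for stat in ("mean_diff", "cov_diff"):
                obs, p, _ = subregion_contrast(
                    rescale01(vals), labels, stat, ens, rescale=False
                )
                contrasts.append(
                    {
                        "map": name, "statistic": stat, "observed": obs,
                        "p_perm": p, "n_surrogates": config.n_surrogates,
                    }
                )
        r2_df = pd.DataFrame(
            r2,
            index=[f"sG{i + 1}" for i in range(ks)],
            columns=[f"fG{j + 1}" for j in range(kf)],
        )
        report.stages["tethering"] = {
            "r2": r2_df,
            "r2_p": pd.DataFrame(r2_p, index=r2_df.index, columns=r2_df.columns),
            "pairs": pairs,
            "weighted_residual_map": wrm,
            "contrasts": pd.DataFrame(contrasts),
            "mean_r2": float(r2.mean()),
        }

        # 4 -- cortical maps -------------------------------------------------
        _stage("cortical")
        s_maps = [
            gradient_weighted_cortical_map(
                conn_s, grads_s.component(p.structural_index), name=f"sG{p.structural_index + 1}ctx"
            )
            for p in pairs
        ]
        f_maps = [
            gradient_weighted_cortical_map(
                conn_f, grads_f.component(p.functional_index), name=f"fG{p.functional_index + 1}ctx"
            )
            for p in pairs
        ]
        crm = cortical_residual_map(
            s_maps, f_maps, [p.weight for p in pairs],
            normalize_weights=config.normalize_weights,
        )
        sg1ctx = gradient_weighted_cortical_map(conn_s, grads_s.component(0), "sG1ctx")
        fg1ctx = gradient_weighted_cortical_map(conn_f, grads_f.component(0), "fG1ctx")
        crm_map = ParcelMap(
            parcel_ids=parc.parcel_ids, values=crm.values, name="cortical_residual"
        )
        report.stages["cortical"] = {
            "sG1ctx": sg1ctx,
            "fG1ctx": fg1ctx,
            "residual_map": crm_map,
            "networks": networks,
            "network_decomposition": {
                "sG1ctx": network_decomposition(sg1ctx, networks),
                "fG1ctx": network_decomposition(fg1ctx, networks),
                "residual": network_decomposition(crm_map, networks),
            },
        }

        # 5 -- surface geodesics --------------------------------------------
        _stage("surface")
        seed_dir = seed_region.coords_mm.mean(axis=0)
        seed_dir = seed_dir / np.linalg.norm(seed_dir)
        angles = np.arccos(np.clip(surf.vertices @ seed_dir, -1, 1))
        prob = np.exp(-0.5 * (angles / config.seed_cap_sigma) ** 2)
        seed_label = seed_label_from_probability(prob, config.seed_threshold)
        dist_vertex = geodesic_distance(surf, seed_label)
        dist_map = parcellate_vertex_map(
            dist_vertex, parc, rescale=True, name="geodesic_distance"
        )
        report.stages["surface_distance"] = {
            "seed_label": seed_label,
            "vertex_distance": dist_vertex,
            "parcel_map": dist_map,
        }

        # 6 -- covariate maps ------------------------------------------------
        _stage("covariates")
        myelin = synthetic.make_autocorrelated_map(
            parc, correlation_length=0.4, seed=sub["myelin"], name="myelin_analog"
        )
        tracer = ParcelMap(
            parcel_ids=parc.parcel_ids, values=truth.branch_field, name="tracer_analog"
        )
        report.stages["covariates"] = {"myelin_analog": myelin, "tracer_analog": tracer}

        # 7 -- spatial statistics -------------------------------------------
        _stage("nulls")
        cent = parc.centroids
        conn_strength_s = ParcelMap(parc.parcel_ids, conn_s.values.mean(axis=0), "structural_strength")
        conn_strength_f = ParcelMap(parc.parcel_ids, conn_f.values.mean(axis=0), "functional_strength")
        correlations = []
        spin_pairs = [
            ("structural_strength", conn_strength_s, dist_map),
            ("functional_strength", conn_strength_f, dist_map),
            ("residual_vs_distance", crm_map, dist_map),
            ("residual_vs_myelin", crm_map, myelin),
            ("residual_vs_tracer", crm_map, tracer),
            ("tracer_vs_distance", tracer, dist_map),
        ]
        for i, (name, a, b) in enumerate(spin_pairs):
            r, p = correlate_maps(
                a, b, null_kind="spin", centroids=cent,
                n_perm=config.n_spins, seed=sub["spins"] + i,
            )
            correlations.append(
                {"pair": name, "r": r, "p_spin": p, "n_perm": config.n_spins}
            )
        diff, lo, hi, p_boot = bootstrap_correlation_difference(
            rescale01(dist_map.values),
            rescale01(conn_strength_f.values),
            rescale01(conn_strength_s.values),
            n_boot=config.n_boot,
            seed=sub["bootstrap"],
        )
        report.stages["statistics"] = {
            "correlations": pd.DataFrame(correlations),
            "bootstrap_functional_minus_structural": {
                "difference": diff, "ci_low": lo, "ci_high": hi,
                "p_boot": p_boot, "n_boot": config.n_boot,
            },
        }

        # 8 -- composite map -------------------------------------------------
        _stage("composite")
        components = {
            "cortical_residual": crm_map,
            "tracer_analog": tracer,
            "geodesic_distance": dist_map,
            "myelin_analog": myelin,
        }
        acc = np.zeros(parc.n_parcels)
        for name, pm in components.items():
            v = rescale01(pm.values)
            if name in config.invert_for_composite:
                v = 1.0 - v
            acc += v
        composite = ParcelMap(
            parcel_ids=parc.parcel_ids, values=acc / len(components), name="composite"
        )
        report.stages["composite"] = composite
    except Exception as exc:
        failed = len(report.stages)
        raise RuntimeError(
            f"pipeline failed after {failed} completed stages: {exc}"
        ) from exc

    if outdir is not None:
        _write_outputs(report, Path(outdir))
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    from .io import parcel_map_to_csv

    outdir.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    header = f"# seedgrad config_hash={cfg.config_hash()} seed={cfg.seed}\n"

    def write_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=index)

    (outdir / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2))
    (outdir / "seeds.json").write_text(json.dumps(report.seeds, indent=2))
    g = report.stages["gradients"]
    write_df(g["scree"], "scree.csv")
    write_df(g["voxel_maps"], "voxel_gradients.csv")
    t = report.stages["tethering"]
    write_df(t["r2"], "pairwise_r2.csv", index=True)
    write_df(t["r2_p"], "pairwise_r2_pvalues.csv", index=True)
    write_df(t["contrasts"], "subregion_contrasts.csv")
    wrm = t["weighted_residual_map"]
    write_df(
        pd.DataFrame(
            {
                "voxel_id": report.stages["seed_region"].voxel_ids,
                "weighted_residual": wrm.values,
            }
        ),
        "weighted_residual_map.csv",
    )
    c = report.stages["cortical"]
    for key in ("sG1ctx", "fG1ctx", "residual_map"):
        parcel_map_to_csv(c[key], outdir / f"{key}.csv")
    write_df(
        pd.concat(
            {k: v for k, v in c["network_decomposition"].items()},
            names=["map"],
        ).reset_index(level=0),
        "network_decomposition.csv",
    )
    parcel_map_to_csv(report.stages["surface_distance"]["parcel_map"], outdir / "geodesic_distance.csv")
    parcel_map_to_csv(report.stages["covariates"]["myelin_analog"], outdir / "myelin_analog.csv")
    parcel_map_to_csv(report.stages["covariates"]["tracer_analog"], outdir / "tracer_analog.csv")
    s = report.stages["statistics"]
    write_df(s["correlations"], "spin_correlations.csv")
    (outdir / "bootstrap.json").write_text(
        json.dumps(s["bootstrap_functional_minus_structural"], indent=2)
    )
    parcel_map_to_csv(report.stages["composite"], outdir / "composite_map.csv")
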