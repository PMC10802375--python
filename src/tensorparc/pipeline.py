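"""End-to-end orchestration: simulate -> sync -> decompose -> parcellate
-> evaluate, with a serializable config and a reproducible run manifest.

Every random stage draws its seed deterministically from the config's
master seed, so two runs with an identical config produce bitwise
identical outputs (including GIFTI label files). Each stage writes its
outputs before the next starts; disabled stages are reloaded from a
previous run's output directory when later stages need them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import mesh as mesh_mod
from .cp import GroupTensor, cp_decompose, feature_matrix
from .embedding import (Parcellation, ParcellateConfig, hyperparameter_schedule,
                        parcellate_hemisphere)
from .evaluation import adjusted_rand_index, homogeneity, ratio_curve, rsfc_z
from .sync import normalize_timeseries, sync_group
from .synthetic import make_dataset, make_ground_truth

__all__ = ["RunConfig", "run_pipeline", "hyperparameter_schedule"]

log = logging.getLogger("tensorparc")

STAGES = ("simulate", "sync", "decompose", "parcellate", "evaluate")
HEMIS = ("left", "right")


@dataclass
class RunConfig:
    """All pipeline hyperparameters; round-trips losslessly through YAML."""

    out_dir: str = "tensorparc_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # synthetic data
    mesh_subdivisions: int = 3
    n_subjects: int = 8
    t_session: int = 60
    rank_truth: int = 6
    n_parcels_truth: int = 10
    smoothness: float = 3.0
    overlap: float = 0.5
    noise_sd: float = 0.3
    single_session_fraction: float = 0.25
    # synchronization
    sync_max_iter: int = 10
    sync_tol: float = 1e-6
    # decomposition
    rank: int = 6
    cp_max_iter: int = 200
    cp_tol: float = 1e-8
    feature_scaling: str = "unit_norm"
    # parcellation
    parcels_per_hemi: int = 10
    sigma: float = 0.5
    kernel_form: str = "similarity"
    nb: int | None = None
    window: int | None = None
    nb_scale: float | str = "auto"
    dim: int = 128
    negative_samples: int = 1
    embed_scaling: str = "sqrt_singular"
    n_init: int = 500
    kmeans_max_iter: int = 20000
    # evaluation
    null_draws: int = 50
    ratio_ks: list[int] = field(default_factory=lambda: [5, 10, 20])

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def stage_seed(self, stage: str, hemi: str) -> int:
        """Deterministic per-(stage, hemisphere) seed below 2**31."""
        h = f"{stage}:{hemi}"
        return int((self.seed * 1_000_003 + sum(ord(c) * 31**i for i, c in enumerate(h))) % (2**31 - 1))

    def parcellate_config(self, hemi: str) -> ParcellateConfig:
        return ParcellateConfig(
            sigma=self.sigma, kernel_form=self.kernel_form, nb=self.nb,
            window=self.window, dim=self.dim,
            negative_samples=self.negative_samples,
            embed_scaling=self.embed_scaling, n_init=self.n_init,
            kmeans_max_iter=self.kmeans_max_iter,
            seed=self.stage_seed("parcellate", hemi), nb_scale=self.nb_scale,
            total_parcels=2 * self.parcels_per_hemi,
        )


def _save_h5(path, arrays: dict[str, np.ndarray]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for k, v in arrays.items():
            fh.create_dataset(k, data=v)


def _load_h5(path) -> dict[str, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as fh:
        return {k: fh[k][()] for k in fh}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    A stage failure raises with the stage named; outputs of completed
    stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "outputs": {}}
    ctx: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        log.info("stage %s starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out, ctx, manifest)
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest


def _get_mesh(config: RunConfig, hemi: str, ctx: dict) -> mesh_mod.SurfaceMesh:
    key = f"mesh_{hemi}"
    if key not in ctx:
        m = mesh_mod.build_icosphere(config.mesh_subdivisions)
        m.hemisphere = hemi
        ctx[key] = m
    return ctx[key]


def _sessions(config: RunConfig, rng: np.random.Generator) -> list[int]:
    n_single = int(round(config.single_session_fraction * config.n_subjects))
    sessions = [1] * n_single + [2] * (config.n_subjects - n_single)
    rng.shuffle(sessions)
    return sessions


def _stage_simulate(config, out, ctx, manifest):
    for hemi in HEMIS:
        mesh = _get_mesh(config, hemi, ctx)
        seed = config.stage_seed("simulate", hemi)
        truth = make_ground_truth(
            mesh, n_parcels=config.n_parcels_truth, R=config.rank_truth,
            smoothness=config.smoothness, overlap=config.overlap,
            n_timepoints=2 * config.t_session, n_subjects=config.n_subjects,
            noise_sd=config.noise_sd, seed=seed,
        )
        sessions = _sessions(config, np.random.default_rng(seed + 1))
        subjects, tensor = make_dataset(truth, config.n_subjects, config.t_session,
                                        sessions, seed=seed + 2)
        ctx[f"truth_{hemi}"], ctx[f"subjects_{hemi}"] = truth, subjects
        surf = out / f"{hemi}.surf.gii"
        mesh_mod.write_surface(surf, mesh)
        lab = out / f"{hemi}.truth.label.gii"
        mesh_mod.write_labels(lab, truth.parcellation.labels)
        h5 = out / f"{hemi}.data.h5"
        _save_h5(h5, {"tensor": tensor.data,
                      "truth_labels": truth.parcellation.labels,
                      "truth_maps": truth.networks.spatial_maps,
                      "sessions": np.array(sessions)})
        manifest["outputs"][f"simulate_{hemi}"] = [str(surf), str(lab), str(h5)]


def _stage_sync(config, out, ctx, manifest):
    for hemi in HEMIS:
        if f"subjects_{hemi}" not in ctx:
            data = _load_h5(out / f"{hemi}.data.h5")
            ctx[f"subjects_{hemi}"] = [data["tensor"][:, :, s].T
                                       for s in range(data["tensor"].shape[2])]
        normalized = [normalize_timeseries(s)[0] for s in ctx[f"subjects_{hemi}"]]
        res = sync_group(normalized, max_iter=config.sync_max_iter, tol=config.sync_tol)
        ctx[f"sync_{hemi}"] = res
        h5 = out / f"{hemi}.sync.h5"
        _save_h5(h5, {"aligned": np.stack(res.aligned),
                      "transforms": np.stack(res.transforms),
                      "template": res.template,
                      "objective_trace": np.array(res.objective_trace)})
        manifest["outputs"][f"sync_{hemi}"] = [str(h5)]


def _stage_decompose(config, out, ctx, manifest):
    for hemi in HEMIS:
        if f"sync_{hemi}" in ctx:
            aligned = ctx[f"sync_{hemi}"].aligned
        else:
            aligned = list(_load_h5(out / f"{hemi}.sync.h5")["aligned"])
        tensor = GroupTensor(np.stack([a.T for a in aligned], axis=2))
        nets = cp_decompose(tensor, R=config.rank, max_iter=config.cp_max_iter,
                            tol=config.cp_tol,
                            seed=config.stage_seed("decompose", hemi))
        ctx[f"networks_{hemi}"] = nets
        h5 = out / f"{hemi}.networks.h5"
        _save_h5(h5, {"magnitudes": nets.magnitudes,
                      "spatial_maps": nets.spatial_maps,
                      "time_courses": nets.time_courses,
                      "subject_loadings": nets.subject_loadings,
                      "error_trace": np.array(nets.error_trace)})
        mesh_mod.write_metric(out / f"{hemi}.maps.func.gii", nets.spatial_maps)
        manifest["outputs"][f"decompose_{hemi}"] = [
            str(h5), str(out / f"{hemi}.maps.func.gii")]


def _stage_parcellate(config, out, ctx, manifest):
    for hemi in HEMIS:
        mesh = _get_mesh(config, hemi, ctx)
        if f"networks_{hemi}" in ctx:
            nets = ctx[f"networks_{hemi}"]
        else:
            d = _load_h5(out / f"{hemi}.networks.h5")
            from .cp import NetworkSet

            nets = NetworkSet(d["magnitudes"], d["spatial_maps"],
                              d["time_courses"], d["subject_loadings"])
        feats = feature_matrix(nets, scaling=config.feature_scaling)
        parc, graph, emb = parcellate_hemisphere(
            feats, mesh, k=config.parcels_per_hemi,
            config=config.parcellate_config(hemi), return_audit=True)
        ctx[f"parcellation_{hemi}"] = parc
        lab = out / f"{hemi}.parcellation.label.gii"
        mesh_mod.write_labels(lab, parc.labels)
        h5 = out / f"{hemi}.audit.h5"
        _save_h5(h5, {"A": graph.correlation, "M": emb.M,
                      "B": emb.embeddings, "labels": parc.labels,
                      "trial_costs": parc.trial_costs,
                      "nb": np.array(graph.nb),
                      "singular_values": emb.singular_values})
        manifest["outputs"][f"parcellate_{hemi}"] = [str(lab), str(h5)]


def _stage_evaluate(config, out, ctx, manifest):
    import pandas as pd

    rows = []
    summary: dict = {}
    for hemi in HEMIS:
        mesh = _get_mesh(config, hemi, ctx)
        if f"parcellation_{hemi}" in ctx:
            parc = ctx[f"parcellation_{hemi}"]
        else:
            labels, _ = mesh_mod.read_labels(out / f"{hemi}.parcellation.label.gii")
            parc = Parcellation(labels=labels, n_parcels=int(labels.max()) + 1)
        if f"subjects_{hemi}" not in ctx:
            data = _load_h5(out / f"{hemi}.data.h5")
            ctx[f"subjects_{hemi}"] = [data["tensor"][:, :, s].T
                                       for s in range(data["tensor"].shape[2])]
        zs = [rsfc_z(s)[0] for s in ctx[f"subjects_{hemi}"]]
        homs = [homogeneity(z, parc).weighted_average for z in zs]
        for s, h in enumerate(homs):
            rows.append({"hemisphere": hemi, "subject": s, "metric": "homogeneity",
                         "value": h})
        summary[f"homogeneity_{hemi}"] = float(np.mean(homs))
        truth_path = out / f"{hemi}.truth.label.gii"
        if f"truth_{hemi}" in ctx:
            truth_labels = ctx[f"truth_{hemi}"].parcellation.labels
        elif truth_path.exists():
            truth_labels, _ = mesh_mod.read_labels(truth_path)
        else:
            truth_labels = None
        if truth_labels is not None:
            summary[f"ari_{hemi}"] = adjusted_rand_index(truth_labels, parc.labels)
        if config.ratio_ks:
            ratios = ratio_curve({parc.n_parcels: parc}, mesh, metric="homogeneity",
                                 z_matrices=zs, null_draws=config.null_draws,
                                 seed=config.stage_seed("evaluate", hemi))
            summary[f"homogeneity_ratio_{hemi}"] = ratios[parc.n_parcels]
    csv = out / "evaluation.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    with open(out / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["outputs"]["evaluate"] = [str(csv), str(out / "evaluation.json")]
    manifest["evaluation"] = summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "sync": _stage_sync,
    "decompose": _stage_decompose,
    "parcellate": _stage_parcellate,
    "evaluate": _stage_evaluate,
}
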