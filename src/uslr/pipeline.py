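"""Two-stage pipeline orchestration: rigid alignment, then diffeomorphic refinement.

Stage order and file layout
---------------------------
``rigid``     pairwise rigid registrations + graph inference -> latent rigid logs
``diff``      pairwise SVF registrations on the rigidly-aligned images + graph
              inference -> latent velocity fields (requires ``rigid``)
``template``  unbiased subject space + fused template (requires both)
``trajectory``voxelwise linear fit of the latent SVFs + 1-year Jacobian map
``seg``       time-consistent label fusion per timepoint + volume table

Inputs follow a BIDS-like subject directory: ``sessions.tsv`` (columns
``session_id``, ``years_from_baseline``) and per session
``<ses>/<ses>_T1w.nii.gz`` and ``<ses>/<ses>_dseg.nii.gz``. Every emitted
image is resampled from the original inputs through a concatenated transform
chain — one interpolation per product. A JSON manifest records inputs,
outputs, seed and a config hash, and lets later stages resume from the
transforms already on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import FusionConfig, fuse_labels, label_volumes, normalize_intensities
from .graph import ObservationGraph, TimepointNode, build_full_graph
from .inference import InferenceConfig, solve_rigid_graph, solve_svf_graph
from .lie_rigid import (RigidLog, load_rigid_log, rigid_exp, rigid_log,
                        load_rigid_matrix, save_rigid_log, save_rigid_matrix)
from .registration import RegistrationConfig, centroid_rigid_register, ssd_svf_register
from .svf import (ImageGrid, VelocityField, load_scalar_volume, load_velocity_field,
                  resample_image, save_scalar_volume, save_velocity_field)
from .template import build_template, define_subject_space, timepoint_pullback_chain
from .trajectory import fit_stationary_trajectory, jacobian_period

__all__ = ["PipelineConfig", "run_pipeline", "load_subject"]

ALL_STAGES = ("rigid", "diff", "template", "trajectory", "seg")
_DEPS = {
    "rigid": (),
    "diff": ("rigid",),
    "template": ("rigid", "diff"),
    "trajectory": ("diff",),
    "seg": ("rigid", "diff"),
}


class MissingStageError(RuntimeError):
    """A requested stage depends on a stage that has not been run."""


@dataclass
class PipelineConfig:
    subject_dir: str
    out_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    backend: str = "centroid+ssd"  # or "precomputed"
    subject_spacing: float | None = None  # None: finest input spacing
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    wm_label_ids: tuple[int, ...] = (2,)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Subject:
    nodes: list[TimepointNode]
    images: list[np.ndarray]
    labelmaps: list[np.ndarray]
    grids: list[ImageGrid]

    @property
    def times(self) -> list[float]:
        return [n.time_from_baseline for n in self.nodes]

    @property
    def masks(self) -> list[np.ndarray]:
        return [(lm > 0).astype(float) for lm in self.labelmaps]


def load_subject(subject_dir: str | Path) -> Subject:
    subject_dir = Path(subject_dir)
    sessions = pd.read_csv(subject_dir / "sessions.tsv", sep="\t")
    nodes, images, labelmaps, grids = [], [], [], []
    for i, row in sessions.iterrows():
        ses = str(row["session_id"])
        img_path = subject_dir / ses / f"{ses}_T1w.nii.gz"
        lab_path = subject_dir / ses / f"{ses}_dseg.nii.gz"
        img, grid = load_scalar_volume(img_path)
        lab, lgrid = load_scalar_volume(lab_path)
        if not grid.matches(lgrid):
            raise ValueError(f"{ses}: image and labelmap grids differ")
        nodes.append(TimepointNode(int(i), float(row["years_from_baseline"]),
                                   str(img_path), str(lab_path)))
        images.append(np.asarray(img, dtype=float))
        labelmaps.append(np.asarray(lab).astype(np.int16))
        grids.append(grid)
    if len(nodes) < 2:
        raise ValueError("a longitudinal subject needs at least 2 sessions")
    return Subject(nodes, images, labelmaps, grids)


def _require(out: Path, stage: str, done: set[str]) -> None:
    for dep in _DEPS[stage]:
        if dep in done:
            continue
        marker = {
            "rigid": out / "latents" / "rigid_00.log.txt",
            "diff": out / "latents" / "svf_00.nii.gz",
        }.get(dep)
        if marker is None or not marker.exists():
            raise MissingStageError(f"stage '{stage}' requires stage '{dep}' to have run")
        done.add(dep)


def _load_rigid_latents(out: Path, n: int) -> list[RigidLog]:
    return [load_rigid_log(out / "latents" / f"rigid_{i:02d}.log.txt") for i in range(n)]


def _load_svf_latents(out: Path, n: int) -> list[VelocityField]:
    return [load_velocity_field(out / "latents" / f"svf_{i:02d}.nii.gz",
                                kind=VelocityField) for i in range(n)]


def _subject_grid(out: Path) -> ImageGrid:
    meta = json.loads((out / "subject_space.json").read_text())
    return ImageGrid(tuple(meta["shape"]), np.array(meta["affine"]))


def _stage_rigid(cfg: PipelineConfig, subj: Subject, out: Path, manifest: dict) -> None:
    g = build_full_graph(subj.nodes)
    tdir = out / "transforms"
    tdir.mkdir(parents=True, exist_ok=True)
    for e in g.edges:
        path = tdir / f"rigid_obs_{e.ref_index:02d}_{e.tgt_index:02d}.txt"
        if cfg.backend == "precomputed":
            m = load_rigid_matrix(path)
        else:
            m = centroid_rigid_register(
                subj.labelmaps[e.ref_index], subj.grids[e.ref_index],
                subj.labelmaps[e.tgt_index], subj.grids[e.tgt_index],
            )
            save_rigid_matrix(m, path)
        e.log_params = rigid_log(m)
    latents = solve_rigid_graph(g, cfg.inference)
    (out / "latents").mkdir(exist_ok=True)
    for i, l in enumerate(latents):
        save_rigid_log(l, out / "latents" / f"rigid_{i:02d}.log.txt")

    spacing = cfg.subject_spacing or min(float(g.spacing.min()) for g in subj.grids)
    grid = define_subject_space(latents, subj.grids, spacing=spacing)
    (out / "subject_space.json").write_text(json.dumps(
        {"shape": list(grid.shape), "affine": grid.affine.tolist()}))
    manifest["stages"]["rigid"] = {"n_edges": g.n_edges,
                                   "latents": [f"latents/rigid_{i:02d}.log.txt"
                                               for i in range(len(latents))]}


def _stage_diff(cfg: PipelineConfig, subj: Subject, out: Path, manifest: dict) -> None:
    n = len(subj.nodes)
    rigid_latents = _load_rigid_latents(out, n)
    grid = _subject_grid(out)
    # rigid-only resample onto the subject grid, used solely to drive the
    # non-linear registrations; final products resample from the originals
    aligned = [resample_image(img, g, [rigid_exp(l)], grid)
               for img, g, l in zip(subj.images, subj.grids, rigid_latents)]

    g = build_full_graph(subj.nodes)
    tdir = out / "transforms"
    tdir.mkdir(parents=True, exist_ok=True)
    for e in g.edges:
        path = tdir / f"svf_obs_{e.ref_index:02d}_{e.tgt_index:02d}.nii.gz"
        if cfg.backend == "precomputed":
            v = load_velocity_field(path, expect_grid=grid, kind=VelocityField)
        else:
            v = ssd_svf_register(aligned[e.ref_index], aligned[e.tgt_index],
                                 grid, cfg.registration)
            save_velocity_field(v, path)
        e.log_params = v
    latents = solve_svf_graph(g, cfg.inference)
    for i, v in enumerate(latents):
        save_velocity_field(v, out / "latents" / f"svf_{i:02d}.nii.gz")
    manifest["stages"]["diff"] = {"n_edges": g.n_edges,
                                  "latents": [f"latents/svf_{i:02d}.nii.gz"
                                              for i in range(n)]}


def _stage_template(cfg: PipelineConfig, subj: Subject, out: Path, manifest: dict):
    n = len(subj.nodes)
    template = build_template(
        subj.images, subj.grids,
        _load_rigid_latents(out, n), _load_svf_latents(out, n),
        _subject_grid(out), masks=subj.masks, labelmaps=subj.labelmaps,
    )
    files = template.save(out, prefix="template")
    manifest["stages"]["template"] = files
    return template


def _stage_trajectory(cfg: PipelineConfig, subj: Subject, out: Path, manifest: dict):
    n = len(subj.nodes)
    fit = fit_stationary_trajectory(_load_svf_latents(out, n), subj.times)
    save_velocity_field(fit.slope, out / "trajectory_slope.nii.gz")
    save_velocity_field(fit.intercept, out / "trajectory_intercept.nii.gz")
    jac = jacobian_period(fit, 1.0)
    save_scalar_volume(jac.astype(np.float32), fit.slope.grid, out / "jacobian_1y.nii.gz")
    manifest["stages"]["trajectory"] = {
        "slope": "trajectory_slope.nii.gz",
        "intercept": "trajectory_intercept.nii.gz",
        "jacobian_1y": "jacobian_1y.nii.gz",
    }
    return fit


def _stage_seg(cfg: PipelineConfig, subj: Subject, out: Path, manifest: dict) -> None:
    n = len(subj.nodes)
    rigid_latents = _load_rigid_latents(out, n)
    svf_latents = _load_svf_latents(out, n)
    normed = [normalize_intensities(img, lab, cfg.wm_label_ids, cfg.fusion)
              for img, lab in zip(subj.images, subj.labelmaps)]
    seg_dir = out / "seg"
    seg_dir.mkdir(exist_ok=True)
    rows = []
    outputs = {}
    for i in range(n):
        fused = fuse_labels(i, normed, subj.labelmaps, subj.grids,
                            rigid_latents, svf_latents, cfg.fusion)
        path = seg_dir / f"ses-{i:02d}_space-orig_dseg.nii.gz"
        save_scalar_volume(fused.astype(np.int16), subj.grids[i], path)
        outputs[f"ses-{i:02d}"] = str(path)
        vols = label_volumes(fused, subj.grids[i])
        vols.insert(0, "session", i)
        vols.insert(1, "years_from_baseline", subj.times[i])
        rows.append(vols)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "volumes.csv", index=False)
    manifest["stages"]["seg"] = {"labelmaps": outputs, "volumes": "volumes.csv"}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    subj = load_subject(cfg.subject_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest.update({
        "subject_dir": str(cfg.subject_dir),
        "inputs": [n.image_path for n in subj.nodes],
        "times": subj.times,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    })

    done = set(manifest["stages"])
    runners = {"rigid": _stage_rigid, "diff": _stage_diff, "template": _stage_template,
               "trajectory": _stage_trajectory, "seg": _stage_seg}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        _require(out, stage, done)
        runners[stage](cfg, subj, out, manifest)
        done.add(stage)
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
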