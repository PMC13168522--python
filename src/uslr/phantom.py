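"""Synthetic longitudinal phantoms with known ground truth.

Emulates the generative model the framework assumes: a geometric subject
template (nested ellipsoids with tissue-like intensities), per-timepoint
latent transforms built as rigid jitter plus a smooth atrophy velocity field
scaled by acquisition time (mean-subtracted so the latents sum to zero, the
drift-free condition), images produced by a single-interpolation warp of the
template plus additive Gaussian intensity noise, per-timepoint labelmaps
with an independent smooth segmentation-error warp, and pairwise
registration observations equal to the true log-domain compositions
corrupted by Laplacian noise (optionally with gross outlier edges).

Every draw runs through one seeded generator, so a seed fixes the phantom
bitwise. Realistic MRI physics (bias fields, Rician noise) is out of scope;
the additive-noise model matches what the inference assumes, which is the
point: tests isolate the estimator from the registration backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .graph import ObservationEdge, ObservationGraph, TimepointNode
from .lie_rigid import RigidLog, rigid_exp
from .svf import DisplacementField, ImageGrid, VelocityField, resample_image, svf_exp
from .template import SubjectTemplate

__all__ = [
    "PhantomStructure",
    "PhantomConfig",
    "LongitudinalSeries",
    "make_phantom_template",
    "atrophy_slope_field",
    "simulate_longitudinal_series",
    "pairwise_true_logs",
    "corrupt_registrations",
    "write_phantom",
]


@dataclass(frozen=True)
class PhantomStructure:
    """An ellipsoidal structure: label id, centre (mm), radii (mm), intensity,
    and volume change in percent per year (negative = atrophy)."""

    label: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float
    atrophy_pct_per_year: float = 0.0


def _default_structures() -> tuple[PhantomStructure, ...]:
    # WM-like intensity 110 so the label-fusion normalisation is exercised untouched.
    # Rates mimic an AD-like subject: diffuse cortical loss, focal medial-temporal
    # atrophy, ventricular expansion.
    return (
        PhantomStructure(1, (0.0, 0.0, 0.0), (60.0, 54.0, 51.0), 70.0, -0.8),  # GM-like shell
        PhantomStructure(2, (0.0, 0.0, 0.0), (42.0, 36.0, 33.0), 110.0),       # WM-like core
        PhantomStructure(3, (18.0, 15.0, -12.0), (15.0, 13.5, 12.0), 85.0, -3.0),  # hippocampus-like
        PhantomStructure(4, (-15.0, 15.0, 9.0), (15.0, 12.0, 12.0), 30.0, 6.0),    # ventricle-like
        # off the plane of the other centroids, so label-centroid rigid
        # alignment is well-conditioned in all six degrees of freedom
        PhantomStructure(5, (0.0, -21.0, -15.0), (10.5, 9.0, 9.0), 95.0),          # cerebellum-like
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    A head-sized field of view on a coarse grid (48 voxels at 3 mm cover
    144 mm), so structure sizes and the millimetre scale of atrophy
    displacements stay anatomical while volumes remain desk-sized. Follow-up
    of 2 years over 5 unevenly spaced sessions, head repositioning jitter of
    a couple of degrees / millimetres, a small smooth fluctuation of the
    latent deformations around their linear trend, intensity noise a few
    percent of the white-matter level, sub-voxel segmentation error, and
    pairwise-registration noise of a quarter millimetre — the regime of a
    longitudinal T1w study in elderly adults processed with a learned
    registration backend.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 3.0
    structures: tuple[PhantomStructure, ...] = field(default_factory=_default_structures)
    times: tuple[float, ...] = (0.0, 0.35, 0.9, 1.4, 2.0)
    rigid_rot_deg: float = 2.0
    rigid_trans_mm: float = 2.0
    svf_perturb_mm: float = 0.1
    image_noise_sd: float = 3.0
    seg_noise_mm: float = 1.0
    reg_noise_b: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        scales = (self.rigid_rot_deg, self.rigid_trans_mm, self.svf_perturb_mm,
                  self.image_noise_sd, self.seg_noise_mm, self.reg_noise_b)
        if any(s < 0 for s in scales):
            raise ValueError("noise scales must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return len(self.times)


def make_phantom_template(cfg: PhantomConfig) -> SubjectTemplate:
    """Deterministic geometric template: intensity, mask and labelmap.

    Structures are painted in listed order (later entries overwrite earlier
    ones where they overlap). The grid is isotropic RAS, centred at the world
    origin. An empty structure list yields an all-background volume.
    """
    grid = ImageGrid.isotropic(cfg.shape, cfg.spacing, centred=True)
    world = grid.world_coordinates()
    labels = np.zeros(cfg.shape, dtype=np.int16)
    intensity = np.zeros(cfg.shape)
    for s in cfg.structures:
        rel = (world - np.array(s.center)) / np.array(s.radii)
        inside = np.sum(rel**2, axis=-1) <= 1.0
        labels[inside] = s.label
        intensity[inside] = s.intensity
    # mild smoothing gives the intensity image usable gradients for registration
    intensity = ndimage.gaussian_filter(intensity, 0.6)
    mask = (labels > 0).astype(float)
    return SubjectTemplate(grid, intensity, mask, labels)


def atrophy_slope_field(cfg: PhantomConfig, grid: ImageGrid) -> VelocityField:
    """Per-year slope SVF realising each structure's volume change rate.

    Inside a structure with rate r %/yr the field is the linear contraction
    ``(delta/3) (x - c)`` with ``delta = ln(1 + r/100)``, windowed by a
    plateau that is 1 over the (slightly dilated) structure and decays
    smoothly outside, so the divergence inside is uniform and the flow over
    one year multiplies the structure volume by exactly ``1 + r/100``.
    """
    world = grid.world_coordinates()
    values = np.zeros(grid.shape + (3,))
    labelmap = make_phantom_template(cfg).segmentation
    for s in cfg.structures:
        if s.atrophy_pct_per_year == 0.0:
            continue
        delta = np.log1p(s.atrophy_pct_per_year / 100.0)
        mask = labelmap == s.label
        window = ndimage.binary_dilation(mask, iterations=3).astype(float)
        window = ndimage.gaussian_filter(window, 1.5)
        window /= max(window.max(), 1e-12)
        values += (delta / 3.0) * (world - np.array(s.center)) * window[..., None]
    return VelocityField(grid, values)


@dataclass
class LongitudinalSeries:
    """A simulated subject: per-timepoint data plus the generating ground truth."""

    grid: ImageGrid
    times: tuple[float, ...]
    images: list[np.ndarray]
    labelmaps: list[np.ndarray]
    masks: list[np.ndarray]
    true_rigid: list[RigidLog]
    true_svf: list[VelocityField]
    slope: VelocityField

    @property
    def nodes(self) -> list[TimepointNode]:
        return [TimepointNode(i, t) for i, t in enumerate(self.times)]

    @property
    def grids(self) -> list[ImageGrid]:
        return [self.grid] * len(self.times)


def _smooth_random_field(grid: ImageGrid, amplitude_mm: float,
                         rng: np.random.Generator, sigma_vox: float = 4.0) -> np.ndarray:
    if amplitude_mm == 0.0:
        return np.zeros(grid.shape + (3,))
    noise = rng.standard_normal(grid.shape + (3,))
    for j in range(3):
        noise[..., j] = ndimage.gaussian_filter(noise[..., j], sigma_vox)
    mag = np.linalg.norm(noise, axis=-1).max()
    return noise * (amplitude_mm / max(mag, 1e-12))


def simulate_longitudinal_series(
    template: SubjectTemplate, cfg: PhantomConfig
) -> LongitudinalSeries:
    """Draw one longitudinal series from the generative model.

    Latent SVFs are ``(t_n - mean t) * slope + perturbation`` with the
    per-timepoint perturbations mean-subtracted, so the latents sum to zero
    identically; rigid jitters are drawn in the log domain and mean-subtracted
    likewise. Each timepoint image is the template pulled through the inverse
    latent map in a single interpolation, plus additive Gaussian noise.
    Labelmaps additionally traverse an independent smooth error warp,
    emulating cross-sectional segmentation noise.
    """
    cfg_n = cfg.n_timepoints
    if cfg_n < 2:
        raise ValueError("need at least 2 timepoints")
    rng = np.random.default_rng(cfg.seed)
    grid = template.grid
    times = np.asarray(cfg.times, dtype=float)

    slope = atrophy_slope_field(cfg, grid)
    max_slope_disp = np.linalg.norm(slope.values, axis=-1).max() * np.ptp(times)
    if max_slope_disp > 0.4 * np.min(grid.spacing) * min(grid.shape):
        raise ValueError("configured atrophy exceeds the diffeomorphic bound")

    perturb = np.stack([_smooth_random_field(grid, cfg.svf_perturb_mm, rng)
                        for _ in range(cfg_n)])
    perturb -= perturb.mean(axis=0)
    t_c = times - times.mean()
    true_svf = [VelocityField(grid, t_c[n] * slope.values + perturb[n]) for n in range(cfg_n)]

    rot_rad = np.deg2rad(cfg.rigid_rot_deg)
    logs = np.concatenate(
        [rng.uniform(-rot_rad, rot_rad, (cfg_n, 3)),
         rng.uniform(-cfg.rigid_trans_mm, cfg.rigid_trans_mm, (cfg_n, 3))], axis=1
    )
    logs -= logs.mean(axis=0)
    true_rigid = [RigidLog.from_vector(logs[n]) for n in range(cfg_n)]

    images, labelmaps, masks = [], [], []
    for n in range(cfg_n):
        inv_chain = [rigid_exp(true_rigid[n]).inverse(),
                     svf_exp(true_svf[n], time_scale=-1.0)]
        img = resample_image(template.intensity, grid, inv_chain, grid)
        img = img + rng.normal(0.0, cfg.image_noise_sd, grid.shape) if cfg.image_noise_sd else img
        seg_chain = inv_chain
        if cfg.seg_noise_mm:
            err = DisplacementField(grid, _smooth_random_field(grid, cfg.seg_noise_mm, rng))
            seg_chain = [err] + inv_chain
        lab = resample_image(template.segmentation.astype(float), grid, seg_chain,
                             grid, mode="nearest").astype(np.int16)
        msk = resample_image(template.mask, grid, inv_chain, grid)
        images.append(img)
        labelmaps.append(lab)
        masks.append(msk)

    return LongitudinalSeries(grid, tuple(times), images, labelmaps, masks,
                              true_rigid, true_svf, slope)


def pairwise_true_logs(true_latents: list, graph: ObservationGraph) -> list:
    """Noise-free log-domain compositions T_tgt - T_ref for every edge."""
    pos = {idx: i for i, idx in enumerate(graph.node_indices)}
    out = []
    for e in graph.edges:
        i, j = pos[e.ref_index], pos[e.tgt_index]
        if isinstance(true_latents[0], RigidLog):
            out.append(RigidLog.from_vector(true_latents[j].vector - true_latents[i].vector))
        else:
            out.append(VelocityField(true_latents[0].grid,
                                     true_latents[j].values - true_latents[i].values))
    return out


def corrupt_registrations(
    graph: ObservationGraph,
    true_latents: list,
    b: float,
    outlier_fraction: float = 0.0,
    seed: int = 0,
) -> ObservationGraph:
    """Attach noisy observations ``R_k = T_tgt - T_ref + Laplace(0, b)`` to a graph.

    ``true_latents`` is the list of latent RigidLogs or VelocityFields in
    node order. ``round(outlier_fraction * K)`` seeded-chosen edges are
    additionally shifted by a gross offset of 10x the typical observation
    magnitude, for robustness experiments. ``b = 0`` reproduces the exact
    compositions.
    """
    if b < 0:
        raise ValueError("Laplace scale must be >= 0")
    rng = np.random.default_rng(seed)
    rigid = isinstance(true_latents[0], RigidLog)
    pos = {idx: i for i, idx in enumerate(graph.node_indices)}

    clean = []
    for e in graph.edges:
        i, j = pos[e.ref_index], pos[e.tgt_index]
        if rigid:
            clean.append(true_latents[j].vector - true_latents[i].vector)
        else:
            clean.append(true_latents[j].values - true_latents[i].values)
    typical = max(float(np.max([np.max(np.abs(c)) for c in clean])), b, 1e-6)

    k = graph.n_edges
    n_out = int(round(outlier_fraction * k))
    outliers = rng.choice(k, size=n_out, replace=False) if n_out else np.array([], dtype=int)

    edges = []
    for idx, (e, c) in enumerate(zip(graph.edges, clean)):
        obs = c + rng.laplace(0.0, b, c.shape) if b > 0 else c.copy()
        if idx in outliers:
            obs = obs + 10.0 * typical * rng.choice([-1.0, 1.0], size=c.shape)
        if rigid:
            payload = RigidLog.from_vector(obs)
        else:
            payload = VelocityField(graph.edges[idx].log_params.grid
                                    if graph.edges[idx].log_params is not None
                                    else true_latents[0].grid, obs)
        edges.append(ObservationEdge(e.ref_index, e.tgt_index, payload))
    return ObservationGraph(list(graph.nodes), edges)


def write_phantom(series: LongitudinalSeries, template: SubjectTemplate,
                  out_dir: str | Path) -> Path:
    """Emit the phantom as a BIDS-like subject directory plus ground truth."""
    import json

    from .svf import save_scalar_volume, save_velocity_field
    from .lie_rigid import save_rigid_log

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    rows = ["session_id\tyears_from_baseline"]
    for n, t in enumerate(series.times):
        ses = out / f"ses-{n:02d}"
        ses.mkdir(exist_ok=True)
        save_scalar_volume(series.images[n].astype(np.float32), series.grid,
                           ses / f"ses-{n:02d}_T1w.nii.gz")
        save_scalar_volume(series.labelmaps[n], series.grid,
                           ses / f"ses-{n:02d}_dseg.nii.gz")
        save_rigid_log(series.true_rigid[n], out / "truth" / f"rigid_{n:02d}.log.txt")
        save_velocity_field(series.true_svf[n], out / "truth" / f"svf_{n:02d}.nii.gz")
        rows.append(f"ses-{n:02d}\t{t}")
    (out / "sessions.tsv").write_text("\n".join(rows) + "\n")
    template.save(out / "truth", prefix="template")
    (out / "manifest.json").write_text(json.dumps(
        {"n_timepoints": len(series.times), "times": list(series.times)}, indent=2))
    return out
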