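"""Time-consistent segmentation by intensity-weighted label fusion.

Each timepoint's segmentation is re-estimated from *all* timepoints: every
other timepoint's image and one-hot labelmap are pulled into the reference
timepoint's space through the concatenated latent transforms (one
interpolation, routed through the template), and fused with per-voxel
weights ``w(x) = exp(-(I_ref(x) - I_deformed(x))^2 / (2 sigma^2))`` — a
Gaussian intensity-likelihood kernel. The reference's own weight is 1
everywhere (its self-difference is zero), so it always contributes at least
as much as any other timepoint. Images are first normalised so the mean
white-matter intensity is 110, giving the kernel width a fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lie_rigid import RigidLog, RigidMatrix, rigid_exp
from .svf import ImageGrid, VelocityField, resample_image, svf_exp

__all__ = ["FusionConfig", "normalize_intensities", "fuse_labels", "label_volumes"]


@dataclass(frozen=True)
class FusionConfig:
    """kernel_sigma: Gaussian kernel width on the WM-110 intensity scale;
    wm_target: mean white-matter intensity after normalisation."""

    kernel_sigma: float = 3.0
    wm_target: float = 110.0

    def __post_init__(self) -> None:
        if self.kernel_sigma <= 0 or self.wm_target <= 0:
            raise ValueError("fusion config values must be positive")


def normalize_intensities(
    img: np.ndarray,
    labels: np.ndarray,
    wm_label_ids: Sequence[int],
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Scale an image so its mean white-matter intensity equals ``wm_target``."""
    cfg = cfg or FusionConfig()
    wm = np.isin(labels, np.asarray(wm_label_ids))
    if not wm.any():
        raise ValueError("white-matter mask is empty")
    mean_wm = float(np.asarray(img, dtype=float)[wm].mean())
    if mean_wm <= 0:
        raise ValueError("non-positive mean white-matter intensity")
    return np.asarray(img, dtype=float) * (cfg.wm_target / mean_wm)


def _as_matrix(latent) -> RigidMatrix:
    return rigid_exp(latent) if isinstance(latent, RigidLog) else latent


def cross_timepoint_chain(
    rigid_latents, svf_latents, ref: int, other: int
) -> list:
    """Point-map chain from timepoint-``ref`` space to timepoint-``other`` space.

    Routed through the template: rigid_ref^-1, then exp(-T_ref) into template
    space, then exp(T_other) and rigid_other back out. Displacement fields
    are evaluated on the subject grid, where the intermediate points live.
    """
    chain: list = [_as_matrix(rigid_latents[ref]).inverse()]
    if svf_latents is not None:
        chain.append(svf_exp(svf_latents[ref], time_scale=-1.0))
        chain.append(svf_exp(svf_latents[other]))
    chain.append(_as_matrix(rigid_latents[other]))
    return chain


def fuse_labels(
    reference_index: int,
    images: list[np.ndarray],
    labelmaps: list[np.ndarray],
    grids: list[ImageGrid],
    rigid_latents: list,
    svf_latents: list[VelocityField] | None,
    cfg: FusionConfig | None = None,
) -> np.ndarray:
    """Fused labelmap for one timepoint, in that timepoint's own space.

    ``images`` must already be intensity-normalised. With a single timepoint
    the input segmentation is returned unchanged. Output labels are always a
    subset of the union of input labels; argmax ties break to the lowest id.
    """
    cfg = cfg or FusionConfig()
    n = len(images)
    if not (len(labelmaps) == len(grids) == n):
        raise ValueError("images, labelmaps and grids must align")
    if n == 1:
        return np.asarray(labelmaps[0]).copy()

    ref_img = np.asarray(images[reference_index], dtype=float)
    ref_grid = grids[reference_index]
    labels = np.unique(np.concatenate([np.unique(lm) for lm in labelmaps]))

    weighted = np.zeros(ref_grid.shape + (labels.size,))
    weight_sum = np.zeros(ref_grid.shape)
    for other in range(n):
        onehot = (np.asarray(labelmaps[other])[..., None] == labels).astype(float)
        if other == reference_index:
            img_o, onehot_o = ref_img, onehot
        else:
            chain = cross_timepoint_chain(rigid_latents, svf_latents, reference_index, other)
            img_o = resample_image(images[other], grids[other], chain, ref_grid)
            onehot_o = resample_image(onehot, grids[other], chain, ref_grid)
        w = np.exp(-((ref_img - img_o) ** 2) / (2.0 * cfg.kernel_sigma**2))
        weighted += w[..., None] * onehot_o
        weight_sum += w
    fused = weighted / weight_sum[..., None]
    return labels[np.argmax(fused, axis=-1)]


def label_volumes(labelmap: np.ndarray, grid: ImageGrid,
                  label_ids: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-label volume table (label, voxels, mm3)."""
    voxel_mm3 = float(abs(np.linalg.det(grid.affine[:3, :3])))
    ids = np.unique(labelmap) if label_ids is None else np.asarray(label_ids)
    ids = ids[ids != 0]
    counts = [(int(i), int(np.sum(labelmap == i))) for i in ids]
    return pd.DataFrame(
        [(i, c, c * voxel_mm3) for i, c in counts], columns=["label", "voxels", "mm3"]
    )
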