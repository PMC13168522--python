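"""Unbiased subject space and subject-specific template.

After the rigid stage, a 1 mm isotropic RAS grid is defined as the smallest
cuboid covering every rigidly-mapped timepoint plus a 5-voxel margin on each
face, centred at the world origin. After the non-linear stage, every
timepoint is pulled onto that grid through its single concatenated map (one
interpolation from the original image) and fused voxelwise: median intensity
(the MAP fusion under Laplacian image noise), mean mask (tissue
probability), and argmax of the mean one-hot encodings (segmentation).
Because every timepoint enters symmetrically, the template is invariant to
the ordering of the timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lie_rigid import RigidLog, RigidMatrix, rigid_exp
from .svf import ImageGrid, VelocityField, resample_image, save_scalar_volume, svf_exp

__all__ = ["SubjectTemplate", "define_subject_space", "build_template"]

SPACE_MARGIN_VOXELS = 5


@dataclass
class SubjectTemplate:
    grid: ImageGrid
    intensity: np.ndarray
    mask: np.ndarray
    segmentation: np.ndarray | None = None

    def binary_mask(self, threshold: float = 0.5) -> np.ndarray:
        return self.mask >= threshold

    def save(self, directory: str | Path, prefix: str = "template") -> dict[str, str]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        pairs = [("T1w", self.intensity.astype(np.float32)), ("mask", self.mask.astype(np.float32))]
        if self.segmentation is not None:
            pairs.append(("dseg", self.segmentation.astype(np.int16)))
        for suffix, data in pairs:
            path = directory / f"{prefix}_{suffix}.nii.gz"
            save_scalar_volume(data, self.grid, path)
            out[suffix] = str(path)
        return out


def _as_rigid_matrix(latent) -> RigidMatrix:
    return rigid_exp(latent) if isinstance(latent, RigidLog) else latent


def define_subject_space(
    rigid_latents: list[RigidLog | RigidMatrix],
    grids: list[ImageGrid],
    spacing: float = 1.0,
    margin: int = SPACE_MARGIN_VOXELS,
) -> ImageGrid:
    """Isotropic RAS grid covering all rigidly-mapped timepoints, centred at origin.

    Each timepoint's eight voxel-corner world coordinates are mapped through
    the *inverse* of its latent rigid transform (latents map subject-space
    points to timepoint-space points); the bounding cuboid of all mapped
    corners is padded by ``margin`` voxels per face and the affine translates
    the cuboid centre to world (0, 0, 0).
    """
    if not grids:
        raise ValueError("no input grids")
    if len(rigid_latents) != len(grids):
        raise ValueError("one rigid latent per timepoint grid is required")
    corners_sub = []
    for latent, grid in zip(rigid_latents, grids):
        inv = _as_rigid_matrix(latent).inverse()
        corner_vox = np.array(
            [[i, j, k] for i in (0, grid.shape[0] - 1)
             for j in (0, grid.shape[1] - 1) for k in (0, grid.shape[2] - 1)],
            dtype=float,
        )
        corners_sub.append(inv.apply(grid.voxel_to_world(corner_vox)))
    pts = np.vstack(corners_sub)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent_vox = np.round((hi - lo) / spacing).astype(int) + 1
    shape = tuple(int(s) for s in extent_vox + 2 * margin)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0
    return ImageGrid(shape, affine)


def timepoint_pullback_chain(rigid_latent, svf_latent: VelocityField | None):
    """Transform chain mapping subject-space points to a timepoint's space.

    Applied in order during resampling: first the small non-linear
    deformation exp(T_n) on the subject grid, then the rigid map. Passing the
    original timepoint image through this chain pulls it onto the subject
    grid with a single interpolation.
    """
    chain = []
    if svf_latent is not None:
        chain.append(svf_exp(svf_latent))
    chain.append(_as_rigid_matrix(rigid_latent))
    return chain


def build_template(
    images: list[np.ndarray],
    grids: list[ImageGrid],
    rigid_latents: list[RigidLog | RigidMatrix],
    svf_latents: list[VelocityField] | None,
    subject_grid: ImageGrid,
    masks: list[np.ndarray] | None = None,
    labelmaps: list[np.ndarray] | None = None,
) -> SubjectTemplate:
    """Fuse all timepoints, resampled once each, into the subject template."""
    n = len(images)
    if svf_latents is None:
        svf_latents = [None] * n
    if not (len(grids) == len(rigid_latents) == len(svf_latents) == n):
        raise ValueError("images, grids and latents must align")

    chains = [timepoint_pullback_chain(r, s) for r, s in zip(rigid_latents, svf_latents)]
    stack = np.stack(
        [resample_image(img, g, ch, subject_grid) for img, g, ch in zip(images, grids, chains)]
    )
    intensity = np.median(stack, axis=0)

    if masks is not None:
        mstack = np.stack(
            [resample_image(m.astype(float), g, ch, subject_grid)
             for m, g, ch in zip(masks, grids, chains)]
        )
        mask = np.clip(mstack.mean(axis=0), 0.0, 1.0)
    else:
        mask = np.ones(subject_grid.shape)

    segmentation = None
    if labelmaps is not None:
        labels = np.unique(np.concatenate([np.unique(lm) for lm in labelmaps]))
        onehot_mean = np.zeros(subject_grid.shape + (labels.size,))
        for lm, g, ch in zip(labelmaps, grids, chains):
            onehot = (lm[..., None] == labels).astype(float)
            onehot_mean += resample_image(onehot, g, ch, subject_grid)
        onehot_mean /= n
        # np.argmax breaks ties at the first (lowest) label id
        segmentation = labels[np.argmax(onehot_mean, axis=-1)]

    return SubjectTemplate(subject_grid, intensity, mask, segmentation)
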