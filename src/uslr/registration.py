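"""Pairwise registration backends producing the observed log-transforms.

The graph inference is agnostic to how the pairwise registrations are
produced; three interchangeable sources are provided:

* ``centroid_rigid_register`` — orthogonal-Procrustes alignment of label
  centroids, a fast rigid aligner driven by any cross-sectional segmentation;
* ``ssd_svf_register`` — a coarse-to-fine demons-style optimiser of the sum
  of squared intensity differences over a stationary velocity field;
* ``load_transform`` — precomputed transforms from disk (4x4 affine text
  files or 4-D NIfTI velocity fields), so outputs of external learned
  registration tools plug straight in.

Direction convention: the stored transform for edge (ref, tgt) is the point
map from reference space to target space, i.e. resampling the *target* image
through it pulls the target onto the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .lie_rigid import RigidMatrix
from .svf import (
    DisplacementField,
    GridMismatchError,
    ImageGrid,
    VelocityField,
    load_velocity_field,
    resample_image,
    svf_exp,
)

__all__ = [
    "RegistrationConfig",
    "centroid_rigid_register",
    "ssd_svf_register",
    "load_transform",
]


class DegenerateGeometryError(ValueError):
    """Too few shared labels, or collinear centroids: rotation unrecoverable."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs of the SSD velocity-field optimiser.

    pyramid_levels: number of coarse-to-fine resolution levels (factor 2).
    smoothing_sigma: Gaussian sigma (voxels) of the fluid-like smoothing of
        each update; a quarter of it is re-applied to the accumulated field
        each iteration (diffusion-like regularisation).
    step_size: scale of the demons force update.
    max_iters: iterations per pyramid level.
    """

    pyramid_levels: int = 2
    smoothing_sigma: float = 2.0
    step_size: float = 1.0
    max_iters: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pyramid_levels, self.max_iters) < 1 or self.smoothing_sigma <= 0 \
                or self.step_size <= 0:
            raise ValueError("registration config values must be positive")


def _label_centroids(labels: np.ndarray, grid: ImageGrid, ids: np.ndarray) -> np.ndarray:
    coms = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    return grid.voxel_to_world(np.asarray(coms))


def centroid_rigid_register(
    labels_ref: np.ndarray,
    grid_ref: ImageGrid,
    labels_tgt: np.ndarray,
    grid_tgt: ImageGrid,
) -> RigidMatrix:
    """Rigid ref->tgt map by orthogonal Procrustes on shared label centroids.

    World-space centroids of every label present in both maps are matched;
    the optimal rotation comes from the SVD of the cross-covariance with the
    usual determinant correction, so a reflection is never returned.
    """
    shared = np.intersect1d(np.unique(labels_ref), np.unique(labels_tgt))
    shared = shared[shared != 0]
    if shared.size < 3:
        raise DegenerateGeometryError(f"only {shared.size} shared non-background labels")
    p_ref = _label_centroids(labels_ref, grid_ref, shared)
    p_tgt = _label_centroids(labels_tgt, grid_tgt, shared)

    mu_ref, mu_tgt = p_ref.mean(axis=0), p_tgt.mean(axis=0)
    a, b = p_ref - mu_ref, p_tgt - mu_tgt
    # collinear centroids leave a rotation about their common axis undetermined
    if np.linalg.matrix_rank(a, tol=1e-6) < 2:
        raise DegenerateGeometryError("shared label centroids are collinear")
    H = a.T @ b
    Usvd, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ Usvd.T))])
    U = Vt.T @ D @ Usvd.T
    t = mu_tgt - U @ mu_ref
    return RigidMatrix(U, t)


def _smooth_field(values: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for j in range(3):
        out[..., j] = ndimage.gaussian_filter(values[..., j], sigma_vox, mode="nearest")
    return out


def _downsample(img: np.ndarray, grid: ImageGrid, factor: int) -> tuple[np.ndarray, ImageGrid]:
    if factor == 1:
        return img, grid
    sm = ndimage.gaussian_filter(img, factor / 2.0, mode="nearest")
    small = sm[::factor, ::factor, ::factor]
    affine = grid.affine.copy()
    affine[:3, :3] *= factor
    return small, ImageGrid(small.shape, affine)


def ssd_svf_register(
    img_ref: np.ndarray,
    img_tgt: np.ndarray,
    grid: ImageGrid,
    cfg: RegistrationConfig | None = None,
) -> VelocityField:
    """Stationary velocity field v aligning target onto reference by SSD descent.

    Gradient descent on ``|| img_tgt o exp(v) - img_ref ||^2`` with the
    classical stabilised demons force (symmetric gradient), Gaussian
    smoothing of both the update (fluid) and the accumulated field
    (diffusion), coarse-to-fine over a factor-2 pyramid. The returned v is
    the ref->tgt log-transform. Its exponential is checked for positive
    Jacobian at convergence; a non-diffeomorphic result raises a
    RuntimeWarning and the field is still returned for inspection.
    """
    cfg = cfg or RegistrationConfig()
    img_ref = np.asarray(img_ref, dtype=float)
    img_tgt = np.asarray(img_tgt, dtype=float)
    if img_ref.shape != grid.shape or img_tgt.shape != grid.shape:
        raise GridMismatchError("images must share the subject grid")

    v: VelocityField | None = None
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        factor = 2**level
        ref_l, grid_l = _downsample(img_ref, grid, factor)
        tgt_l, _ = _downsample(img_tgt, grid, factor)
        if v is None:
            v_vals = np.zeros(grid_l.shape + (3,))
        else:  # upsample previous level's field to this level
            v_vals = resample_image(v.values, v.grid, [], grid_l)
        v = VelocityField(grid_l, v_vals)

        spacing = grid_l.spacing
        fluid_vox = cfg.smoothing_sigma
        diffusion_vox = 0.25 * cfg.smoothing_sigma
        step_cap = 0.5 * float(spacing.min())  # trust region: half a voxel per update
        # intensity-scale normalisation for the demons denominator
        scale2 = np.mean((tgt_l - tgt_l.mean()) ** 2) + 1e-12
        grad_ref = np.stack(np.gradient(ref_l, *spacing), axis=-1)
        for _ in range(cfg.max_iters):
            disp = svf_exp(v, n_squarings=4)
            warped = resample_image(tgt_l, grid_l, [disp], grid_l)
            residual = warped - ref_l
            # symmetric (ESM-like) gradient improves inverse consistency
            grad = 0.5 * (np.stack(np.gradient(warped, *spacing), axis=-1) + grad_ref)
            gnorm2 = np.sum(grad**2, axis=-1)
            denom = gnorm2 + residual**2 / scale2
            force = -cfg.step_size * residual[..., None] * grad / (denom[..., None] + 1e-9)
            fmag = np.linalg.norm(force, axis=-1, keepdims=True)
            force *= np.minimum(1.0, step_cap / np.maximum(fmag, 1e-12))
            force = _smooth_field(force, fluid_vox)
            v_vals = _smooth_field(v.values + force, diffusion_vox)
            v = VelocityField(grid_l, v_vals)

    if v.grid.shape != grid.shape:  # pragma: no cover - pyramid always ends at full res
        v = VelocityField(grid, resample_image(v.values, v.grid, [], grid))
    from .svf import jacobian_determinant

    jac = jacobian_determinant(svf_exp(v))
    if np.min(jac) <= 0:
        import warnings

        warnings.warn(
            f"registration converged to a non-diffeomorphic field (min |J| = {jac.min():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return VelocityField(grid, v.values)


def load_transform(path: str | Path, kind: str,
                   expect_grid: ImageGrid | None = None):
    """Load a precomputed transform: ``kind`` is ``"rigid"`` or ``"svf"``."""
    if kind == "rigid":
        from .lie_rigid import load_rigid_matrix

        return load_rigid_matrix(path)
    if kind == "svf":
        return load_velocity_field(path, expect_grid=expect_grid, kind=VelocityField)
    raise ValueError(f"unknown transform kind {kind!r}")
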