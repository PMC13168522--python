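"""Stationary velocity fields and resampling.

A stationary velocity field (SVF) ``v`` is a time-constant 3-vector field on
the subject grid, stored in world mm. Its group exponential — the flow of the
ODE ``dx/dt = v(x)`` at ``t = 1`` — is a diffeomorphism, computed here by
scaling-and-squaring: halve the field ``n`` times, then self-compose the small
displacement ``n`` times.

Conventions
-----------
* Fields carry *world-mm* displacement values sampled at the voxels of an
  :class:`ImageGrid`; look-ups convert through the grid affine.
* All transforms are point maps applied as pull-backs: resampling an image
  through ``[phi1, phi2]`` evaluates ``img(phi2(phi1(x)))`` at each target
  grid point ``x``, with exactly one interpolation of the source image.
* Out-of-grid field look-ups clamp to the nearest edge; out-of-grid image
  samples fill with 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .lie_rigid import RigidMatrix

__all__ = [
    "ImageGrid",
    "VelocityField",
    "DisplacementField",
    "svf_exp",
    "compose_displacements",
    "jacobian_determinant",
    "resample_image",
    "load_velocity_field",
    "save_velocity_field",
    "load_scalar_volume",
    "save_scalar_volume",
]


class GridMismatchError(ValueError):
    """Two fields or volumes that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D sampling lattice: voxel shape plus a 4x4 voxel->world affine (mm, RAS)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("grid shape must be 3 positive integers")
        if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
            raise ValueError("grid affine must be a finite 4x4 matrix")
        if np.linalg.det(affine[:3, :3]) <= 0:
            raise ValueError("grid affine must be orientation-preserving (RAS, det > 0)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm: column norms of the affine's 3x3 block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def isotropic(cls, shape: Sequence[int], spacing: float = 1.0, centred: bool = True) -> "ImageGrid":
        """A diagonal RAS grid, optionally centred at world (0, 0, 0)."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([spacing, spacing, spacing, 1.0])
        if centred:
            affine[:3, 3] = -spacing * (np.array(shape) - 1) / 2.0
        return cls(shape, affine)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """Dense (X, Y, Z, 3) array of world coordinates of every voxel centre."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s, dtype=float) for s in self.shape), indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_world(idx)

    def matches(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass(frozen=True)
class _Field:
    grid: ImageGrid
    values: np.ndarray  # (X, Y, Z, 3) world mm

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape + (3,):
            raise GridMismatchError(
                f"field shape {values.shape} does not match grid {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("field values must be finite")
        object.__setattr__(self, "values", values)

    def sample(self, world_points: np.ndarray) -> np.ndarray:
        """Trilinear field value at arbitrary world points; clamp-to-edge outside."""
        pts = self.grid.world_to_voxel(world_points)
        flat = pts.reshape(-1, 3).T
        out = np.empty((flat.shape[1], 3))
        for j in range(3):
            out[:, j] = ndimage.map_coordinates(
                self.values[..., j], flat, order=1, mode="nearest"
            )
        return out.reshape(world_points.shape)


class VelocityField(_Field):
    """Stationary velocity field, world mm per unit time."""


class DisplacementField(_Field):
    """Dense displacement ``u``: the point map is ``x -> x + u(x)`` (world mm)."""

    def apply(self, world_points: np.ndarray) -> np.ndarray:
        return np.asarray(world_points, dtype=float) + self.sample(world_points)


def zero_velocity(grid: ImageGrid) -> VelocityField:
    return VelocityField(grid, np.zeros(grid.shape + (3,)))


def compose_displacements(a: DisplacementField, b: DisplacementField) -> DisplacementField:
    """Exact composition ``(a o b)(x) = b(x) + a(x + b(x))`` on the shared grid."""
    if not a.grid.matches(b.grid):
        raise GridMismatchError("displacement fields live on different grids")
    world = b.grid.world_coordinates()
    return DisplacementField(b.grid, b.values + a.sample(world + b.values))


def svf_exp(
    v: VelocityField,
    time_scale: float = 1.0,
    n_squarings: int = 8,
) -> DisplacementField:
    """Group exponential ``exp(time_scale * v)`` by scaling and squaring.

    The field is scaled by ``time_scale / 2**n`` and the resulting small
    displacement self-composed ``n`` times. ``n`` starts at ``n_squarings``
    and is increased until the maximum scaled step is below half a voxel,
    which keeps each elementary step well inside the trilinear regime.
    Deterministic: identical inputs give bitwise-identical outputs.
    """
    if n_squarings < 0:
        raise ValueError("n_squarings must be >= 0")
    max_norm = float(np.max(np.linalg.norm(v.values, axis=-1))) * abs(float(time_scale))
    min_spacing = float(np.min(v.grid.spacing))
    n = int(n_squarings)
    while max_norm / 2**n > 0.5 * min_spacing:
        n += 1
    d = DisplacementField(v.grid, v.values * (float(time_scale) / 2**n))
    for _ in range(n):
        d = compose_displacements(d, d)
    return d


def jacobian_determinant(d: DisplacementField) -> np.ndarray:
    """Voxelwise ``det(I + grad u)`` of a displacement, in world coordinates.

    Central finite differences in voxel index space are mapped to world axes
    through the inverse of the grid affine's 3x3 block; the one-voxel border,
    where only one-sided differences exist, is replicated from the interior.
    """
    inv_lin = np.linalg.inv(d.grid.affine[:3, :3])
    grads = np.empty(d.grid.shape + (3, 3))
    for i in range(3):
        g = np.gradient(d.values[..., i], axis=(0, 1, 2))
        dvox = np.stack(g, axis=-1)  # du_i / d voxel_k
        grads[..., i, :] = dvox @ inv_lin  # chain rule -> du_i / d world_j
    det = np.linalg.det(np.eye(3) + grads)
    # replicate interior values onto the border
    if all(s > 2 for s in d.grid.shape):
        interior = det[1:-1, 1:-1, 1:-1]
        det = np.pad(interior, 1, mode="edge")
    return det


def _apply_transform_points(transform, pts: np.ndarray) -> np.ndarray:
    if isinstance(transform, RigidMatrix):
        return transform.apply(pts)
    if isinstance(transform, DisplacementField):
        return transform.apply(pts)
    if isinstance(transform, np.ndarray) and transform.shape == (4, 4):
        return RigidMatrix.from_matrix(transform).apply(pts)
    raise TypeError(f"unsupported transform type {type(transform)!r}")


def resample_image(
    img: np.ndarray,
    img_grid: ImageGrid,
    transforms: Iterable,
    target: ImageGrid,
    mode: str = "trilinear",
) -> np.ndarray:
    """Pull an image onto ``target`` through a chain of transforms, interpolating once.

    Each target grid point is pushed through the transforms *in list order*
    (ending in source-image world space) and the source is sampled exactly
    once there. Scalar ``(X,Y,Z)`` and vector/one-hot ``(X,Y,Z,C)`` volumes
    are supported; ``mode`` is ``"trilinear"`` or ``"nearest"``. Points that
    land outside the source volume fill with 0.
    """
    img = np.asarray(img)
    spatial = img.shape[:3]
    if spatial != img_grid.shape:
        raise GridMismatchError(f"image shape {spatial} does not match its grid {img_grid.shape}")
    order = {"trilinear": 1, "nearest": 0}[mode]

    pts = target.world_coordinates().reshape(-1, 3)
    for tr in transforms:
        pts = _apply_transform_points(tr, pts)
    vox = img_grid.world_to_voxel(pts).T  # (3, M)

    if img.ndim == 3:
        out = ndimage.map_coordinates(img.astype(float), vox, order=order, mode="constant", cval=0.0)
        return out.reshape(target.shape)
    out = np.empty(target.shape + img.shape[3:])
    for c in np.ndindex(img.shape[3:]):
        channel = img[(slice(None),) * 3 + c].astype(float)
        out[(slice(None),) * 3 + c] = ndimage.map_coordinates(
            channel, vox, order=order, mode="constant", cval=0.0
        ).reshape(target.shape)
    return out


# -- NIfTI interchange -------------------------------------------------------


def save_velocity_field(field: _Field, path: str | Path) -> None:
    """Write a vector field as 4-D NIfTI (x, y, z, 3) with the grid affine."""
    nib.save(nib.Nifti1Image(field.values.astype(np.float64), field.grid.affine), str(path))


def load_velocity_field(path: str | Path, expect_grid: ImageGrid | None = None,
                        kind: type = VelocityField) -> _Field:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"{path}: expected a 4-D (x,y,z,3) vector field, got {data.shape}")
    grid = ImageGrid(data.shape[:3], img.affine)
    if expect_grid is not None and not grid.matches(expect_grid):
        raise GridMismatchError(f"{path}: field grid does not match the expected grid")
    return kind(grid, data)


def save_scalar_volume(data: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), grid.affine), str(path))


def load_scalar_volume(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, ImageGrid(data.shape[:3], img.affine)
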