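"""Single stationary longitudinal trajectory from the latent velocity fields.

A voxelwise ordinary-least-squares line is fitted through the N latent SVFs
against acquisition time (years from baseline), independently per voxel and
coordinate: ``T_n(x) = c(x) + That(x) * t_n``. The slope field ``That`` is a
per-year rate of deformation; its exponential ``exp(t * That)`` evaluates
the trajectory at any time — between observations (interpolation) or outside
the follow-up window (prediction) — and its Jacobian determinant over a
period gives tensor-based-morphometry maps of local volume change
(> 1 expansion, < 1 contraction).

A linear model in the log domain is *not* linear in the deformations: the
exponential map keeps every evaluated transform diffeomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .svf import DisplacementField, VelocityField, jacobian_determinant, resample_image, svf_exp
from .template import SubjectTemplate

__all__ = [
    "TrajectoryFit",
    "fit_stationary_trajectory",
    "evaluate_trajectory",
    "jacobian_period",
    "predict_image",
]


@dataclass(frozen=True)
class TrajectoryFit:
    intercept: VelocityField
    slope: VelocityField  # per-year rate
    times_used: tuple[float, ...]


def fit_stationary_trajectory(
    svf_latents: list[VelocityField], times: list[float]
) -> TrajectoryFit:
    """Closed-form voxelwise OLS of the latent SVFs against time.

    With two timepoints the line interpolates both fields exactly; with one,
    or with all times equal, the slope is undefined and an error is raised.
    """
    if len(svf_latents) != len(times):
        raise ValueError("one acquisition time per latent field is required")
    if len(svf_latents) < 2:
        raise ValueError("at least 2 timepoints are needed to fit a trajectory")
    t = np.asarray(times, dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("all acquisition times are equal: slope is rank-deficient")
    grid = svf_latents[0].grid
    for f in svf_latents:
        if not f.grid.matches(grid):
            raise ValueError("latent fields live on different grids")

    stack = np.stack([f.values for f in svf_latents])  # (N, X, Y, Z, 3)
    t_c = t - t.mean()
    mean_field = stack.mean(axis=0)
    slope = np.tensordot(t_c, stack - mean_field, axes=(0, 0)) / np.sum(t_c**2)
    intercept = mean_field - t.mean() * slope
    return TrajectoryFit(VelocityField(grid, intercept), VelocityField(grid, slope), tuple(t))


def evaluate_trajectory(
    fit: TrajectoryFit, t: float, include_intercept: bool = False
) -> DisplacementField:
    """Displacement ``exp(t * That)`` (optionally ``exp(c + t * That)``) at time t."""
    v = fit.slope.values * float(t)
    if include_intercept:
        v = v + fit.intercept.values
    return svf_exp(VelocityField(fit.slope.grid, v))


def jacobian_period(fit: TrajectoryFit, delta_t: float = 1.0) -> np.ndarray:
    """Jacobian-determinant map of the trajectory integrated over ``delta_t`` years."""
    return jacobian_determinant(evaluate_trajectory(fit, delta_t))


def predict_image(
    template: SubjectTemplate,
    fit: TrajectoryFit,
    t: float,
    include_intercept: bool = True,
) -> np.ndarray:
    """Template intensity deformed to time ``t`` — one interpolation, no blurring.

    The predicted scan at time t is the template pulled through
    ``exp(-(c + t*That))`` (the timepoint-to-template direction is the
    negated log). The intercept ``c`` shifts the time origin onto the
    template; dropping it (``include_intercept=False``) evaluates the pure
    rate model ``exp(t * That)`` instead.
    """
    v = fit.slope.values * float(t)
    if include_intercept:
        v = v + fit.intercept.values
    disp = svf_exp(VelocityField(fit.slope.grid, -v))
    return resample_image(template.intensity, template.grid, [disp], template.grid)
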