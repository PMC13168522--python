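"""Longitudinal evaluation statistics.

Reliability and sensitivity measures for volume series and deformation maps:

* symmetrised percent change, SPC = 100 * 2 (V2 - V1) / (V1 + V2), and its
  absolute value ASPC — test-retest reliability of a volumetric measure;
* trajectory smoothness — the l2-norm of the finite differences of a volume
  series over time (lower is smoother);
* the minimum per-group sample size of a longitudinal study,
  m = 2 (z_{1-alpha} + z_P)^2 sigma^2 (1 - rho) / (N s_x^2 d^2),
  and the ratio of sample sizes needed by two processing methods,
  R = 100 * sigma1^2 (1 - rho1) / (sigma2^2 (1 - rho2));
* a voxelwise two-sample t-test on Jacobian maps with Benjamini-Hochberg
  false-discovery-rate control, for tensor-based morphometry group studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "VolumeSeries",
    "PowerConfig",
    "spc",
    "aspc",
    "trajectory_smoothness",
    "sample_size",
    "sample_size_ratio",
    "benjamini_hochberg",
    "voxelwise_group_test",
]


@dataclass(frozen=True)
class VolumeSeries:
    structure: int
    volumes: tuple[float, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.times):
            raise ValueError("volumes and times must align")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be positive")


def spc(v1: float, v2: float) -> float:
    """Symmetrised percent change between two volume measurements."""
    if v1 + v2 <= 0:
        raise ValueError("V1 + V2 must be positive")
    return 100.0 * 2.0 * (v2 - v1) / (v1 + v2)


def aspc(v1: float, v2: float) -> float:
    """Absolute symmetrised percent change."""
    return abs(spc(v1, v2))


def trajectory_smoothness(series: VolumeSeries) -> float:
    """l2-norm of consecutive finite differences of a volume trajectory.

    Zero for a constant series; a straight line is minimal among all series
    sharing its endpoints and times.
    """
    v = np.asarray(series.volumes, dtype=float)
    t = np.asarray(series.times, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 timepoints")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.sqrt(np.sum((np.diff(v) / dt) ** 2)))


@dataclass(frozen=True)
class PowerConfig:
    """Design of a two-group longitudinal study.

    alpha: type-I error rate (one-sided, as in the standard longitudinal
    sample-size formula); power: target power P; effect: target effect size d
    (slope difference, units of the outcome per unit time); n_timepoints:
    scans per subject N; within_subject_time_variance: s_x^2, variance of the
    acquisition times; sigma: residual standard deviation of the outcome;
    rho: correlation of repeated measures.
    """

    alpha: float = 0.05
    power: float = 0.8
    effect: float = 1.0
    n_timepoints: int = 2
    within_subject_time_variance: float = 1.0
    sigma: float = 1.0
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.within_subject_time_variance <= 0 or self.sigma <= 0:
            raise ValueError("variances must be positive")
        if self.rho >= 1:
            raise ValueError("rho must be < 1")


def sample_size(cfg: PowerConfig) -> float:
    """Minimum subjects per group to detect a slope difference ``d``.

    ``m = 2 (z_{1-alpha} + z_P)^2 sigma^2 (1 - rho) / (N s_x^2 d^2)`` with
    Gaussian quantiles ``z_q``. Monotone: decreasing in d, N and s_x^2,
    increasing in sigma^2.
    """
    z = stats.norm.ppf
    num = 2.0 * (z(1.0 - cfg.alpha) + z(cfg.power)) ** 2 * cfg.sigma**2 * (1.0 - cfg.rho)
    den = cfg.n_timepoints * cfg.within_subject_time_variance * cfg.effect**2
    return num / den


def sample_size_ratio(sigma1: float, rho1: float, sigma2: float, rho2: float) -> float:
    """Percent of subjects method 1 needs relative to method 2 (same design)."""
    if rho1 >= 1 or rho2 >= 1:
        raise ValueError("correlations must be < 1")
    return 100.0 * (sigma1**2 * (1.0 - rho1)) / (sigma2**2 * (1.0 - rho2))


def benjamini_hochberg(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Step-up BH rule: boolean rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float).ravel()
    m = p.size
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject.reshape(np.shape(p_values))


def voxelwise_group_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    q: float = 0.05,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance t-test per voxel with BH-FDR thresholding.

    ``maps_a`` and ``maps_b`` are (subjects, X, Y, Z) stacks of co-registered
    Jacobian maps. Returns ``(t_thresholded, reject_mask)``: t-values zeroed
    where not significant after correction across in-mask voxels; voxels with
    degenerate (zero pooled) variance are masked out. Two-sided.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    na, nb = maps_a.shape[0], maps_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    shape = maps_a.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    mean_a, mean_b = maps_a.mean(axis=0), maps_b.mean(axis=0)
    var_a = maps_a.var(axis=0, ddof=1)
    var_b = maps_b.var(axis=0, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    valid = mask & (se > 0)

    tmap = np.zeros(shape)
    tmap[valid] = (mean_a[valid] - mean_b[valid]) / se[valid]
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(tmap[valid]), df)

    reject_flat = benjamini_hochberg(p, q)
    reject = np.zeros(shape, dtype=bool)
    reject[valid] = reject_flat
    out = np.where(reject, tmap, 0.0)
    return out, reject
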