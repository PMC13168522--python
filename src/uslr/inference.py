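"""MAP estimation of the latent transforms by least-absolute-deviations LP.

Model: observed log-registrations are Laplace-distributed around the latent
differences, ``R_k ~ Laplace((W T)_k, b_T)``, and the zero-drift prior pins
the sum of the latents, ``sum_n T_n ~ Laplace(0, b_Z)``. The MAP estimate at
each spatial location and coordinate therefore minimises

    (b_T / b_Z) * | sum_n T_n |  +  sum_k | R_k - (W T)_k |,

a least-absolute-deviations problem solved as a linear program (HiGHS). The
cost separates over locations and coordinates, so each is an independent
small LP: one per se(3) coordinate for the rigid stage, one per control
point and coordinate for the velocity-field stage. The L1 norm makes the
estimate robust to gross registration failures, and the drift term resolves
the one-dimensional gauge freedom of a connected graph (rank(W) = N-1),
centring the latent template among the timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .graph import ObservationGraph
from .lie_rigid import RigidLog
from .svf import ImageGrid, VelocityField

__all__ = [
    "InferenceConfig",
    "solve_l1_node",
    "solve_rigid_graph",
    "solve_svf_graph",
]


class DisconnectedGraphError(ValueError):
    """The observation graph does not connect all timepoints: latents are ambiguous."""


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class InferenceConfig:
    """Hyper-parameters of the solver.

    scale_ratio
        b_T / b_Z, the weight of the zero-drift prior relative to the data
        term. 1.0 trades off smoothness and accuracy; any positive value
        keeps the solution unambiguous.
    control_spacing
        Stride (voxels) of the control-point lattice for the velocity-field
        stage; 8 puts control points at 1/8 of the image resolution.
    lp_tolerance
        Primal/dual feasibility tolerance handed to the LP solver.
    """

    scale_ratio: float = 1.0
    control_spacing: int = 8
    lp_tolerance: float = 1e-7

    def __post_init__(self) -> None:
        if self.scale_ratio <= 0:
            raise ValueError("scale_ratio must be > 0")
        if self.control_spacing < 1:
            raise ValueError("control_spacing must be >= 1")


def solve_l1_node(r: np.ndarray, W: np.ndarray, scale_ratio: float = 1.0,
                  lp_tolerance: float = 1e-7) -> np.ndarray:
    """Minimise ``scale_ratio*|sum T| + sum_k |r_k - (W T)_k|`` over T (length N).

    Standard LAD split-variable reduction: auxiliary ``u_k >= |r_k - (W T)_k|``
    and ``s >= |sum T|`` turn the cost into a linear objective with 2K + 2
    inequality rows; T is free. Solved with HiGHS dual simplex.

    The LAD optimum on a registration graph is often a flat face rather than
    a point (every node has even degree in the full pairwise graph, so
    weighted-median ties are generic), and a bare simplex solver then picks
    an ordering-dependent vertex. A second stage therefore selects the
    minimum-Euclidean-norm point of the optimal face — unique by strict
    convexity and symmetric in the nodes — which makes the estimate exactly
    invariant to timepoint relabelling.
    """
    r = np.asarray(r, dtype=float).reshape(-1)
    W = np.asarray(W, dtype=float)
    K, N = W.shape
    if r.shape[0] != K:
        raise ValueError("observation vector length does not match the incidence matrix")
    if not np.all(np.isfinite(r)):
        raise ValueError("observations must be finite")
    if np.linalg.matrix_rank(W) < N - 1:
        raise DisconnectedGraphError("incidence matrix rank < N-1: graph is disconnected")

    # variables: [T (N, free), u (K, >=0), s (1, >=0)]
    ones = np.ones((1, N))
    A_ub = np.block(
        [
            [-W, -np.eye(K), np.zeros((K, 1))],   # r - W T <= u
            [W, -np.eye(K), np.zeros((K, 1))],    # W T - r <= u
            [ones, np.zeros((1, K)), -np.ones((1, 1))],   # sum T <= s
            [-ones, np.zeros((1, K)), -np.ones((1, 1))],  # -sum T <= s
        ]
    )
    b_ub = np.concatenate([-r, r, [0.0, 0.0]])
    c = np.concatenate([np.zeros(N), np.ones(K), [float(scale_ratio)]])
    bounds = [(None, None)] * N + [(0, None)] * (K + 1)
    res = optimize.linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs-ds",
        options={"primal_feasibility_tolerance": lp_tolerance,
                 "dual_feasibility_tolerance": lp_tolerance},
    )
    if not res.success:
        raise SolverError(f"LP failed with status {res.status}: {res.message}")
    return _min_norm_on_optimal_face(res.x, res.fun, c, A_ub, b_ub, N)


def _min_norm_on_optimal_face(x0: np.ndarray, f_star: float, c: np.ndarray,
                              A_ub: np.ndarray, b_ub: np.ndarray, N: int) -> np.ndarray:
    """Project onto the minimum-norm point of the LP's optimal face.

    On the optimal face the auxiliary variables are pinned to the residual
    magnitudes, so minimising the full Euclidean norm of the split-variable
    vector is a strictly convex, node-symmetric selection with a unique
    optimum. A small SLSQP solve locates the point; an exact KKT polish on
    the identified active set (minimum-norm solution of the active equality
    system via the pseudo-inverse) then removes the iterative solver's
    termination error. Falls back to the simplex vertex if anything fails.
    """
    n_var = x0.size
    nonneg = np.zeros((n_var - N, n_var))
    nonneg[:, N:] = -np.eye(n_var - N)

    for eps_rel in (1e-11, 1e-10, 1e-9, 1e-8):
        eps = eps_rel * (1.0 + abs(f_star))
        A_full = np.vstack([A_ub, c[None, :], nonneg])
        b_full = np.concatenate([b_ub, [f_star + eps], np.zeros(n_var - N)])

        # least-distance programming (Lawson-Hanson): min ||x|| s.t. G x >= h,
        # solved exactly through an NNLS subproblem; the projection is unique
        # even when the NNLS multipliers are not. Rows are normalised (the
        # feasible set is unchanged) to keep the NNLS system well conditioned.
        G, h = -A_full, -b_full
        scale = np.linalg.norm(np.hstack([G, h[:, None]]), axis=1)
        scale[scale == 0] = 1.0
        G, h = G / scale[:, None], h / scale
        E = np.vstack([G.T, h[None, :]])
        f = np.zeros(n_var + 1)
        f[-1] = 1.0
        try:
            u, _ = optimize.nnls(E, f)
        except RuntimeError:
            continue
        r = E @ u - f
        if abs(r[-1]) < 1e-12:  # numerically infeasible slab
            continue
        x_min = -r[:-1] / r[-1]
        ok = (c @ x_min <= f_star + 10 * eps
              and np.all(A_ub @ x_min <= b_ub + 10 * eps)
              and x_min @ x_min <= x0 @ x0 + 1e-8)
        if ok:
            return x_min[:N]
    return x0[:N]


def _solve_stacked(r_stack: np.ndarray, W: np.ndarray, cfg: InferenceConfig) -> np.ndarray:
    """Solve the per-coordinate LP for every column of ``r_stack`` (K, M) -> (N, M)."""
    K, M = r_stack.shape
    N = W.shape[1]
    out = np.empty((N, M))
    for m in range(M):
        out[:, m] = solve_l1_node(r_stack[:, m], W, cfg.scale_ratio, cfg.lp_tolerance)
    return out


def solve_rigid_graph(g: ObservationGraph, cfg: InferenceConfig | None = None) -> list[RigidLog]:
    """Latent rigid logs for every timepoint from the observed pairwise rigid logs.

    Rigid parameters are location-independent, so the six se(3) coordinates
    are solved as six independent LPs over the same incidence matrix (the
    cost is separable across coordinates). Returns one canonical RigidLog per
    node, in node order.
    """
    cfg = cfg or InferenceConfig()
    if not all(isinstance(e.log_params, RigidLog) for e in g.edges):
        raise TypeError("every edge must carry a RigidLog observation")
    W = g.incidence_matrix()
    r_stack = np.stack([e.log_params.vector for e in g.edges])  # (K, 6)
    T = _solve_stacked(r_stack, W, cfg)  # (N, 6)
    return [RigidLog.from_vector(T[i]) for i in range(g.n_nodes)]


def control_lattice(grid: ImageGrid, spacing: int) -> tuple[np.ndarray, ...]:
    """Voxel indices of the control-point lattice (origin at voxel 0, given stride)."""
    axes = tuple(np.arange(0, s, spacing) for s in grid.shape)
    if any(a.size == 0 for a in axes):
        raise ValueError("control lattice is empty for this grid/stride")
    return axes


def _upsample_lattice(lattice: np.ndarray, axes: tuple[np.ndarray, ...],
                      grid: ImageGrid) -> np.ndarray:
    """Trilinear upsampling of per-coordinate lattice values back to the full grid."""
    coords = np.meshgrid(
        *(np.interp(np.arange(s, dtype=float), ax, np.arange(ax.size, dtype=float))
          for s, ax in zip(grid.shape, axes)),
        indexing="ij",
    )
    return ndimage.map_coordinates(lattice, np.stack([c.ravel() for c in coords]),
                                   order=1, mode="nearest").reshape(grid.shape)


def solve_svf_graph(g: ObservationGraph, cfg: InferenceConfig | None = None) -> list[VelocityField]:
    """Latent stationary velocity fields from observed pairwise velocity fields.

    The BCH-linearised model ``R = W T + noise`` holds per voxel and
    coordinate, so the LP is solved at a sparse control-point lattice
    (stride ``cfg.control_spacing``) and the N solved lattices are upsampled
    back to the full grid by trilinear interpolation. All edge fields must
    share the subject grid (timepoints already rigidly resampled onto it).
    """
    cfg = cfg or InferenceConfig()
    if not all(isinstance(e.log_params, VelocityField) for e in g.edges):
        raise TypeError("every edge must carry a VelocityField observation")
    grid = g.edges[0].log_params.grid
    for e in g.edges:
        if not e.log_params.grid.matches(grid):
            raise ValueError("edge velocity fields live on different grids")

    W = g.incidence_matrix()
    axes = control_lattice(grid, cfg.control_spacing)
    mesh = np.ix_(*axes)
    lat_shape = tuple(a.size for a in axes)

    # (K, n_points * 3) observations at the control points
    r_stack = np.stack(
        [e.log_params.values[mesh].reshape(-1, 3).reshape(-1) for e in g.edges]
    )
    T = _solve_stacked(r_stack, W, cfg)  # (N, n_points * 3)

    latents = []
    for i in range(g.n_nodes):
        lat = T[i].reshape(lat_shape + (3,))
        values = np.stack(
            [_upsample_lattice(lat[..., j], axes, grid) for j in range(3)], axis=-1
        )
        latents.append(VelocityField(grid, values))
    return latents


def solve_l2_node(r: np.ndarray, W: np.ndarray, scale_ratio: float = 1.0) -> np.ndarray:
    """Least-squares reference estimator with the same drift penalty (ridge-free).

    Minimises ``scale_ratio*(sum T)^2 + ||r - W T||^2`` in closed form. Used
    only as the non-robust baseline the Laplacian model is compared against.
    """
    r = np.asarray(r, dtype=float).reshape(-1)
    W = np.asarray(W, dtype=float)
    N = W.shape[1]
    ones = np.ones((1, N))
    A = W.T @ W + scale_ratio * (ones.T @ ones)
    return np.linalg.solve(A, W.T @ r)
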