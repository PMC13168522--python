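"""The L1 graph solver against brute-force and least-squares references."""

import itertools

import numpy as np
import pytest

from uslr import InferenceConfig, VelocityField, solve_l1_node, solve_rigid_graph, solve_svf_graph
from uslr.graph import TimepointNode, build_full_graph
from uslr.inference import DisconnectedGraphError, control_lattice, solve_l2_node
from uslr.lie_rigid import RigidLog
from uslr.phantom import PhantomConfig, corrupt_registrations, make_phantom_template, \
    simulate_longitudinal_series

from conftest import smooth_field


def l1_cost(T, r, W, ratio):
    return ratio * abs(T.sum()) + np.abs(r - W @ T).sum()


def test_two_node_symmetry_case():
    """One observation R splits evenly: T = (-R/2, +R/2) zeroes both terms."""
    T = solve_l1_node(np.array([3.0]), np.array([[-1.0, 1.0]]), 1.0)
    assert np.allclose(T, [-1.5, 1.5], atol=1e-9)


def test_noise_free_recovery_is_exact(rng):
    for n in (3, 5, 8):
        g = build_full_graph([TimepointNode(i, i) for i in range(n)])
        W = g.incidence_matrix()
        t_star = rng.normal(size=n)
        t_star -= t_star.mean()  # zero drift
        T = solve_l1_node(W @ t_star, W, 1.0)
        assert np.abs(T - t_star).max() < 1e-6


def brute_force_minimum(r, W, ratio, lo=-10.0, hi=10.0, step=0.25):
    grid = np.arange(lo, hi + step / 2, step)
    best = np.inf
    for T in itertools.product(grid, repeat=W.shape[1]):
        best = min(best, l1_cost(np.array(T), r, W, ratio))
    return best


def test_lp_matches_brute_force_grid(rng):
    """Exhaustive lattice search over {-10..10}^3 at step 0.25 confirms the LP
    objective on random integer instances (N=3, full graph)."""
    g = build_full_graph([TimepointNode(i, i) for i in range(3)])
    W = g.incidence_matrix()
    for _ in range(5):
        r = rng.integers(-5, 6, size=3).astype(float)
        T = solve_l1_node(r, W, 1.0)
        assert l1_cost(T, r, W, 1.0) <= brute_force_minimum(r, W, 1.0) + 1e-6


def test_lp_matches_brute_force_small_cases(rng):
    """All N <= 3, K <= 3 connected topologies with integer data."""
    cases = [
        np.array([[-1.0, 1.0]]),
        np.array([[-1, 1, 0], [0, -1, 1]], dtype=float),
        np.array([[-1, 1, 0], [0, -1, 1], [-1, 0, 1]], dtype=float),
    ]
    for W in cases:
        for _ in range(3):
            r = rng.integers(-5, 6, size=W.shape[0]).astype(float)
            T = solve_l1_node(r, W, 1.0)
            assert l1_cost(T, r, W, 1.0) <= brute_force_minimum(r, W, 1.0) + 1e-6


def test_disconnected_graph_rejected():
    W = np.array([[-1.0, 1.0, 0.0, 0.0], [0.0, 0.0, -1.0, 1.0]])
    with pytest.raises(DisconnectedGraphError):
        solve_l1_node(np.array([1.0, 2.0]), W, 1.0)


def test_prior_weight_drives_drift_to_zero(rng):
    g = build_full_graph([TimepointNode(i, i) for i in range(4)])
    W = g.incidence_matrix()
    r = rng.normal(size=W.shape[0]) + 2.0
    strong = solve_l1_node(r, W, 1e6)
    assert abs(strong.sum()) < 1e-6


def test_outlier_robustness_l1_vs_l2(rng):
    """A gross outlier edge moves the L1 solution less than least squares."""
    g = build_full_graph([TimepointNode(i, i) for i in range(5)])
    W = g.incidence_matrix()
    t_star = rng.normal(size=5)
    t_star -= t_star.mean()
    r = W @ t_star
    r_bad = r.copy()
    r_bad[3] += 10.0 * np.abs(r).max()
    shift_l1 = np.abs(solve_l1_node(r_bad, W, 1.0) - solve_l1_node(r, W, 1.0)).max()
    shift_l2 = np.abs(solve_l2_node(r_bad, W, 1.0) - solve_l2_node(r, W, 1.0)).max()
    assert shift_l1 < shift_l2


def make_rigid_graph(n, b, seed):
    cfg = PhantomConfig(seed=seed, times=tuple(0.5 * i for i in range(n)))
    tpl = make_phantom_template(cfg)
    series = simulate_longitudinal_series(tpl, cfg)
    g = build_full_graph(series.nodes)
    return series, corrupt_registrations(g, series.true_rigid, b, seed=seed + 1)


def test_rigid_graph_all_zero_observations():
    g = build_full_graph([TimepointNode(i, i) for i in range(4)])
    for e in g.edges:
        e.log_params = RigidLog(np.zeros(3), np.zeros(3))
    latents = solve_rigid_graph(g)
    assert all(np.abs(l.vector).max() < 1e-9 for l in latents)


def test_rigid_recovery_under_laplace_noise():
    """Full graph, 5 timepoints, Laplace b = 0.01: median error below b."""
    series, g = make_rigid_graph(5, b=0.01, seed=21)
    latents = solve_rigid_graph(g)
    err = np.concatenate([l.vector - t.vector for l, t in zip(latents, series.true_rigid)])
    assert np.median(np.abs(err)) < 0.01


def test_rigid_permutation_equivariance():
    """Reversing the timepoint order relabels the solution exactly."""
    series, g = make_rigid_graph(5, b=0.05, seed=22)
    latents = solve_rigid_graph(g)
    perm = list(reversed(range(5)))
    g_rev = build_full_graph([g.nodes[i] for i in perm])
    by_pair = {}
    for e in g.edges:
        by_pair[(e.ref_index, e.tgt_index)] = e.log_params
    for e in g_rev.edges:
        if (e.ref_index, e.tgt_index) in by_pair:
            e.log_params = by_pair[(e.ref_index, e.tgt_index)]
        else:  # reversed direction: negate the log-parameters
            e.log_params = -by_pair[(e.tgt_index, e.ref_index)]
    latents_rev = solve_rigid_graph(g_rev)
    for i, node_idx in enumerate(perm):
        assert np.abs(latents_rev[i].vector - latents[node_idx].vector).max() < 1e-9


def test_svf_zero_edges_give_zero_latents(small_grid):
    g = build_full_graph([TimepointNode(i, i) for i in range(3)])
    for e in g.edges:
        e.log_params = VelocityField(small_grid, np.zeros(small_grid.shape + (3,)))
    latents = solve_svf_graph(g, InferenceConfig(control_spacing=8))
    assert all(np.abs(l.values).max() < 1e-9 for l in latents)


def test_svf_noise_free_recovery_at_control_points(small_grid):
    fields = [smooth_field(small_grid, 1.0, seed=s).values for s in (1, 2, 3, 4)]
    mean = np.mean(fields, axis=0)
    t_star = [VelocityField(small_grid, f - mean) for f in fields]
    g = build_full_graph([TimepointNode(i, i) for i in range(4)])
    pos = {e: i for i, e in enumerate(range(4))}
    for e in g.edges:
        e.log_params = VelocityField(
            small_grid, t_star[e.tgt_index].values - t_star[e.ref_index].values
        )
    latents = solve_svf_graph(g, InferenceConfig(control_spacing=8))
    axes = control_lattice(small_grid, 8)
    mesh = np.ix_(*axes)
    for l, t in zip(latents, t_star):
        assert np.abs(l.values[mesh] - t.values[mesh]).max() < 1e-5


def test_svf_error_decreases_with_graph_density(default_phantom):
    """Tree (K=N-1) vs full (K=N(N-1)/2) observation graphs, same noise seed."""
    cfg, tpl, series = default_phantom
    from uslr.graph import ObservationEdge, ObservationGraph

    full = build_full_graph(series.nodes)
    tree = ObservationGraph(series.nodes,
                            [ObservationEdge(i, i + 1) for i in range(4)])
    axes = control_lattice(series.grid, 8)
    mesh = np.ix_(*axes)

    def mae(graph):
        noisy = corrupt_registrations(graph, series.true_svf, cfg.reg_noise_b, seed=33)
        latents = solve_svf_graph(noisy)
        return np.mean([np.mean(np.abs(l.values[mesh] - t.values[mesh]))
                        for l, t in zip(latents, series.true_svf)])

    assert mae(full) < mae(tree)
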