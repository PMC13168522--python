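"""Observation graph over a subject's timepoints.

The N scans of one subject are the vertices; a latent subject template sits
at the centre, connected to every timepoint by an unobserved transform (the
spanning tree). The observed data are K pairwise registrations between
timepoints; each one is, in the log domain, a noisy difference of two latent
transforms. The K x N incidence matrix W encodes that path: row k has -1 at
the reference node and +1 at the target node, so R ~ W T + noise.

The full pairwise set K = N(N-1)/2 is the default; any connected subset with
N <= K edges is admissible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

__all__ = [
    "TimepointNode",
    "ObservationEdge",
    "ObservationGraph",
    "build_full_graph",
    "subsample_graph",
    "registration_crossover",
]


@dataclass(frozen=True)
class TimepointNode:
    """One scan session: index, acquisition time (years from baseline), file paths."""

    index: int
    time_from_baseline: float
    image_path: str | None = None
    labelmap_path: str | None = None


@dataclass
class ObservationEdge:
    """A pairwise registration: reference node, target node, log-domain parameters.

    ``log_params`` is a :class:`~uslr.lie_rigid.RigidLog` (rigid stage) or a
    :class:`~uslr.svf.VelocityField` (non-linear stage); it may be None while
    the graph topology exists but registrations have not been run yet.
    """

    ref_index: int
    tgt_index: int
    log_params: object = None

    def __post_init__(self) -> None:
        if self.ref_index == self.tgt_index:
            raise ValueError("edge must connect two distinct timepoints")


@dataclass
class ObservationGraph:
    nodes: list[TimepointNode]
    edges: list[ObservationEdge] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_indices(self) -> list[int]:
        return [node.index for node in self.nodes]

    def incidence_matrix(self) -> np.ndarray:
        """K x N matrix with -1 at each edge's reference and +1 at its target."""
        pos = {idx: col for col, idx in enumerate(self.node_indices)}
        W = np.zeros((self.n_edges, self.n_nodes))
        for k, e in enumerate(self.edges):
            W[k, pos[e.ref_index]] = -1.0
            W[k, pos[e.tgt_index]] = 1.0
        return W

    def is_connected(self) -> bool:
        return _connected(self.node_indices, [(e.ref_index, e.tgt_index) for e in self.edges])


def build_full_graph(nodes: list[TimepointNode]) -> ObservationGraph:
    """All N(N-1)/2 unordered pairs, the lower index always the reference.

    Fixing the edge direction by index order makes runs reproducible; the
    direction is arbitrary as long as it is known, since reversing an edge
    just negates its row of W and its observed log-parameters.
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 timepoints to build an observation graph")
    indices = [n.index for n in nodes]
    if len(set(indices)) != len(indices):
        raise ValueError("timepoint indices must be unique")
    edges = [ObservationEdge(a, b) for a, b in combinations(sorted(indices), 2)]
    return ObservationGraph(list(nodes), edges)


def subsample_graph(g: ObservationGraph, k_target: int, seed: int = 0) -> ObservationGraph:
    """Keep a connected subset of ``k_target`` edges, chain-preferring, seeded.

    Consecutive-timepoint edges are retained first (guaranteeing
    connectivity), then the remaining quota is filled from the other edges in
    a seeded random order.
    """
    n = g.n_nodes
    k_max = n * (n - 1) // 2
    if not n <= k_target <= k_max:
        raise ValueError(f"k_target must satisfy N={n} <= K <= N(N-1)/2={k_max}")
    if k_target == g.n_edges:
        return ObservationGraph(list(g.nodes), list(g.edges))

    order = sorted(g.node_indices)
    rank = {idx: i for i, idx in enumerate(order)}
    chain = [e for e in g.edges if abs(rank[e.ref_index] - rank[e.tgt_index]) == 1]
    rest = [e for e in g.edges if abs(rank[e.ref_index] - rank[e.tgt_index]) != 1]
    rng = np.random.default_rng(seed)
    rng.shuffle(rest)
    kept = chain + rest[: k_target - len(chain)]

    sub = ObservationGraph(list(g.nodes), kept)
    if not sub.is_connected():  # chain edges guarantee this; checked regardless
        raise RuntimeError("subsampled graph lost connectivity")
    return sub


def registration_crossover(cross_sectional_per_node: int = 4) -> int:
    """Largest N for which the full pairwise graph needs no more registrations
    than an iterative groupwise scheme running ``cross_sectional_per_node``
    registrations per timepoint: N(N-1)/2 <= c*N."""
    n = 2
    while (n + 1) * n // 2 <= cross_sectional_per_node * (n + 1):
        n += 1
    return n


def _connected(indices: list[int], pairs: list[tuple[int, int]]) -> bool:
    """Union-find connectivity over the given node indices."""
    parent = {i: i for i in indices}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        parent[find(a)] = find(b)
    roots = {find(i) for i in indices}
    return len(roots) == 1


# -- manifest sidecar --------------------------------------------------------


def save_graph_manifest(g: ObservationGraph, path: str | Path,
                        edge_files: dict[int, str] | None = None) -> None:
    payload = {
        "nodes": [
            {
                "index": n.index,
                "time_from_baseline": n.time_from_baseline,
                "image": n.image_path,
                "labelmap": n.labelmap_path,
            }
            for n in g.nodes
        ],
        "edges": [
            {
                "ref": e.ref_index,
                "tgt": e.tgt_index,
                "transform": (edge_files or {}).get(k),
            }
            for k, e in enumerate(g.edges)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_graph_manifest(path: str | Path) -> tuple[ObservationGraph, list[str | None]]:
    payload = json.loads(Path(path).read_text())
    nodes = [
        TimepointNode(d["index"], d["time_from_baseline"], d.get("image"), d.get("labelmap"))
        for d in payload["nodes"]
    ]
    edges = [ObservationEdge(d["ref"], d["tgt"]) for d in payload["edges"]]
    files = [d.get("transform") for d in payload["edges"]]
    return ObservationGraph(nodes, edges), files
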