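"""Weighted brain graphs, path-length metrics, null normalization, hubs.

Connectivity matrices are thresholded to a target edge density over a
maximum-spanning-tree backbone (which guarantees connectedness), negative
correlations being zeroed or rectified by policy.  Path lengths use the
standard distance transform d = 1/w for correlation-weighted connectomes.

Metrics follow the connectomics conventions:

* connection strength (weighted degree): sum of a node's incident weights;
  total connection strength is the sum over nodes (twice the edge-weight sum);
* nodal efficiency: mean inverse shortest-path length to the other nodes;
* farness (the closeness-centrality variant used for hub analysis): mean
  shortest-path length to the other nodes — lower is better;
* global efficiency: mean inverse shortest-path length over ordered pairs.

Efficiency and farness are normalized against the mean over an ensemble of
degree-preserving surrogate graphs: the binary topology is randomized by
connectivity-preserving double-edge swaps and the empirical edge-weight
multiset is randomly permuted onto the rewired edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree

__all__ = [
    "BrainGraph",
    "NullEnsembleSpec",
    "NodalMetrics",
    "GlobalMetrics",
    "build_graph",
    "compute_nodal_metrics",
    "compute_global_metrics",
    "generate_null_ensemble",
    "identify_hubs",
]


@dataclass
class BrainGraph:
    """Thresholded, connected, non-negatively weighted undirected graph."""

    subject_id: str
    weights: np.ndarray  # symmetric, zero diagonal, >= 0
    edge_density: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-edges are not allowed")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> np.ndarray:
        """(n_edges, 3) array of (i, j, weight) with i < j."""
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return np.column_stack([iu, ju, self.weights[iu, ju]])


@dataclass(frozen=True)
class NullEnsembleSpec:
    """Size and randomization intensity of the degree-preserving ensemble."""

    n_nulls: int = 500
    swaps_per_edge: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


@dataclass
class NodalMetrics:
    subject_id: str
    strength: np.ndarray
    farness: np.ndarray
    nodal_efficiency: np.ndarray
    hub_flag: np.ndarray | None = None


@dataclass
class GlobalMetrics:
    subject_id: str
    connection_strength_total: float
    global_efficiency_raw: float
    global_efficiency_normalized: float | None = None
    farness_normalized: np.ndarray | None = None
    nodal_efficiency_normalized: np.ndarray | None = None


def _is_connected(weights: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(weights), directed=False)
    return n_comp == 1


def build_graph(
    conn,
    negative_policy: str = "zero",
    target_density: float = 0.10,
) -> BrainGraph:
    """Threshold a connectivity matrix into a connected weighted graph.

    The maximum-weight spanning tree is always retained as a backbone, then
    the strongest remaining edges are added until the target edge density is
    reached, so the realized edge count is ``max(n-1, round(density*n*(n-1)/2))``.
    """
    if negative_policy not in ("zero", "absolute"):
        raise ValueError("negative_policy must be 'zero' or 'absolute'")
    if not (0 < target_density <= 1):
        raise ValueError("target_density must lie in (0, 1]")
    vals = np.array(conn.values if hasattr(conn, "values") else conn, dtype=float)
    n = vals.shape[0]
    w = np.abs(vals) if negative_policy == "absolute" else np.where(vals > 0, vals, 0.0)
    np.fill_diagonal(w, 0.0)

    n_pos = int(np.count_nonzero(np.triu(w, 1)))
    if n_pos < n - 1 or not _is_connected(w):
        raise ValueError(
            "cannot build a connected graph: fewer than n-1 usable edges under "
            f"negative_policy={negative_policy!r} (have {n_pos}, need {n - 1})"
        )

    # maximum spanning tree == minimum spanning tree on negated weights
    mst = minimum_spanning_tree(csr_matrix(-w)).toarray()
    backbone = mst != 0
    backbone = backbone | backbone.T

    m_target = max(n - 1, int(round(target_density * n * (n - 1) / 2.0)))
    keep = np.zeros_like(w, dtype=bool)
    keep |= backbone
    n_more = m_target - (n - 1)
    if n_more > 0:
        iu, ju = np.nonzero(np.triu(w, 1) * ~np.triu(backbone, 1))
        order = np.argsort(w[iu, ju])[::-1][:n_more]
        keep[iu[order], ju[order]] = True
        keep[ju[order], iu[order]] = True

    out = np.where(keep, w, 0.0)
    realized = np.count_nonzero(np.triu(out, 1)) / (n * (n - 1) / 2.0)
    return BrainGraph(
        subject_id=getattr(conn, "subject_id", ""),
        weights=out,
        edge_density=realized,
        provenance={"negative_policy": negative_policy, "target_density": target_density},
    )


def _shortest_path_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    if np.isinf(d).any():
        raise ValueError("graph is disconnected; path-length metrics undefined")
    return d


def _metric_bundle(weights: np.ndarray):
    """strength, farness, nodal efficiency, global efficiency from one Dijkstra."""
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _shortest_path_matrix(weights)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    inv[off] = 1.0 / d[off]
    strength = weights.sum(axis=1)
    farness = d.sum(axis=1) / (n - 1)
    nodal_eff = inv.sum(axis=1) / (n - 1)
    return strength, farness, nodal_eff, float(nodal_eff.mean())


def compute_nodal_metrics(graph: BrainGraph) -> NodalMetrics:
    """Strength, farness, and nodal efficiency (edge length 1/weight)."""
    strength, farness, nodal_eff, _ = _metric_bundle(graph.weights)
    return NodalMetrics(graph.subject_id, strength, farness, nodal_eff)


def _global_efficiency(weights: np.ndarray) -> float:
    return _metric_bundle(weights)[3]


def compute_global_metrics(graph: BrainGraph, nulls=None) -> GlobalMetrics:
    """Whole-network metrics, optionally normalized against a null ensemble.

    Normalized values are ratios of the observed metric to its mean over the
    degree-preserving nulls (global efficiency globally; farness and nodal
    efficiency per node).
    """
    strength, farness, nodal_eff, raw_eff = _metric_bundle(graph.weights)
    gm = GlobalMetrics(
        subject_id=graph.subject_id,
        connection_strength_total=float(strength.sum()),
        global_efficiency_raw=raw_eff,
    )
    if nulls is not None:
        if len(nulls) == 0:
            raise ValueError("normalization requested with an empty null ensemble")
        null_eff, null_far, null_neff = [], [], []
        for g in nulls:
            s_, far_, neff_, geff_ = _metric_bundle(g.weights)
            null_eff.append(geff_)
            null_far.append(far_)
            null_neff.append(neff_)
        gm.global_efficiency_normalized = raw_eff / float(np.mean(null_eff))
        gm.farness_normalized = farness / np.mean(null_far, axis=0)
        gm.nodal_efficiency_normalized = nodal_eff / np.mean(null_neff, axis=0)
    return gm


def _bfs_connected(adj: list[set], n: int) -> bool:
    seen = bytearray(n)
    stack = [0]
    seen[0] = 1
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = 1
                count += 1
                stack.append(v)
    return count == n


def _rewire_connected(edges: np.ndarray, n: int, n_swaps: int, rng, check_every: int = 100):
    """Degree-preserving double-edge swaps that keep the graph connected.

    Swaps are applied greedily; connectivity is verified every ``check_every``
    accepted swaps and the offending window is rolled back on failure.
    Returns the rewired edge list (i, j) with i < j.
    """
    edges = [tuple(sorted(e)) for e in edges]
    edge_set = set(edges)
    adj = [set() for _ in range(n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    def apply(idx_a, idx_b, new_a, new_b):
        for (i, j) in (edges[idx_a], edges[idx_b]):
            edge_set.discard((i, j))
            adj[i].discard(j)
            adj[j].discard(i)
        for (i, j) in (new_a, new_b):
            edge_set.add((i, j))
            adj[i].add(j)
            adj[j].add(i)
        edges[idx_a], edges[idx_b] = new_a, new_b

    m = len(edges)
    accepted = 0
    attempts = 0
    max_attempts = 40 * n_swaps + 100
    window: list[tuple] = []
    while accepted < n_swaps and attempts < max_attempts:
        attempts += 1
        a, b = rng.integers(0, m, size=2)
        if a == b:
            continue
        (u, v), (x, y) = edges[a], edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        e1, e2 = tuple(sorted((u, x))), tuple(sorted((v, y)))
        if e1 in edge_set or e2 in edge_set:
            continue
        window.append((a, b, edges[a], edges[b]))
        apply(a, b, e1, e2)
        accepted += 1
        if accepted % check_every == 0 or accepted == n_swaps:
            if not _bfs_connected(adj, n):
                for a_, b_, old_a, old_b in reversed(window):
                    new_a, new_b = edges[a_], edges[b_]
                    apply(a_, b_, old_a, old_b)
                    assert edges[a_] == old_a and edges[b_] == old_b
                accepted -= len(window)
            window = []
    if window and not _bfs_connected(adj, n):
        for a_, b_, old_a, old_b in reversed(window):
            apply(a_, b_, old_a, old_b)
    return np.array(edges, dtype=int)


def generate_null_ensemble(graph: BrainGraph, spec: NullEnsembleSpec) -> list[BrainGraph]:
    """Degree-preserving, weight-multiset-preserving surrogate graphs.

    Each null rewires the binary topology by connectivity-preserving
    double-edge swaps (a saturated graph admits none and keeps its topology)
    and then randomly permutes the observed edge weights onto the rewired
    edges.  Fully seeded and independent across ensemble members.
    """
    n = graph.n_nodes
    el = graph.edge_list()
    edges = el[:, :2].astype(int)
    weight_pool = el[:, 2]
    m = len(edges)
    n_swaps = spec.swaps_per_edge * m
    rng = np.random.default_rng(spec.seed)
    nulls = []
    saturated = m == n * (n - 1) // 2
    for k in range(spec.n_nulls):
        new_edges = edges if saturated else _rewire_connected(edges, n, n_swaps, rng)
        perm = rng.permutation(m)
        w = np.zeros((n, n))
        w[new_edges[:, 0], new_edges[:, 1]] = weight_pool[perm]
        w += w.T
        nulls.append(
            BrainGraph(
                subject_id=f"{graph.subject_id}~null{k}",
                weights=w,
                edge_density=graph.edge_density,
                provenance={**graph.provenance, "null_index": k},
            )
        )
    return nulls


def identify_hubs(reference_strengths: np.ndarray, k_sd: float = 2.0) -> np.ndarray:
    """Hub regions: reference strength > mean + k_sd * sample SD across regions.

    Reference strengths are per-region means over the gene-negative group, so
    the hub definition is independent of carrier/FTD data.  Zero variance
    across regions yields an empty hub set.
    """
    s = np.asarray(reference_strengths, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 regions to identify hubs")
    sd = s.std(ddof=1)
    if sd == 0:
        return np.zeros(s.size, dtype=bool)
    return s > s.mean() + k_sd * sd
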