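"""Graph-theoretic reduction of directed connectivity networks.

Cohort-level thresholding keeps, for every network in a band, its k
strongest connections, with k fixed across the cohort as the smallest count
for which every thresholded network is (weakly) connected. Scalar indices
(global efficiency, local efficiency, characteristic path length, clustering
coefficient) are computed on the binary directed graph; degree-type metrics
count binary edges while strength-type metrics sum retained weights, per the
Brain Connectivity Toolbox conventions for directed graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityNetwork
from .types import ROILayout


@dataclass
class ThresholdedGraph:
    """Top-k thresholded directed graph (target x source orientation)."""

    binary_adj: np.ndarray
    weighted_adj: np.ndarray
    band: str
    channel_labels: tuple
    subject_id: str = ""
    condition: str = ""

    @property
    def n_edges(self) -> int:
        return int(self.binary_adj.sum())


@dataclass
class GraphSummary:
    """Whole-network scalars plus per-node and per-ROI degree/strength metrics."""

    global_efficiency: float
    local_efficiency: float
    char_path_length: float
    clustering_coeff: float
    node_metrics: dict  # metric name -> per-node array
    roi_metrics: dict = field(default_factory=dict)  # (roi, metric) -> mean
    channel_labels: tuple = ()


def _ranked_edges(net: ConnectivityNetwork) -> list:
    """Off-diagonal edges sorted by descending weight; ties break by labels."""
    labels = net.channel_labels
    n = len(labels)
    edges = [
        (net.weights[t, s], labels[s], labels[t], s, t)
        for s in range(n)
        for t in range(n)
        if s != t and net.weights[t, s] > 0
    ]
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    return edges


def _top_k_adj(net: ConnectivityNetwork, k: int) -> np.ndarray:
    n = len(net.channel_labels)
    adj = np.zeros((n, n), dtype=int)
    for _, _, _, s, t in _ranked_edges(net)[:k]:
        adj[t, s] = 1
    return adj


def _weakly_connected(binary_adj: np.ndarray) -> bool:
    g = nx.from_numpy_array(binary_adj.T, create_using=nx.DiGraph)
    return nx.is_weakly_connected(g)


def fixed_edge_threshold(
    networks: list[ConnectivityNetwork],
) -> tuple[list[ThresholdedGraph], int]:
    """Smallest common edge count that keeps every network connected.

    For each candidate k, every network keeps its own k strongest weights
    (deterministic label-order tie-break); the chosen k is the smallest for
    which the undirected collapse of every thresholded network is connected.
    """
    if not networks:
        raise ValueError("cohort of networks must be non-empty")
    labels = networks[0].channel_labels
    if any(net.channel_labels != labels for net in networks):
        raise ValueError("all networks must share the same node set")
    n = len(labels)
    max_edges = [len(_ranked_edges(net)) for net in networks]
    # a network that is disconnected even with all its nonzero edges can
    # never satisfy the criterion
    offenders = [
        getattr(net, "subject_id", "") or f"network {i}"
        for i, (net, m) in enumerate(zip(networks, max_edges))
        if not _weakly_connected(_top_k_adj(net, m))
    ]
    if offenders:
        raise ValueError(
            "networks cannot be connected even with all nonzero edges: "
            + ", ".join(map(str, offenders))
        )
    for k in range(1, max(max_edges) + 1):
        adjs = [_top_k_adj(net, min(k, m)) for net, m in zip(networks, max_edges)]
        if all(_weakly_connected(a) for a in adjs):
            graphs = [
                ThresholdedGraph(
                    binary_adj=a,
                    weighted_adj=np.where(a > 0, net.weights, 0.0),
                    band=net.band,
                    channel_labels=labels,
                    subject_id=getattr(net, "subject_id", ""),
                    condition=getattr(net, "condition", ""),
                )
                for a, net in zip(adjs, networks)
            ]
            return graphs, k
    raise RuntimeError("unreachable: full edge sets are connected")


def _global_efficiency(binary_adj: np.ndarray, unweighted: bool = True) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    n = binary_adj.shape[0]
    if n < 2:
        return 0.0
    # shortest_path expects [i, j] = edge i -> j; ours is [target, source]
    d = shortest_path(binary_adj.T, method="D", unweighted=unweighted)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv[off] = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv[off].sum() / (n * (n - 1)))


def _char_path_length(binary_adj: np.ndarray, unweighted: bool = True) -> float:
    """Mean finite shortest-path length over ordered node pairs."""
    n = binary_adj.shape[0]
    d = shortest_path(binary_adj.T, method="D", unweighted=unweighted)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def _local_efficiency(
    binary_adj: np.ndarray,
    path_adj: np.ndarray | None = None,
    unweighted: bool = True,
) -> float:
    """Mean over nodes of the global efficiency of the neighborhood subgraph.

    The neighborhood of a node is the union of its in- and out-neighbors
    (directed BCT convention); nodes with fewer than two neighbors
    contribute zero.
    """
    n = binary_adj.shape[0]
    if path_adj is None:
        path_adj = binary_adj
    undirected = (binary_adj + binary_adj.T) > 0
    eff = np.zeros(n)
    for i in range(n):
        nb = np.where(undirected[i])[0]
        nb = nb[nb != i]
        if nb.size < 2:
            continue
        sub = path_adj[np.ix_(nb, nb)]
        eff[i] = _global_efficiency(sub, unweighted=unweighted)
    return float(eff.mean())


def _clustering_coefficient(binary_adj: np.ndarray) -> float:
    """Directed binary clustering (Fagiolo), averaged over nodes.

    t_i = ((A + A^T)^3)_ii / 2 closed directed triangles around node i;
    the denominator corrects total degree for reciprocal edges.
    """
    A = (binary_adj.T > 0).astype(float)  # A[i, j] = edge i -> j
    S = A + A.T
    t = np.diag(S @ S @ S) / 2.0
    d_tot = A.sum(axis=0) + A.sum(axis=1)
    d_bi = np.diag(A @ A)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    c = np.divide(t, denom, out=np.zeros_like(t), where=denom > 0)
    return float(c.mean())


def _weighted_distance_adj(weighted_adj: np.ndarray) -> np.ndarray:
    """Edge lengths 1/weight (target x source orientation preserved)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weighted_adj > 0, 1.0 / weighted_adj, 0.0)
    return lengths


def graph_metrics(
    graph: ThresholdedGraph,
    roi: ROILayout | None = None,
    distance: str = "binary",
) -> GraphSummary:
    """All whole-network, per-node and per-ROI indices of one graph.

    Path-based indices use hop counts by default; ``distance="weighted"``
    uses 1/weight edge lengths instead (degree/strength metrics are
    unaffected).
    """
    if distance not in ("binary", "weighted"):
        raise ValueError("distance must be binary or weighted")
    adj = graph.binary_adj
    n = adj.shape[0]
    if n == 0 or adj.sum() == 0:
        raise ValueError("graph has no edges")
    w = graph.weighted_adj
    in_degree = adj.sum(axis=1).astype(float)  # row = target
    out_degree = adj.sum(axis=0).astype(float)
    in_strength = w.sum(axis=1)
    out_strength = w.sum(axis=0)
    tot = in_degree + out_degree
    with np.errstate(invalid="ignore", divide="ignore"):
        in_fraction = np.where(tot > 0, in_degree / tot, np.nan)
    node_metrics = {
        "degree": in_degree + out_degree,
        "in_degree": in_degree,
        "out_degree": out_degree,
        "strength": in_strength + out_strength,
        "in_strength": in_strength,
        "out_strength": out_strength,
        "in_degree_fraction": in_fraction,
    }
    if distance == "binary":
        path_adj, unweighted = adj, True
    else:
        path_adj, unweighted = _weighted_distance_adj(w), False
    summary = GraphSummary(
        global_efficiency=_global_efficiency(path_adj, unweighted=unweighted),
        local_efficiency=_local_efficiency(
            adj, path_adj=path_adj, unweighted=unweighted
        ),
        char_path_length=_char_path_length(path_adj, unweighted=unweighted),
        clustering_coeff=_clustering_coefficient(adj),
        node_metrics=node_metrics,
        channel_labels=graph.channel_labels,
    )
    if roi is not None and graph.channel_labels:
        idx = {ch: i for i, ch in enumerate(graph.channel_labels)}
        for roi_name, members in roi.rois.items():
            rows = [idx[ch] for ch in members if ch in idx]
            if not rows:
                continue
            for mname, values in node_metrics.items():
                vals = values[rows]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    summary.roi_metrics[(roi_name, mname)] = float(vals.mean())
    return summary
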