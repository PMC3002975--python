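"""Local and global descriptors of contact networks.

A contact network is a simple, undirected, unweighted graph. The
descriptors computed here are the per-node degree k_i, the mean degree of
a node's neighbors k_nn,i (nearest-neighbor degree correlation), the
clustering coefficient C_i (fraction of a node's neighbor pairs that are
themselves connected), and the mean shortest-path length L_i. Profiles of
k_nn and C against degree are the raw material for the assortativity
analysis: a rising k_nn(k) means high-degree nodes preferentially touch
other high-degree nodes.

Quantities that are undefined for a node (k_nn for isolated nodes, C for
degree < 2, L for singleton components) are reported as NaN and excluded
from every average, never zero-filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ContactGraph",
    "DegreeProfile",
    "compute_degrees",
    "compute_knn",
    "compute_clustering",
    "compute_path_lengths",
    "build_degree_profile",
    "edge_degree_correlation",
    "node_table",
]


@dataclass(frozen=True)
class ContactGraph:
    """Simple undirected unweighted graph on nodes 0..n_nodes-1.

    Equivalent to a symmetric 0/1 adjacency matrix with zero diagonal.
    Node labels from input files are preserved in ``labels`` for
    round-tripping; all computation uses the integer indices.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("ContactGraph needs at least one node")
        canon = set()
        for e in self.edges:
            i, j = e
            if i == j:
                raise ValueError(f"self-edge on node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge {e} outside 0..{self.n_nodes - 1}")
            canon.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(canon))
        if self.labels is not None and len(self.labels) != self.n_nodes:
            raise ValueError("labels length must equal n_nodes")

    @classmethod
    def from_edges(cls, n_nodes: int, edges, labels=None) -> "ContactGraph":
        edges = frozenset((min(i, j), max(i, j)) for i, j in edges)
        return cls(n_nodes=n_nodes,
                   edges=edges,
                   labels=None if labels is None else tuple(labels))

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "ContactGraph":
        nodes = sorted(g.nodes())
        index = {v: i for i, v in enumerate(nodes)}
        edges = frozenset((index[u], index[v]) for u, v in g.edges())
        return cls(n_nodes=len(nodes), edges=edges,
                   labels=tuple(str(v) for v in nodes))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def compute_degrees(graph: ContactGraph) -> np.ndarray:
    """Per-node degree k_i; the sum over nodes equals twice the edge count."""
    k = np.zeros(graph.n_nodes, dtype=int)
    for i, j in graph.edges:
        k[i] += 1
        k[j] += 1
    return k


def compute_knn(graph: ContactGraph) -> np.ndarray:
    """Mean neighbor degree k_nn,i = (1/k_i) Σ_j A_ij k_j; NaN for isolated nodes."""
    g = graph.to_networkx()
    knn = nx.average_neighbor_degree(g)
    out = np.full(graph.n_nodes, np.nan)
    k = compute_degrees(graph)
    for i in range(graph.n_nodes):
        if k[i] > 0:
            out[i] = knn[i]
    return out


def compute_clustering(graph: ContactGraph) -> np.ndarray:
    """Clustering coefficient C_i = 2 I_i / (k_i (k_i - 1)); NaN for k_i < 2.

    I_i is the number of edges interconnecting the neighbors of i.
    """
    g = graph.to_networkx()
    cc = nx.clustering(g)
    k = compute_degrees(graph)
    out = np.full(graph.n_nodes, np.nan)
    for i in range(graph.n_nodes):
        if k[i] >= 2:
            out[i] = cc[i]
    return out


def compute_path_lengths(graph: ContactGraph) -> np.ndarray:
    """Mean shortest-path length L_i from all other reachable nodes to i.

    Averaged within the node's connected component; NaN for singleton
    components. The systems of interest are connected, so the
    per-component averaging is a safety rail and is logged.
    """
    g = graph.to_networkx()
    out = np.full(graph.n_nodes, np.nan)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        logger.warning(
            "graph is disconnected (%d components); path lengths averaged "
            "within components", len(components))
    for comp in components:
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        for i, dists in nx.all_pairs_shortest_path_length(sub):
            out[i] = sum(dists.values()) / (len(comp) - 1)
    return out


def edge_degree_correlation(graph: ContactGraph) -> float:
    """Pearson correlation of end-point degrees over edges (both orientations).

    Positive values indicate assortative mixing. NaN when either end's
    degree sequence is constant (regular graphs), where the correlation
    is undefined.
    """
    if graph.n_edges < 2:
        raise ValueError("need at least 2 edges for a degree correlation")
    k = compute_degrees(graph)
    x, y = [], []
    for i, j in graph.edges:
        x.extend((k[i], k[j]))
        y.extend((k[j], k[i]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def node_table(graph: ContactGraph) -> pd.DataFrame:
    """All per-node descriptors in one frame (columns node_label, k, knn, C, L)."""
    labels = graph.labels or tuple(str(i) for i in range(graph.n_nodes))
    return pd.DataFrame({
        "node_label": labels,
        "k": compute_degrees(graph),
        "knn": compute_knn(graph),
        "C": compute_clustering(graph),
        "L": compute_path_lengths(graph),
    })


@dataclass(frozen=True)
class DegreeProfile:
    """Per-degree aggregates pooled over a set of graphs.

    ``degrees`` lists the degrees retained for the k_nn/C profiles after
    the exclusion rules (minimum node count per degree bin, optional
    degree window); ``p_k`` is the empirical degree distribution over
    *all* observed degrees, unaffected by the exclusions.
    """

    degrees: tuple[int, ...]
    n_k: tuple[int, ...]
    knn_mean: tuple[float, ...]
    knn_sd: tuple[float, ...]
    C_mean: tuple[float, ...]
    C_sd: tuple[float, ...]
    p_k: dict[int, float] = field(repr=False)

    @property
    def z(self) -> float:
        """Mean degree of the pooled node set."""
        return sum(k * p for k, p in self.p_k.items())

    @property
    def k2_over_z(self) -> float:
        """Second-to-first moment ratio of the pooled degree distribution."""
        return sum(k * k * p for k, p in self.p_k.items()) / self.z

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.degrees,
            "n_k": self.n_k,
            "knn_mean": self.knn_mean,
            "knn_sd": self.knn_sd,
            "C_mean": self.C_mean,
            "C_sd": self.C_sd,
        })


def build_degree_profile(graphs,
                         min_nodes_per_degree: int = 1,
                         degree_window: tuple[int, int] | None = None,
                         ) -> DegreeProfile:
    """Pool nodes across graphs and aggregate k_nn and C by degree.

    Degree bins with fewer than ``min_nodes_per_degree`` nodes, or outside
    the inclusive ``degree_window``, are excluded from the k_nn/C profile
    (they lack the statistics to be meaningful) but are retained in the
    empirical degree distribution p_k. Dispersions are sample standard
    deviations (NaN for single-node bins).
    """
    if min_nodes_per_degree < 1:
        raise ValueError("min_nodes_per_degree must be >= 1")
    graphs = list(graphs)
    if not graphs or all(g.n_nodes == 0 for g in graphs):
        raise ValueError("need at least one non-empty graph")

    frames = []
    for g in graphs:
        frames.append(pd.DataFrame({
            "k": compute_degrees(g),
            "knn": compute_knn(g),
            "C": compute_clustering(g),
        }))
    pool = pd.concat(frames, ignore_index=True)

    counts = pool["k"].value_counts().sort_index()
    p_k = (counts / counts.sum()).to_dict()

    grouped = pool.groupby("k").agg(
        n_k=("k", "size"),
        knn_mean=("knn", "mean"),
        knn_sd=("knn", lambda s: s.std(ddof=1)),
        C_mean=("C", "mean"),
        C_sd=("C", lambda s: s.std(ddof=1)),
    ).reset_index()

    keep = grouped["n_k"] >= min_nodes_per_degree
    if degree_window is not None:
        lo, hi = degree_window
        keep &= (grouped["k"] >= lo) & (grouped["k"] <= hi)
    for _, row in grouped[~keep].iterrows():
        logger.info("degree bin k=%d excluded (n_k=%d)",
                    int(row["k"]), int(row["n_k"]))
    grouped = grouped[keep]
    if grouped.empty:
        raise ValueError("no degree bins retained after filtering")

    return DegreeProfile(
        degrees=tuple(int(k) for k in grouped["k"]),
        n_k=tuple(int(n) for n in grouped["n_k"]),
        knn_mean=tuple(float(v) for v in grouped["knn_mean"]),
        knn_sd=tuple(float(v) for v in grouped["knn_sd"]),
        C_mean=tuple(float(v) for v in grouped["C_mean"]),
        C_sd=tuple(float(v) for v in grouped["C_sd"]),
        p_k={int(k): float(p) for k, p in p_k.items()},
    )
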