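"""Weighted graphs from connectivity matrices and the 24 graph-level measures.

Conventions
-----------
Edge weights default to the absolute correlation |r| (association strength);
a signed mode exists but most measures are undefined for negative weights.
Path-based measures (average path length, betweenness, closeness, diameter,
eccentricity, efficiency, community path lengths) convert strength to
distance as ``d = 1/w`` (strong association = short distance); ``1 - w`` is
available as an alternative.  Degree-based measures use the binary degree
when proportional thresholding is on and the weighted strength (sum of
incident weights) otherwise.  Transitivity, density and the k-core index are
computed on edge presence in both modes.  Node-level measures are aggregated
by their unweighted mean over nodes.

The seven community path-length statistics (AFC, AIC, ALC, ALPC, AEBC, ASPC,
AMC) find the largest community under, respectively, fastgreedy, infomap,
leading-eigenvector, label-propagation, edge-betweenness, spinglass and
multilevel community detection, and return the mean shortest-path distance
within that community's induced subgraph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix
from .data import FeatureTable

STANDARD_MEASURES: tuple[str, ...] = (
    "assortativity", "average_path_length", "betweenness_centrality",
    "closeness_centrality", "eigenvector_centrality", "diameter", "hub_score",
    "knn", "mean_degree", "second_moment_degree", "entropy_degree",
    "transitivity", "complexity", "k_core", "eccentricity", "density",
    "efficiency",
)

#: community-APL measure name -> detection algorithm
COMMUNITY_MEASURES: dict[str, str] = {
    "AFC": "fastgreedy",
    "AIC": "infomap",
    "ALC": "leading_eigenvector",
    "ALPC": "label_propagation",
    "AEBC": "edge_betweenness",
    "ASPC": "spinglass",
    "AMC": "multilevel",
}

ALL_MEASURES: tuple[str, ...] = STANDARD_MEASURES + tuple(COMMUNITY_MEASURES)

COMMUNITY_ALGORITHMS: tuple[str, ...] = tuple(COMMUNITY_MEASURES.values())


@dataclass
class GraphConfig:
    """How a connectivity matrix becomes a graph and how distances are derived.

    threshold: proportional threshold in (0, 1] keeping that fraction of the
        strongest edges by |r|, or None for the fully weighted dense graph.
    weight_mode: "abs" uses |r| as edge weight; "signed" keeps r (positive
        edges only are retained, negative correlations are dropped).
    distance: "inverse" (d = 1/w) or "one_minus" (d = 1 - w).
    """

    weight_mode: str = "abs"
    threshold: float | None = None
    distance: str = "inverse"

    def __post_init__(self) -> None:
        if self.weight_mode not in ("abs", "signed"):
            raise ValueError("weight_mode must be 'abs' or 'signed'")
        if self.threshold is not None and not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1] or None")
        if self.distance not in ("inverse", "one_minus"):
            raise ValueError("distance must be 'inverse' or 'one_minus'")

    @property
    def binary_degrees(self) -> bool:
        return self.threshold is not None


@dataclass
class WeightedGraph:
    """Undirected weighted graph; absent edges have weight 0, no self-loops."""

    node_names: list[str]
    W: np.ndarray
    config: GraphConfig = field(default_factory=GraphConfig)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        n = len(self.node_names)
        if self.W.shape != (n, n):
            raise ValueError(f"weight matrix must be {n}x{n}")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.diag(self.W).any():
            raise ValueError("self-loops are not allowed")
        if (self.W < 0).any():
            raise ValueError("edge weights must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return int((self.W > 0).sum()) // 2


def build_graph(matrix: ConnectivityMatrix | np.ndarray,
                config: GraphConfig | None = None,
                node_names: list[str] | None = None) -> WeightedGraph:
    """Turn a connectivity matrix into a weighted graph per the config.

    With proportional thresholding, exactly ``round(threshold * n_pairs)`` of
    the strongest edges by |r| are retained (ties broken by pair order).  A
    node left isolated is recorded as a note, not an error.
    """
    config = config or GraphConfig()
    if isinstance(matrix, ConnectivityMatrix):
        values = matrix.values
        names = list(matrix.channel_names)
    else:
        values = np.asarray(matrix, dtype=np.float64)
        names = node_names or [f"n{i}" for i in range(values.shape[0])]
    n = values.shape[0]
    W = np.abs(values.copy()) if config.weight_mode == "abs" else values.copy()
    np.fill_diagonal(W, 0.0)
    if config.weight_mode == "signed":
        W[W < 0] = 0.0
    notes: list[str] = []
    if config.threshold is not None:
        iu = np.triu_indices(n, k=1)
        strengths = np.abs(values)[iu]
        n_keep = int(round(config.threshold * strengths.size))
        keep = np.zeros(strengths.size, dtype=bool)
        keep[np.argsort(-strengths, kind="stable")[:n_keep]] = True
        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = keep
        mask |= mask.T
        W = np.where(mask, W, 0.0)
    isolated = np.flatnonzero((W > 0).sum(axis=1) == 0)
    if isolated.size:
        notes.append(f"isolated nodes after thresholding: {[names[i] for i in isolated]}")
    return WeightedGraph(node_names=names, W=W, config=config, notes=notes)


def distance_weights(graph: WeightedGraph) -> np.ndarray:
    """Per-edge distances under the graph's distance convention (0 = absent)."""
    W = graph.W
    D = np.zeros_like(W)
    present = W > 0
    if graph.config.distance == "inverse":
        D[present] = 1.0 / W[present]
    else:
        D[present] = np.maximum(1.0 - W[present], 1e-12)
    return D


def distance_matrix(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path distances (inf across components)."""
    return shortest_path(csr_matrix(distance_weights(graph)), method="D", directed=False)


def _to_igraph(graph: WeightedGraph) -> ig.Graph:
    src, dst = np.nonzero(np.triu(graph.W, k=1))
    w = graph.W[src, dst]
    g = ig.Graph(n=graph.n_nodes, edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = w.tolist()
    if graph.config.distance == "inverse":
        g.es["distance"] = (1.0 / w).tolist()
    else:
        g.es["distance"] = np.maximum(1.0 - w, 1e-12).tolist()
    return g


def _degrees(graph: WeightedGraph) -> np.ndarray:
    if graph.config.binary_degrees:
        return (graph.W > 0).sum(axis=1).astype(float)
    return graph.W.sum(axis=1)


def compute_standard_measures(graph: WeightedGraph) -> dict[str, float]:
    """The 17 standard graph-level scalars.

    Path-based measures of a disconnected graph are computed on the largest
    connected component and a note is recorded on the graph.  Assortativity of
    a perfectly regular graph (zero degree variance) is defined as 0.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("graph needs >= 2 nodes")
    W = graph.W
    B = (W > 0)
    deg = _degrees(graph)
    adj = B.astype(float) if graph.config.binary_degrees else W

    mean_degree = float(deg.mean())
    smd = float((deg**2).mean())
    complexity = smd / mean_degree if mean_degree > 0 else 0.0

    total = deg.sum()
    if total > 0:
        p = deg[deg > 0] / total
        entropy_degree = float(-(p * np.log(p)).sum())
    else:
        entropy_degree = 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        knn_i = (adj @ deg) / deg
    knn = float(np.nanmean(np.where(deg > 0, knn_i, np.nan))) if (deg > 0).any() else 0.0

    src, dst = np.nonzero(np.triu(B, k=1))
    if src.size:
        x = np.concatenate([deg[src], deg[dst]])
        y = np.concatenate([deg[dst], deg[src]])
        if np.ptp(x) == 0:
            assortativity = 0.0  # regular graph: no degree-mixing trend
        else:
            assortativity = float(np.corrcoef(x, y)[0, 1])
    else:
        assortativity = 0.0

    # spectral measures: the Perron vector of W (largest algebraic eigenvalue,
    # unique and nonnegative for connected nonnegative graphs).  On an
    # undirected graph the principal-eigenvector hub measure coincides with
    # eigenvector centrality, so both report the same aggregate.
    evals, evecs = np.linalg.eigh(W)
    v = np.abs(evecs[:, np.argmax(evals)])
    ec = float((v / v.max()).mean()) if v.max() > 0 else 0.0
    hub = ec

    # presence-based measures
    bint = B.astype(np.int64)
    triads = int((bint.sum(axis=1) * (bint.sum(axis=1) - 1)).sum())
    closed = int(np.trace(bint @ bint @ bint))
    transitivity = closed / triads if triads else 0.0
    density = float(bint.sum() / (n * (n - 1)))
    gx = nx.from_numpy_array(bint)
    gx.remove_edges_from(nx.selfloop_edges(gx))
    k_core = float(max(nx.core_number(gx).values())) if gx.number_of_edges() else 0.0

    # path-based measures
    D = distance_matrix(graph)
    n_comp, labels = connected_components(csr_matrix(B), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        comp = int(np.argmax(sizes))
        L = np.flatnonzero(labels == comp)
        graph.notes.append(
            f"graph has {n_comp} components; path measures computed on the "
            f"largest ({sizes[comp]} nodes)"
        )
    else:
        L = np.arange(n)
    DL = D[np.ix_(L, L)]
    m = len(L)
    if m > 1:
        off = ~np.eye(m, dtype=bool)
        apl = float(DL[off].mean())
        diameter = float(DL[off].max())
        eccentricity = float(DL.max(axis=1).mean())
        closeness = float(((m - 1) / DL.sum(axis=1)).mean())
    else:
        apl = diameter = eccentricity = closeness = 0.0

    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    efficiency = float(inv.sum() / (n * (n - 1)))

    g = _to_igraph(graph)
    bc = float(np.mean(g.betweenness(weights="distance"))) if g.ecount() else 0.0

    return {
        "assortativity": assortativity,
        "average_path_length": apl,
        "betweenness_centrality": bc,
        "closeness_centrality": closeness,
        "eigenvector_centrality": ec,
        "diameter": diameter,
        "hub_score": hub,
        "knn": knn,
        "mean_degree": mean_degree,
        "second_moment_degree": smd,
        "entropy_degree": entropy_degree,
        "transitivity": transitivity,
        "complexity": complexity,
        "k_core": k_core,
        "eccentricity": eccentricity,
        "density": density,
        "efficiency": efficiency,
    }


@dataclass
class CommunityPartition:
    """Node-to-community assignment with contiguous ids.

    Communities are canonically relabeled by (size descending, smallest member
    node index ascending), so community 0 is always "the largest" under the
    deterministic tie-break.
    """

    algorithm: str
    membership: np.ndarray
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.membership = _canonicalize(np.asarray(self.membership, dtype=np.int64))

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1

    def members(self, community_id: int) -> np.ndarray:
        return np.flatnonzero(self.membership == community_id)


def _canonicalize(membership: np.ndarray) -> np.ndarray:
    membership = np.asarray(membership)
    ids = np.unique(membership)
    order = sorted(ids, key=lambda c: (-int((membership == c).sum()),
                                       int(np.flatnonzero(membership == c)[0])))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in membership], dtype=np.int64)


def detect_communities(graph: WeightedGraph, algorithm: str,
                       seed: int = 0) -> CommunityPartition:
    """Run one of the seven community-detection algorithms, seeded.

    Stochastic algorithms (infomap, label propagation, spinglass, multilevel)
    are reproducible at a fixed seed.  Spinglass requires a connected graph;
    on a disconnected one it falls back to per-component detection, recorded
    in the partition notes.
    """
    if algorithm not in COMMUNITY_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {COMMUNITY_ALGORITHMS}")
    g = _to_igraph(graph)
    notes: list[str] = []
    state = random.getstate()
    random.seed(seed)
    try:
        membership = _detect(g, algorithm, graph, notes)
    finally:
        random.setstate(state)
    return CommunityPartition(
        algorithm=algorithm,
        membership=_canonicalize(membership),
        seed=seed,
        notes=notes,
    )


def _detect(g: ig.Graph, algorithm: str, graph: WeightedGraph,
            notes: list[str]) -> list[int]:
    w = "weight" if g.ecount() else None
    if algorithm == "fastgreedy":
        return g.community_fastgreedy(weights=w).as_clustering().membership
    if algorithm == "infomap":
        return g.community_infomap(edge_weights=w).membership
    if algorithm == "leading_eigenvector":
        return g.community_leading_eigenvector(weights=w).membership
    if algorithm == "label_propagation":
        return g.community_label_propagation(weights=w).membership
    if algorithm == "edge_betweenness":
        # edges are removed by betweenness under the distance convention, and
        # the cut of the resulting dendrogram is chosen by maximum modularity
        # under the strength weights (the two roles need different semantics)
        d = "distance" if g.ecount() else None
        dendro = g.community_edge_betweenness(weights=d)
        n_comp = len(g.connected_components())
        best_membership, best_q = None, -np.inf
        for k in range(n_comp, g.vcount() + 1):
            memb = dendro.as_clustering(k).membership
            q = g.modularity(memb, weights="weight" if g.ecount() else None)
            if q > best_q + 1e-12:
                best_q, best_membership = q, memb
        return best_membership
    if algorithm == "multilevel":
        return g.community_multilevel(weights=w).membership
    # spinglass: connected graphs only -> per-component fallback
    if g.is_connected():
        return g.community_spinglass(weights=w).membership
    notes.append("spinglass on disconnected graph: per-component detection")
    membership = np.zeros(g.vcount(), dtype=np.int64)
    offset = 0
    comps = g.connected_components()
    for comp in comps:
        sub = g.induced_subgraph(comp)
        if sub.vcount() == 1 or sub.ecount() == 0:
            local = [0] * sub.vcount()
        else:
            local = sub.community_spinglass(
                weights="weight" if sub.ecount() else None).membership
        for node, c in zip(comp, local):
            membership[node] = offset + c
        offset += max(local) + 1
    return membership.tolist()


def largest_community_apl(graph: WeightedGraph, partition: CommunityPartition) -> float:
    """Average shortest-path length within the largest community.

    The community with the most nodes (tie: canonical id 0, i.e. the one with
    the smallest member index) is induced as a subgraph and the mean distance
    over all ordered pairs within it is returned; a size-1 community gives 0.
    Unreachable pairs inside the community (possible after thresholding) are
    excluded, with a note recorded.
    """
    nodes = partition.members(0)
    if len(nodes) < 2:
        partition.notes.append("largest community has a single node; APL set to 0")
        return 0.0
    sub = WeightedGraph(
        node_names=[graph.node_names[i] for i in nodes],
        W=graph.W[np.ix_(nodes, nodes)],
        config=graph.config,
    )
    D = distance_matrix(sub)
    off = ~np.eye(len(nodes), dtype=bool)
    vals = D[off]
    finite = np.isfinite(vals)
    if not finite.all():
        partition.notes.append(
            "largest community is internally disconnected; APL over reachable pairs"
        )
    if not finite.any():
        return 0.0
    return float(vals[finite].mean())


def community_apl_features(graph: WeightedGraph, seed: int = 0) -> dict[str, float]:
    """The seven community path-length statistics for one graph."""
    out = {}
    for name, algorithm in COMMUNITY_MEASURES.items():
        partition = detect_communities(graph, algorithm, seed=seed)
        out[name] = largest_community_apl(graph, partition)
    return out


def compute_feature_vector(matrix: ConnectivityMatrix, config: GraphConfig | None = None,
                           seed: int = 0) -> dict[str, float]:
    """All 24 graph measures for one connectivity matrix."""
    graph = build_graph(matrix, config)
    out = compute_standard_measures(graph)
    out.update(community_apl_features(graph, seed=seed))
    return out


def assemble_level_c(matrices: list[ConnectivityMatrix],
                     config: GraphConfig | None = None,
                     seed: int = 0) -> FeatureTable:
    """One row of 24 graph measures per (subject, window)."""
    if not matrices:
        raise ValueError("no connectivity matrices given")
    rows = []
    for i, m in enumerate(matrices):
        features = compute_feature_vector(m, config, seed=seed + i)
        for name, value in features.items():
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite measure {name} for subject {m.subject_id} "
                    f"window {m.window_id}"
                )
        rows.append([features[name] for name in ALL_MEASURES])
    return FeatureTable(
        level="C",
        feature_names=list(ALL_MEASURES),
        X=np.array(rows),
        y=np.array([m.class_label for m in matrices]),
        groups=np.array([m.subject_id for m in matrices], dtype=object),
        window_ids=np.array([m.window_id for m in matrices]),
    )


def window_measure_summary(table: FeatureTable,
                           measures: tuple[str, ...] = ("closeness_centrality",
                                                        "assortativity")) -> pd.DataFrame:
    """Per-window median and quartiles of chosen measures (boxplot-ready)."""
    if table.window_ids is None:
        raise ValueError("table must retain window ids")
    for m in measures:
        if m not in table.feature_names:
            raise ValueError(f"measure {m!r} not in table")
    df = table.to_frame()
    records = []
    for m in measures:
        grouped = df.groupby("window")[m]
        for window, vals in grouped:
            records.append({
                "measure": m,
                "window": window,
                "median": float(vals.median()),
                "q1": float(vals.quantile(0.25)),
                "q3": float(vals.quantile(0.75)),
                "n": int(vals.size),
            })
    return pd.DataFrame.from_records(records)
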