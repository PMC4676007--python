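"""Functional graphs from PLV matrices and binary-graph statistics.

A window's symmetric PLV matrix is binarized by keeping edges whose weight
strictly exceeds the 75th percentile of that matrix's off-diagonal weight
distribution (percentile by the (n+1)p order-statistic interpolation).  The
resulting undirected graphs are screened by two admissibility criteria:

* connectivity — graphs in which fewer than 99% of nodes belong to the
  largest connected component are removed;
* ensemble homogeneity — graphs outside the 5th-95th percentile of the
  ensemble's node-count, edge-count or density distributions are removed.

On the retained graphs we compute the mean clustering coefficient C
(functional segregation), the characteristic path length L (functional
integration; disconnected pairs excluded from the mean and counted), and
normalized betweenness centrality.  Graph algorithms are delegated to
networkx and validated elsewhere against brute-force oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .lfpsync import PLVMatrix

logger = logging.getLogger(__name__)

#: default binarization percentile of the off-diagonal weight distribution
THRESHOLD_PERCENTILE = 75.0
#: minimum fraction of nodes in the largest component for admissibility
MIN_CONNECTED_FRACTION = 0.99
#: ensemble outlier fences, percentiles of node/edge/density distributions
OUTLIER_PERCENTILES = (5.0, 95.0)
#: below this ensemble size the outlier filter is a no-op
MIN_ENSEMBLE_FOR_OUTLIERS = 20


class GraphError(ValueError):
    """Graph construction or statistics preconditions violated."""


@dataclass
class FunctionalGraph:
    """Binary undirected graph from one thresholded PLV window."""

    n_nodes: int
    edges: list[tuple[int, int]]
    node_labels: list | None = None
    window: tuple[float, float] | None = None
    threshold_used: float = float("nan")
    degenerate: bool = False  # all weights tied -> empty graph

    def __post_init__(self) -> None:
        for (i, j) in self.edges:
            if i == j:
                raise GraphError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise GraphError("edge references an invalid node")
        self.edges = [tuple(sorted(e)) for e in self.edges]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        possible = self.n_nodes * (self.n_nodes - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass
class GraphStats:
    """Per-graph summary: segregation C, integration L, hubness, admissibility."""

    C: float
    L: float
    betweenness: np.ndarray
    admissible: bool
    n_nodes: int
    n_edges: int
    density: float
    n_disconnected_pairs: int = 0
    window: tuple[float, float] | None = None


@dataclass
class GraphEnsemble:
    """Graphs across windows plus admissibility bookkeeping."""

    graphs: list[FunctionalGraph] = field(default_factory=list)
    removed: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)


# ---------------------------------------------------------------------------
# construction and filtering
# ---------------------------------------------------------------------------


def weight_percentile(weights: np.ndarray, percentile: float) -> float:
    """(n+1)p order-statistic interpolation percentile of the weights."""
    return float(np.percentile(np.asarray(weights, float), percentile, method="weibull"))


def threshold_graph(
    plv: PLVMatrix | np.ndarray, percentile: float = THRESHOLD_PERCENTILE
) -> FunctionalGraph:
    """Binarize one PLV matrix: keep edges strictly above the percentile.

    The threshold is the stated percentile of *this matrix's* upper-triangle
    off-diagonal weights.  An all-tied matrix yields zero edges and is
    flagged degenerate.  ``percentile == 0`` keeps every positive-weight
    pair (complete graph for strictly positive matrices).
    """
    if isinstance(plv, PLVMatrix):
        values, window = plv.values, plv.window
    else:
        values, window = np.asarray(plv, dtype=np.float64), None
    n = values.shape[0]
    if n < 2:
        raise GraphError("need at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    w = values[iu]
    degenerate = bool(np.all(w == w[0]))
    if degenerate:
        thr = float(w[0])
        mask = np.zeros_like(w, dtype=bool)
    elif percentile == 0:
        thr = 0.0
        mask = w > thr
    else:
        thr = weight_percentile(w, percentile)
        mask = w > thr
    edges = [(int(i), int(j)) for i, j, m in zip(iu[0], iu[1], mask) if m]
    return FunctionalGraph(
        n_nodes=n,
        edges=edges,
        window=window,
        threshold_used=thr,
        degenerate=degenerate,
    )


def is_admissible_connectivity(g: FunctionalGraph) -> bool:
    """True iff the largest connected component holds >= 99% of nodes."""
    if g.n_nodes == 0:
        return False
    comps = nx.connected_components(g.to_networkx())
    largest = max(len(c) for c in comps)
    return largest / g.n_nodes >= MIN_CONNECTED_FRACTION


def filter_outlier_graphs(ensemble: GraphEnsemble | list[FunctionalGraph]) -> GraphEnsemble:
    """Drop ensemble outliers in node count, edge count or density.

    A graph is removed if any of the three statistics falls strictly outside
    the [5th, 95th] percentile fences of the ensemble's own distribution.
    Ensembles smaller than 20 graphs are returned unchanged with a warning.
    """
    graphs = ensemble.graphs if isinstance(ensemble, GraphEnsemble) else list(ensemble)
    removed = dict(ensemble.removed) if isinstance(ensemble, GraphEnsemble) else {}
    if len(graphs) < MIN_ENSEMBLE_FOR_OUTLIERS:
        logger.warning(
            "ensemble of %d graphs too small for outlier filtering; skipped",
            len(graphs),
        )
        return GraphEnsemble(graphs=graphs, removed=removed)
    stats = {
        "nodes": np.asarray([g.n_nodes for g in graphs], float),
        "edges": np.asarray([g.n_edges for g in graphs], float),
        "density": np.asarray([g.density for g in graphs], float),
    }
    keep = np.ones(len(graphs), dtype=bool)
    for name, vals in stats.items():
        lo, hi = np.percentile(vals, OUTLIER_PERCENTILES)
        bad = (vals < lo) | (vals > hi)
        removed[f"outlier_{name}"] = removed.get(f"outlier_{name}", 0) + int(
            np.sum(bad & keep)
        )
        keep &= ~bad
    kept = [g for g, k in zip(graphs, keep) if k]
    if len(kept) < len(graphs):
        logger.info("outlier filter removed %d of %d graphs", len(graphs) - len(kept), len(graphs))
    return GraphEnsemble(graphs=kept, removed=removed)


# ---------------------------------------------------------------------------
# binary-graph statistics
# ---------------------------------------------------------------------------


def clustering_coefficient(g: FunctionalGraph) -> tuple[np.ndarray, float]:
    """Per-node binary clustering ``2 t_i / (k_i (k_i - 1))`` and its mean.

    Nodes of degree < 2 contribute 0 and are included in the mean (the
    binary-undirected toolbox convention).
    """
    cc = nx.clustering(g.to_networkx())
    per_node = np.asarray([cc[i] for i in range(g.n_nodes)], dtype=np.float64)
    return per_node, float(per_node.mean()) if g.n_nodes else float("nan")


def characteristic_path_length(
    g: FunctionalGraph, mode: str = "exclude"
) -> tuple[float, int]:
    """Mean shortest-path length over ordered pairs of distinct nodes.

    ``mode="exclude"`` (default) drops infinite (disconnected) distances
    from the mean and reports their count; ``mode="harmonic"`` returns the
    harmonic mean (inverse of mean inverse distance), where disconnected
    pairs contribute zero efficiency.  An edgeless graph has no finite pair
    and yields ``nan``.
    """
    if mode not in ("exclude", "harmonic"):
        raise GraphError(f"unknown mode {mode!r}")
    n = g.n_nodes
    total_pairs = n * (n - 1)
    if total_pairs == 0:
        return float("nan"), 0
    dists = []
    reached = 0
    G = g.to_networkx()
    for _, dd in nx.all_pairs_shortest_path_length(G):
        reached += len(dd) - 1  # exclude self
        for v, d in dd.items():
            if d > 0:
                dists.append(d)
    n_disconnected = total_pairs - reached
    if not dists:
        return float("nan"), n_disconnected
    dists = np.asarray(dists, dtype=np.float64)
    if mode == "exclude":
        L = float(dists.mean())
    else:
        eff = np.sum(1.0 / dists) / total_pairs
        L = float(1.0 / eff) if eff > 0 else float("nan")
    return L, n_disconnected


def betweenness_centrality(g: FunctionalGraph) -> np.ndarray:
    """Brandes betweenness, normalized by (n-1)(n-2)/2, per node."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=True)
    return np.asarray([bc[i] for i in range(g.n_nodes)], dtype=np.float64)


def graph_stats(g: FunctionalGraph, path_mode: str = "exclude") -> GraphStats:
    """All per-graph statistics plus the connectivity admissibility flag."""
    _, C = clustering_coefficient(g)
    L, n_disc = characteristic_path_length(g, mode=path_mode)
    return GraphStats(
        C=C,
        L=L,
        betweenness=betweenness_centrality(g),
        admissible=is_admissible_connectivity(g) and not g.degenerate,
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        density=g.density,
        n_disconnected_pairs=n_disc,
        window=g.window,
    )


def ensemble_stats(
    ensemble: GraphEnsemble | list[FunctionalGraph], path_mode: str = "exclude"
) -> pd.DataFrame:
    """Per-graph C/L samples for an admissibility-screened ensemble.

    Returns one row per graph with columns ``window_start, C, L, admissible,
    n_nodes, n_edges, density``; the C and L columns are the condition-level
    samples consumed by the statistical layer.
    """
    graphs = ensemble.graphs if isinstance(ensemble, GraphEnsemble) else list(ensemble)
    if not graphs:
        raise GraphError("empty ensemble after filtering")
    rows = []
    for g in graphs:
        st = graph_stats(g, path_mode=path_mode)
        rows.append(
            {
                "window_start": g.window[0] if g.window else float("nan"),
                "C": st.C,
                "L": st.L,
                "admissible": st.admissible,
                "n_nodes": st.n_nodes,
                "n_edges": st.n_edges,
                "density": st.density,
                "n_disconnected_pairs": st.n_disconnected_pairs,
            }
        )
    return pd.DataFrame(rows)


def export_edge_list(g: FunctionalGraph) -> str:
    """Plain-text edge list (one ``i<TAB>j`` per line, node labels if set)."""
    lab = g.node_labels if g.node_labels is not None else list(range(g.n_nodes))
    return "\n".join(f"{lab[i]}\t{lab[j]}" for i, j in g.edges)


def export_graphml(g: FunctionalGraph, path) -> None:
    """Write the graph as GraphML (node labels as a ``label`` attribute)."""
    G = g.to_networkx()
    if g.node_labels is not None:
        nx.set_node_attributes(
            G, {i: str(g.node_labels[i]) for i in range(g.n_nodes)}, "label"
        )
    nx.write_graphml(G, path)
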