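"""Compilation and topology analysis of the multi-source interaction network.

The network integrates protein-protein interactions from several evidence
sources (yeast two-hybrid screens, manually curated literature, interactome
databases, neighborhood extension) into one simple undirected graph whose
edges retain per-source provenance and whose nodes carry a class label
(core clock / regulatory / neighborhood).

Topology statistics follow the conventions common for interactome papers:
mean shortest path over unordered reachable pairs of the largest connected
component, per-node clustering C_n = 2 e_n / (k_n (k_n - 1)), the
topological coefficient T_n = mean over nodes m sharing at least one
neighbor with n of |shared neighbors(n, m)| / k_n, and a power-law slope
from a least-squares line on log(count) vs log(degree).  Degree-preserving
double-edge-swap rewiring provides the null model for clustering and
related quantities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "TopologySummary",
    "compile_network",
    "topology_summary",
    "rewire_preserving_degrees",
    "hub_set",
    "randomized_clustering",
]

EDGE_SOURCES = ("Y2H", "MAN", "UniHI", "EXT")
NODE_CLASSES = ("core", "regulatory", "neighborhood")


class InteractionNetwork:
    """Simple undirected PPI graph with node classes and edge provenance.

    Wraps a :class:`networkx.Graph`; node attribute ``node_class`` is one of
    ``core | regulatory | neighborhood``, edge attribute ``sources`` is the
    (nonempty) set of evidence labels for that interaction.
    """

    def __init__(self, graph: nx.Graph):
        if nx.number_of_selfloops(graph):
            raise ValueError("interaction network must not contain self-loops")
        self.graph = graph
        self.merge_stats: dict[str, int] = {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        node_classes: pd.DataFrame | dict | None = None,
    ) -> "InteractionNetwork":
        """Build from an edge table with columns id_a, id_b, source.

        Duplicate rows and reversed duplicates are collapsed (source sets
        merged); self-loops are dropped.  Endpoints without a class entry
        are admitted as ``neighborhood`` with a warning.
        """
        g = nx.Graph()
        n_self = 0
        n_dup = 0
        for row in edges.itertuples(index=False):
            a, b = str(row.id_a), str(row.id_b)
            source = getattr(row, "source", "EXT")
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                g.edges[a, b]["sources"].add(source)
            else:
                g.add_edge(a, b, sources={source})

        classes: dict[str, str] = {}
        if node_classes is not None:
            if isinstance(node_classes, pd.DataFrame):
                classes = dict(
                    zip(node_classes.iloc[:, 0].astype(str), node_classes.iloc[:, 1].astype(str))
                )
            else:
                classes = {str(k): str(v) for k, v in node_classes.items()}
        n_unknown = 0
        for n in g.nodes:
            cls_label = classes.get(n)
            if cls_label not in NODE_CLASSES:
                if node_classes is not None and cls_label is not None:
                    warnings.warn(f"unknown node class {cls_label!r} for {n}; using 'neighborhood'")
                n_unknown += cls_label is None and node_classes is not None
                cls_label = "neighborhood" if cls_label not in NODE_CLASSES else cls_label
            g.nodes[n]["node_class"] = cls_label or "neighborhood"
        net = cls(g)
        net.merge_stats = {
            "self_loops_dropped": n_self,
            "duplicates_collapsed": n_dup,
            "nodes_without_class": int(n_unknown),
        }
        return net

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def degree(self) -> pd.Series:
        d = dict(self.graph.degree())
        return pd.Series(d, name="degree").sort_index()

    def neighbors(self, node: str) -> list[str]:
        return list(self.graph.neighbors(node))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"id_a": a, "id_b": b, "source": "|".join(sorted(d.get("sources", {"EXT"})))}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "source"])

    def copy(self) -> "InteractionNetwork":
        net = InteractionNetwork(self.graph.copy())
        net.merge_stats = dict(self.merge_stats)
        return net


def compile_network(
    edge_tables: pd.DataFrame | list[pd.DataFrame],
    node_classes: pd.DataFrame | dict | None = None,
) -> InteractionNetwork:
    """Merge one or more source-labelled edge tables into one network.

    Each table needs columns ``id_a, id_b, source``.  Edges shared between
    sources end up as a single undirected edge whose ``sources`` set names
    every contributing evidence type; merge statistics (novel vs reproduced
    edges per source, dropped self-loops, collapsed duplicates) are logged
    and stored on the returned network.
    """
    if isinstance(edge_tables, pd.DataFrame):
        edge_tables = [edge_tables]
    if not edge_tables:
        raise ValueError("at least one edge table required")
    combined = pd.concat(edge_tables, ignore_index=True)
    net = InteractionNetwork.from_edges(combined, node_classes)

    per_source: dict[str, int] = {}
    multi = 0
    for _, _, d in net.graph.edges(data=True):
        srcs = d["sources"]
        if len(srcs) > 1:
            multi += 1
        for s in srcs:
            per_source[s] = per_source.get(s, 0) + 1
    net.merge_stats.update(
        {"edges_total": net.n_edges, "edges_multi_source": multi},
        )
    net.merge_stats.update({f"edges_{s}": c for s, c in sorted(per_source.items())})
    logger.info("compiled network: %s", net.merge_stats)
    return net


@dataclass
class TopologySummary:
    """Topology statistics of an interaction network."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_shortest_path: float
    largest_component_size: int
    clustering_coefficient: float
    degree_frequency: pd.DataFrame
    clustering_by_degree: pd.DataFrame
    topological_coefficients: pd.DataFrame
    powerlaw_slope: float
    notes: list[str] = field(default_factory=list)


def _topological_coefficient(g: nx.Graph, n) -> float:
    """T_n = mean over nodes m sharing >=1 neighbor with n of J(n,m)/k_n."""
    k_n = g.degree(n)
    if k_n == 0:
        return float("nan")
    nbrs = set(g.neighbors(n))
    partners_of_partners: set = set()
    for v in nbrs:
        partners_of_partners.update(g.neighbors(v))
    partners_of_partners.discard(n)
    shared = [len(nbrs & set(g.neighbors(m))) for m in partners_of_partners]
    shared = [s for s in shared if s > 0]
    if not shared:
        return float("nan")
    return float(np.mean(shared) / k_n)


def topology_summary(net: InteractionNetwork) -> TopologySummary:
    """Topology statistics per the interactome-analysis conventions above.

    Shortest paths are averaged over unordered reachable pairs within the
    largest connected component (noted when the graph is disconnected);
    nodes of degree < 2 contribute clustering 0 to the global mean but are
    excluded from the degree-averaged clustering curve.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    notes: list[str] = []
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    if len(components) > 1:
        notes.append(
            f"graph has {len(components)} components; path statistics use the "
            f"largest ({giant.number_of_nodes()} nodes)"
        )
    if giant.number_of_edges() > 0:
        mean_sp = nx.average_shortest_path_length(giant)
    else:
        mean_sp = float("nan")
        notes.append("largest component has no edges; mean shortest path undefined")

    degrees = pd.Series(dict(g.degree()), name="degree")
    clustering = pd.Series(nx.clustering(g), name="clustering")  # degree<2 -> 0

    freq = degrees.value_counts().sort_index()
    degree_frequency = pd.DataFrame({"degree": freq.index, "count": freq.to_numpy()})

    cbd = (
        pd.DataFrame({"degree": degrees, "clustering": clustering})
        .query("degree >= 2")
        .groupby("degree", as_index=False)["clustering"]
        .mean()
    )

    tc = pd.DataFrame(
        {
            "node": list(g.nodes),
            "degree": [g.degree(n) for n in g.nodes],
            "topological_coefficient": [_topological_coefficient(g, n) for n in g.nodes],
        }
    )

    pos = degree_frequency.query("degree > 0")
    if len(pos) >= 2:
        slope = float(
            stats.linregress(np.log10(pos["degree"]), np.log10(pos["count"])).slope
        )
    else:
        slope = float("nan")
        notes.append("fewer than two distinct degrees; power-law slope undefined")

    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        mean_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        mean_shortest_path=float(mean_sp),
        largest_component_size=giant.number_of_nodes(),
        clustering_coefficient=float(clustering.mean()),
        degree_frequency=degree_frequency,
        clustering_by_degree=cbd,
        topological_coefficients=tc,
        powerlaw_slope=slope,
        notes=notes,
    )


def rewire_preserving_degrees(
    net: InteractionNetwork,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> InteractionNetwork:
    """Degree-preserving randomization by double edge swaps.

    Each swap replaces edges (a,b),(c,d) by (a,d),(c,b) when that creates
    neither self-loops nor multi-edges, so the degree sequence is preserved
    exactly.  Default swap count is 10 * |E|.  Graphs admitting no legal
    swap (e.g. a triangle) are returned unchanged with a warning.
    """
    g = net.graph.copy()
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    out = InteractionNetwork.__new__(InteractionNetwork)
    out.graph = g
    out.merge_stats = {}
    if g.number_of_edges() < 2 or n_swaps == 0:
        warnings.warn("graph admits no degree-preserving swap; returned unchanged")
        return out
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=max(100 * n_swaps, 1000), seed=seed)
    except nx.NetworkXError as exc:  # includes exhausted tries / too-small graphs
        warnings.warn(f"degree-preserving rewiring incomplete ({exc}); graph may be unchanged")
    return out


def hub_set(net: InteractionNetwork, threshold: int, strict: bool = False) -> list[str]:
    """Nodes whose degree reaches ``threshold`` (``>`` when strict)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    deg = net.degree()
    mask = deg > threshold if strict else deg >= threshold
    return sorted(deg.index[mask])


def randomized_clustering(
    net: InteractionNetwork,
    n_replicates: int = 100,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Global clustering coefficients of a degree-preserving null ensemble."""
    rng = np.random.default_rng(seed)
    vals = np.empty(n_replicates)
    for i in range(n_replicates):
        rewired = rewire_preserving_degrees(net, n_swaps, seed=int(rng.integers(2**31 - 1)))
        vals[i] = float(np.mean(list(nx.clustering(rewired.graph).values())))
    return vals
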