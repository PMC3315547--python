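"""Direct-interaction networks and their connectivity statistics.

A *direct-interaction* network keeps only the edges of a typed interaction
database whose **both** endpoints lie in a supplied root list of
differential entities (no intermediate nodes are added).  Connectivity is
summarised the way signaling-network comparisons report it: nodes with at
least one edge, the largest connected component and its share of nodes,
edge counts, mean degree inside the largest component, the top hub nodes,
and the mixture of edge types — computed per root set and for unions of
root sets, so that the gain from integrating datasets is measurable.

Components and degrees are computed on the undirected simple graph
(multi-type parallel edges collapsed); ``n_edges`` counts typed edges, so
an A–B pair connected both transcriptionally and physically contributes 2
edges but degree 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionDatabase",
    "NetworkStats",
    "build_direct_network",
    "network_stats",
    "edge_type_fractions",
    "compare_integration",
]

KNOWN_TYPES = ("transcriptional", "protein-interaction", "phosphorylation", "other")


@dataclass(frozen=True)
class InteractionDatabase:
    """Typed interaction table: unordered pairs with one or more edge types.

    Built from (source, type, target) rows; self-loops are rejected and
    duplicate rows (same unordered pair and type) collapsed.
    """

    edges: pd.DataFrame  # columns: source, type, target (canonical order)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionDatabase":
        df = df[["source", "type", "target"]].copy()
        if (df["source"].astype(str).str.len() == 0).any() or (
            df["target"].astype(str).str.len() == 0
        ).any():
            raise ValueError("interaction symbols must be non-empty")
        if (df["source"] == df["target"]).any():
            raise ValueError("self-loops are not allowed in the interaction database")
        lo = df[["source", "target"]].min(axis=1)
        hi = df[["source", "target"]].max(axis=1)
        df = pd.DataFrame({"source": lo, "type": df["type"], "target": hi})
        df = df.drop_duplicates().sort_values(["source", "target", "type"])
        return cls(edges=df.reset_index(drop=True))

    @property
    def symbols(self) -> set[str]:
        return set(self.edges["source"]) | set(self.edges["target"])


def build_direct_network(roots: set[str], db: InteractionDatabase) -> nx.Graph:
    """Induced typed subgraph on the root set.

    Nodes are exactly the roots; an edge appears iff both endpoints are
    roots.  The simple graph stores the sorted tuple of types on each
    edge attribute ``types``, so parallel same-type duplicates collapse
    while distinct types are all kept.
    """
    if not roots:
        raise ValueError("root set must be non-empty")
    g = nx.Graph()
    g.add_nodes_from(sorted(roots))
    sub = db.edges[db.edges["source"].isin(roots) & db.edges["target"].isin(roots)]
    for (u, v), grp in sub.groupby(["source", "target"], sort=True):
        g.add_edge(u, v, types=tuple(sorted(grp["type"].unique())))
    return g


@dataclass(frozen=True)
class NetworkStats:
    """Connectivity summary of one direct-interaction network."""

    total_nodes_with_edges: int
    largest_cluster_size: int
    pct_in_largest: float
    n_edges: int
    mean_degree_largest: float
    hubs: tuple[tuple[str, int], ...]
    edge_type_fractions: dict[str, float]

    def to_dict(self) -> dict:
        d = {
            "total_nodes_with_edges": self.total_nodes_with_edges,
            "largest_cluster_size": self.largest_cluster_size,
            "pct_in_largest": self.pct_in_largest,
            "n_edges": self.n_edges,
            "mean_degree_largest": self.mean_degree_largest,
        }
        for i, (sym, deg) in enumerate(self.hubs, start=1):
            d[f"hub{i}"] = f"{sym} ({deg})"
        for t, f in sorted(self.edge_type_fractions.items()):
            d[f"frac_{t}"] = f
        return d


def _typed_edge_count(g: nx.Graph, nodes=None) -> int:
    if nodes is None:
        return sum(len(d["types"]) for _, _, d in g.edges(data=True))
    nodes = set(nodes)
    return sum(
        len(d["types"]) for u, v, d in g.edges(data=True) if u in nodes and v in nodes
    )


def network_stats(g: nx.Graph, top_k: int = 2) -> NetworkStats:
    """Connectivity statistics of a direct-interaction network.

    Treats the graph as undirected and simple for components and degree;
    hubs are the ``top_k`` highest-degree nodes, ties broken
    lexicographically by symbol.  ``mean_degree_largest`` is
    2 x (simple edges inside the largest component) / its node count.
    """
    active = [n for n, d in g.degree() if d >= 1]
    total = len(active)
    if total == 0:
        return NetworkStats(
            0, 0, 0.0, 0, 0.0, tuple(), edge_type_fractions(g, warn_empty=False)
        )
    comps = sorted(nx.connected_components(g.subgraph(active)), key=len, reverse=True)
    largest = comps[0]
    simple_in_largest = g.subgraph(largest).number_of_edges()
    hubs = sorted(((n, g.degree(n)) for n in active), key=lambda x: (-x[1], x[0]))[:top_k]
    return NetworkStats(
        total_nodes_with_edges=total,
        largest_cluster_size=len(largest),
        pct_in_largest=100.0 * len(largest) / total,
        n_edges=_typed_edge_count(g),
        mean_degree_largest=2.0 * simple_in_largest / len(largest),
        hubs=tuple((n, int(d)) for n, d in hubs),
        edge_type_fractions=edge_type_fractions(g, warn_empty=False),
    )


def edge_type_fractions(g: nx.Graph, warn_empty: bool = True) -> dict[str, float]:
    """Share of typed edges per interaction type (sums to 1 when edges exist)."""
    counts: dict[str, int] = {}
    for _, _, d in g.edges(data=True):
        for t in d["types"]:
            counts[t] = counts.get(t, 0) + 1
    total = sum(counts.values())
    if total == 0:
        if warn_empty:
            import warnings

            warnings.warn("network has no edges; type fractions are all zero", stacklevel=2)
        return {}
    return {t: c / total for t, c in sorted(counts.items())}


def compare_integration(
    root_sets: dict[str, set[str]],
    db: InteractionDatabase,
    unions: list[tuple[str, ...]] | None = None,
    top_k: int = 2,
) -> pd.DataFrame:
    """Connectivity table across individual root sets and their unions.

    One row per named root set and one per requested union (named
    ``a+b+...``), all against the same database — the quantitative form of
    asking how much integrating datasets improves network connectivity.
    """
    if len(root_sets) < 2:
        raise ValueError("need at least 2 named root sets to compare")
    if unions is None:
        unions = [tuple(root_sets)]
    rows = []
    order = list(root_sets)
    for name in order:
        g = build_direct_network(root_sets[name], db)
        rows.append({"dataset": name, **network_stats(g, top_k).to_dict()})
    for combo in unions:
        missing = [c for c in combo if c not in root_sets]
        if missing:
            raise ValueError(f"unknown dataset name(s) in union: {missing}")
        merged: set[str] = set()
        for c in combo:
            merged |= root_sets[c]
        g = build_direct_network(merged, db)
        rows.append({"dataset": "+".join(combo), **network_stats(g, top_k).to_dict()})
    return pd.DataFrame(rows)
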