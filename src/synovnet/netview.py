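"""Differential network characterization.

Given the two group graphs, edges are partitioned into a shared set and
per-group unique sets; centralities (degree, unnormalized betweenness with
fractional geodesic counting) are computed on both the full graphs and the
unique-edge subgraphs (the views where group differences live); community
structure on a graph is the most frequent partition over repeated Louvain
runs, with communities of three or more members labeled alphabetically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: protein classes rolled up into the extracellular-matrix category
ECM_CLASSES = frozenset(
    {
        "extracellular matrix structural protein",
        "extracellular matrix protein",
        "extracellular matrix glycoprotein",
    }
)


@dataclass
class DifferentialNetwork:
    """Shared/unique edge partition of two group graphs."""

    groups: tuple[str, str]
    full: dict[str, nx.Graph]
    shared_edges: set[frozenset]
    unique_edges: dict[str, set[frozenset]]
    unique_subgraph: dict[str, nx.Graph]

    def summary(self) -> dict[str, int]:
        out = {
            "shared_edges": len(self.shared_edges),
            "shared_nodes": len({n for e in self.shared_edges for n in e}),
        }
        for g in self.groups:
            out[f"unique_edges_{g}"] = len(self.unique_edges[g])
            out[f"unique_nodes_{g}"] = self.unique_subgraph[g].number_of_nodes()
        return out


def partition_edges(
    G_a: nx.Graph, G_b: nx.Graph, names: tuple[str, str] = ("healthy", "mild")
) -> DifferentialNetwork:
    """Classify every edge as shared or unique to one group.

    The node universe is the union; unique-edge subgraphs keep only nodes
    incident to at least one unique edge (no isolated nodes).
    """
    graphs = dict(zip(names, (G_a, G_b)))
    edges = {g: {frozenset(e) for e in graphs[g].edges} for g in names}
    shared = edges[names[0]] & edges[names[1]]
    unique = {g: edges[g] - shared for g in names}
    subs = {}
    for g in names:
        H = nx.Graph()
        H.add_edges_from(tuple(e) for e in unique[g])
        subs[g] = H
    full = {}
    universe = set(G_a.nodes) | set(G_b.nodes)
    for g in names:
        H = graphs[g].copy()
        H.add_nodes_from(universe - set(H.nodes))
        full[g] = H
    return DifferentialNetwork(
        groups=tuple(names),
        full=full,
        shared_edges=shared,
        unique_edges=unique,
        unique_subgraph=subs,
    )


def degree(G: nx.Graph) -> pd.Series:
    """Integer edge count per node."""
    return pd.Series(dict(G.degree), dtype=int).sort_index()


def betweenness(G: nx.Graph) -> pd.Series:
    """Unnormalized betweenness with fractional geodesic counting.

    Endpoints excluded; each unordered pair contributes the fraction of its
    geodesics passing through the node (Brandes accumulation); disconnected
    pairs contribute nothing.
    """
    return pd.Series(nx.betweenness_centrality(G, normalized=False)).sort_index()


def centrality_table(net: DifferentialNetwork) -> pd.DataFrame:
    """Degree and betweenness per node on the full and unique-edge views."""
    rows = []
    for g in net.groups:
        for view, graph in (("full", net.full[g]), ("unique", net.unique_subgraph[g])):
            deg = degree(graph) if graph.number_of_nodes() else pd.Series(dtype=int)
            btw = betweenness(graph) if graph.number_of_nodes() else pd.Series(dtype=float)
            for node in graph.nodes:
                rows.append(
                    dict(group=g, view=view, node=node,
                         degree=int(deg.get(node, 0)),
                         betweenness=float(btw.get(node, 0.0)))
                )
    return pd.DataFrame(rows, columns=["group", "view", "node", "degree", "betweenness"])


@dataclass
class CommunityPartition:
    """Consensus community structure of one graph."""

    membership: dict
    modularity: float
    run_frequency: int
    n_runs: int
    labels: dict[str, frozenset] = field(default_factory=dict)

    @property
    def communities(self) -> list[frozenset]:
        out: dict = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [frozenset(s) for s in out.values()]

    def labeled(self) -> dict[str, frozenset]:
        return dict(self.labels)


def _canonical(partition: Iterable[set]) -> frozenset:
    return frozenset(frozenset(c) for c in partition)


def louvain_consensus(
    G: nx.Graph, runs: int = 20, seed: int = 0
) -> CommunityPartition:
    """Most frequent Louvain partition over ``runs`` seeded runs.

    Partition identity is label-free (compared as sets of node-sets). Ties
    break by higher modularity, then by a canonical ordering of the
    partitions. Communities of size ≥ 3 are labeled A, B, C… in order of
    decreasing size, then by smallest member.
    """
    if runs < 1:
        raise ValueError("runs must be ≥ 1")
    if G.number_of_nodes() == 0:
        return CommunityPartition({}, 0.0, runs, runs)
    seeds = np.random.SeedSequence(seed).generate_state(runs)
    results = []
    for s in seeds:
        comms = nx.community.louvain_communities(G, seed=int(s % (2**31)))
        results.append(_canonical(comms))
    counts = Counter(results)
    top = max(counts.values())
    candidates = [p for p, c in counts.items() if c == top]
    scored = sorted(
        candidates,
        key=lambda p: (
            -nx.community.modularity(G, [set(c) for c in p]),
            sorted(sorted(str(n) for n in c) for c in p),
        ),
    )
    best = scored[0]
    comms = [set(c) for c in best]
    mod = float(nx.community.modularity(G, comms))
    membership = {n: i for i, c in enumerate(comms) for n in c}

    big = [c for c in comms if len(c) >= 3]
    big.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    labels = {}
    for i, c in enumerate(big):
        letter = chr(ord("A") + i) if i < 26 else f"A{i}"
        labels[letter] = frozenset(c)
    return CommunityPartition(membership, mod, top, runs, labels)


def annotate_nodes(
    nodes: Sequence[str], class_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Left-join protein classes onto nodes; roll up ECM classes.

    ``class_table`` needs columns ``gene`` and ``protein_class``; duplicate
    gene keys are an error. Returns the annotated node table and per-class
    counts (including an ``ecm`` rollup flag).
    """
    if class_table.empty:
        annotated = pd.DataFrame(
            {"node": list(nodes), "protein_class": pd.NA, "ecm": False}
        )
        return annotated, pd.DataFrame(columns=["protein_class", "count"])
    if class_table["gene"].duplicated().any():
        dupes = class_table.loc[class_table["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate keys in class table: {dupes[:10]}")
    lut = class_table.set_index("gene")["protein_class"]
    annotated = pd.DataFrame({"node": list(nodes)})
    annotated["protein_class"] = [lut.get(n, pd.NA) for n in nodes]
    annotated["ecm"] = [
        (str(c).lower() in ECM_CLASSES) if pd.notna(c) else False
        for c in annotated["protein_class"]
    ]
    counts = (
        annotated.dropna(subset=["protein_class"])
        .groupby("protein_class", observed=True)
        .size()
        .reset_index(name="count")
    )
    return annotated, counts
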