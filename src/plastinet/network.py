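"""Gene networks: fan-out filtering, intersection, hub ranking, export.

A :class:`GeneNetwork` is an undirected weighted graph over annotated genes
(probe ID is the node key; accession and symbol are display attributes),
tagged with the method that produced it (``glasso`` or ``pearson``) and the
parameters used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from plastinet.io import GeneAnnotation


@dataclass
class GeneNetwork:
    graph: nx.Graph
    method: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loop on node {loops[0][0]!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Edges as sorted (a, b) tuples with a < b, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def degree(self, node: str) -> int:
        return self.graph.degree[node]


def network_from_edges(edges: list[tuple[str, str, float]], method: str,
                       annotation: GeneAnnotation | None = None,
                       provenance: dict | None = None,
                       nodes: list[str] | None = None) -> GeneNetwork:
    """Build a network from (a, b, weight) triples.

    Symmetric duplicates collapse (the last weight wins); self-pairs are
    rejected. ``nodes`` adds isolated nodes beyond the edge endpoints; by
    default the node set is exactly the genes engaged in at least one link.
    """
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-pair on gene {a!r}")
        g.add_edge(a, b, weight=float(w))
    for n in g.nodes:
        g.nodes[n]["symbol"] = annotation.symbol(n) if annotation else n
        g.nodes[n]["accession"] = annotation.accession(n) if annotation else ""
    return GeneNetwork(g, method, dict(provenance or {}))


def collapse_directed_edges(table: pd.DataFrame) -> list[tuple[str, str, float]]:
    """Collapse a doubly-listed (directed) edge table to undirected links.

    Tables that list every link in both directions (96 rows for 48 links)
    reduce to one row per unordered pair; conflicting duplicate weights are
    rejected.
    """
    seen: dict[frozenset, float] = {}
    cols = list(table.columns)
    for _, row in table.iterrows():
        a, b = str(row[cols[0]]), str(row[cols[1]])
        w = float(row[cols[2]]) if len(cols) > 2 else 1.0
        key = frozenset((a, b))
        if len(key) == 1:
            raise ValueError(f"self-pair on gene {a!r}")
        if key in seen and abs(seen[key] - w) > 1e-12 * max(1.0, abs(w)):
            raise ValueError(f"conflicting weights for pair {sorted(key)}")
        seen[key] = w
    return [(min(k), max(k), w) for k, w in sorted(
        seen.items(), key=lambda kv: tuple(sorted(kv[0])))]


def richness_filter(net: GeneNetwork) -> GeneNetwork:
    """Keep genes with a fan-out above one, or linked to such a gene.

    A single pass over the input network's degrees: node v survives iff
    degree(v) > 1 or some neighbor u has degree(u) > 1 — degrees measured on
    the input, not recomputed iteratively, so degree-1 leaves that hang off
    a hub are retained. Edges survive iff both endpoints do; nodes left
    isolated are dropped.
    """
    g = net.graph
    deg = dict(g.degree)
    keep = {v for v in g.nodes
            if deg[v] > 1 or any(deg[u] > 1 for u in g.neighbors(v))}
    sub = g.subgraph(keep).copy()
    sub.remove_nodes_from([v for v in list(sub.nodes) if sub.degree[v] == 0])
    prov = dict(net.provenance)
    prov["richness_filtered"] = True
    return GeneNetwork(sub, net.method, prov)


def intersect_nodes(a: GeneNetwork, b: GeneNetwork) -> set[str]:
    """Genes present in both networks (probe-ID intersection; edges ignored)."""
    return set(a.graph.nodes) & set(b.graph.nodes)


def hub_rank(net: GeneNetwork) -> list[tuple[str, int]]:
    """Nodes by degree descending, ties by probe ID; the head is the hub."""
    return sorted(((n, net.graph.degree[n]) for n in net.graph.nodes),
                  key=lambda nd: (-nd[1], nd[0]))


def export_network(net: GeneNetwork, path: str | Path,
                   fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV or as GraphML.

    Both formats are deterministic: edges are written in sorted order with
    symbol labels and signed weights.
    """
    path = Path(path)
    if fmt == "tsv":
        rows = []
        for a, b in net.edge_pairs():
            rows.append({
                "probe_a": a, "probe_b": b,
                "weight": net.graph.edges[a, b].get("weight", 1.0),
                "method": net.method,
            })
        pd.DataFrame(rows, columns=["probe_a", "probe_b", "weight",
                                    "method"]).to_csv(path, sep="\t",
                                                      index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        g.graph["method"] = net.method
        for n in net.nodes():
            g.add_node(n, symbol=net.graph.nodes[n].get("symbol", n),
                       accession=net.graph.nodes[n].get("accession", ""))
        for a, b in net.edge_pairs():
            g.add_edge(a, b, weight=float(net.graph.edges[a, b].get(
                "weight", 1.0)))
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_network(path: str | Path, fmt: str = "tsv") -> GeneNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"probe_a": str,
                                                "probe_b": str})
        method = str(df["method"].iloc[0]) if len(df) else "unknown"
        edges = [(r.probe_a, r.probe_b, float(r.weight))
                 for r in df.itertuples()]
        return network_from_edges(edges, method)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        method = g.graph.get("method", "unknown")
        edges = [(str(a), str(b), float(d.get("weight", 1.0)))
                 for a, b, d in g.edges(data=True)]
        net = network_from_edges(edges, method, nodes=[str(n) for n in g.nodes])
        for n, d in g.nodes(data=True):
            net.graph.nodes[str(n)].update(
                {"symbol": d.get("symbol", str(n)),
                 "accession": d.get("accession", "")})
        return net
    raise ValueError(f"unsupported format {fmt!r}")


def hub_report(net: GeneNetwork) -> list[dict]:
    """JSON-ready hub ranking (probe_id, symbol, degree, rank)."""
    return [{
        "probe_id": n,
        "symbol": net.graph.nodes[n].get("symbol", n),
        "degree": d,
        "rank": i + 1,
    } for i, (n, d) in enumerate(hub_rank(net))]
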