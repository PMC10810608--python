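"""CDR3 similarity networks for clonal-expansion detection.

Nodes are unique CDR3 amino-acid strings (with abundance counts); an edge
joins two nodes exactly when their Levenshtein distance is 1. Connected
components of size >= ``min_cluster_size`` are flagged as candidate clonal
expansions. Construction uses deletion-neighborhood hashing: every string
is keyed by itself and each of its single-deletion variants, so any pair at
distance 1 shares at least one key; candidate pairs from shared buckets are
then verified with an exact bounded edit-distance check. Runtime is
near-linear in total neighborhood size rather than quadratic in node count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import networkx as nx
import pandas as pd


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion)."""
    if a == b:
        return 0
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def _within_distance_one(a: str, b: str) -> bool:
    if a == b:
        return False
    d = edlib.align(a, b, mode="NW", task="distance", k=1)["editDistance"]
    return d == 1


def _hamming_one(a: str, b: str) -> bool:
    return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1


@dataclass
class SimilarityNetwork:
    """Levenshtein-1 graph over unique CDR3 amino-acid strings."""

    nodes: list[str]
    counts: dict[str, int]
    edges: set[tuple[str, str]]           # lexicographically ordered pairs
    components: dict[str, int]            # node -> component id
    min_cluster_size: int

    @property
    def expanded_components(self) -> set[int]:
        sizes: dict[int, int] = defaultdict(int)
        for node, comp in self.components.items():
            sizes[comp] += 1
        return {c for c, n in sizes.items() if n >= self.min_cluster_size}

    @property
    def n_components(self) -> int:
        return len(set(self.components.values()))

    def component_mass(self) -> dict[int, int]:
        """Total abundance (read/record counts) per component."""
        mass: dict[int, int] = defaultdict(int)
        for node, comp in self.components.items():
            mass[comp] += self.counts[node]
        return dict(mass)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node,
                count=self.counts[node],
                component=self.components[node],
                expanded=self.components[node] in self.expanded_components,
            )
        g.add_edges_from(self.edges)
        return g


def build_network(
    cdr3_counts: Mapping[str, int] | Iterable[tuple[str, int]],
    min_cluster_size: int = 3,
    metric: str = "levenshtein",
) -> SimilarityNetwork:
    """Build the similarity network from deduplicated CDR3 counts.

    ``metric`` is ``"levenshtein"`` (default; includes length +/- 1 indels)
    or ``"hamming"`` (same-length substitutions only). Duplicate input
    strings raise a ``ValueError``.
    """
    if metric not in ("levenshtein", "hamming"):
        raise ValueError(f"unknown metric {metric!r}")
    pairs = list(cdr3_counts.items()) if isinstance(cdr3_counts, Mapping) else list(cdr3_counts)
    seqs = [s for s, _ in pairs]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate CDR3 strings in input; deduplicate first")
    counts = {s: int(c) for s, c in pairs}
    nodes = sorted(seqs)

    buckets: dict[str, list[str]] = defaultdict(list)
    for s in nodes:
        buckets[s].append(s)
        for i in range(len(s)):
            buckets[s[:i] + s[i + 1 :]].append(s)

    verify = _within_distance_one if metric == "levenshtein" else _hamming_one
    edges: set[tuple[str, str]] = set()
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        uniq = sorted(set(bucket))
        for i in range(len(uniq)):
            for k in range(i + 1, len(uniq)):
                pair = (uniq[i], uniq[k])
                if pair not in edges and verify(*pair):
                    edges.add(pair)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    components: dict[str, int] = {}
    for comp_id, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        for node in comp:
            components[node] = comp_id
    return SimilarityNetwork(
        nodes=nodes,
        counts=counts,
        edges=edges,
        components=components,
        min_cluster_size=min_cluster_size,
    )


def export_network(
    net: SimilarityNetwork,
    edge_path: str | Path,
    node_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Write edge-list and node-attribute TSVs (optionally GraphML)."""
    edges = pd.DataFrame(sorted(net.edges), columns=["source", "target"])
    edges.to_csv(edge_path, sep="\t", index=False)
    expanded = net.expanded_components
    nodes = pd.DataFrame(
        {
            "cdr3_aa": net.nodes,
            "count": [net.counts[n] for n in net.nodes],
            "component": [net.components[n] for n in net.nodes],
            "expanded": [net.components[n] in expanded for n in net.nodes],
        }
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.to_networkx(), str(graphml_path))


def load_network(
    edge_path: str | Path, node_path: str | Path, min_cluster_size: int = 3
) -> SimilarityNetwork:
    """Reconstruct a network from exported TSVs (round-trip inverse)."""
    nodes_df = pd.read_csv(node_path, sep="\t", dtype={"cdr3_aa": str})
    edges_df = pd.read_csv(edge_path, sep="\t", dtype=str)
    edges = {
        tuple(sorted((r.source, r.target))) for r in edges_df.itertuples()
    }
    return SimilarityNetwork(
        nodes=list(nodes_df["cdr3_aa"]),
        counts=dict(zip(nodes_df["cdr3_aa"], nodes_df["count"].astype(int))),
        edges=edges,
        components=dict(
            zip(nodes_df["cdr3_aa"], nodes_df["component"].astype(int))
        ),
        min_cluster_size=min_cluster_size,
    )
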