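"""Typed regulatory-network container shared by the co-expression and motif
stages, with GraphML / edge-TSV export."""

from __future__ import annotations

import dataclasses
from typing import Optional

import networkx as nx
import pandas as pd

__all__ = ["RegulatoryNetwork"]

EDGE_TYPES = ("coexpression", "motif", "ppi")


@dataclasses.dataclass
class RegulatoryNetwork:
    """Nodes (genes/TFs) plus typed edges.

    ``nodes``: DataFrame indexed by gene ID; columns may include ``is_tf``,
    ``label`` (NSG/NSTF/MSTF/...), ``log2fc``, ``max_cell_type``.
    ``edges``: DataFrame with ``source``, ``target``, ``edge_type`` and an
    optional ``r`` (Pearson r for coexpression edges).  Motif edges are
    directed TF -> target; coexpression and PPI edges are undirected and are
    stored once with source < target.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.edges):
            bad = set(self.edges["edge_type"]) - set(EDGE_TYPES)
            if bad:
                raise ValueError(f"unknown edge types: {sorted(bad)}")
            ppi = self.edges[self.edges["edge_type"] == "ppi"]
            if (ppi["source"] == ppi["target"]).any():
                raise ValueError("self PPI edges are not allowed")

    def edge_view(self, edge_type: str) -> pd.DataFrame:
        return self.edges[self.edges["edge_type"] == edge_type]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for gid, row in self.nodes.iterrows():
            g.add_node(gid, **{k: v for k, v in row.items() if pd.notna(v)})
        for _, e in self.edges.iterrows():
            attrs = {"edge_type": e["edge_type"],
                     "directed": e["edge_type"] == "motif"}
            if "r" in e.index and pd.notna(e.get("r")):
                attrs["r"] = float(e["r"])
            g.add_edge(e["source"], e["target"], **attrs)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def write_edge_tsv(self, path) -> None:
        cols = [c for c in ("source", "target", "edge_type", "r") if c in self.edges.columns]
        self.edges[cols].to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_edge_tsv(path, nodes: Optional[pd.DataFrame] = None) -> "RegulatoryNetwork":
        edges = pd.read_csv(path, sep="\t")
        if nodes is None:
            ids = sorted(set(edges["source"]) | set(edges["target"]))
            nodes = pd.DataFrame(index=pd.Index(ids, name="gene"))
        return RegulatoryNetwork(nodes=nodes, edges=edges)
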