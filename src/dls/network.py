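"""Discriminative co-expression network of predictions.

Edges run from a signature's gene to each gene it predicts with
confidence above the chosen threshold.  Duplicate (source, target) pairs
are collapsed keeping the maximum confidence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import networkx as nx

from dls.classify import Prediction

SUPPORTED_FORMATS = ("edgelist", "graphml", "sif")


@dataclass
class DiscriminativeNetwork:
    graph: nx.DiGraph
    threshold: float

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float, float]]:
        """(source, target, L, confidence) sorted by source then target."""
        return sorted(
            (u, v, d["L"], d["confidence"]) for u, v, d in self.graph.edges(data=True)
        )


def build_dcn(predictions: list[Prediction], threshold: float) -> DiscriminativeNetwork:
    """Keep predictions above the confidence threshold as directed edges.

    Vertices are the endpoint union (an empty network is fine); self
    edges never arise because a signature does not predict its own gene.
    """
    g = nx.DiGraph()
    for p in predictions:
        if p.confidence <= threshold:
            continue
        if p.gene == p.signature_gene:
            continue
        existing = g.get_edge_data(p.signature_gene, p.gene)
        if existing is None or p.confidence > existing["confidence"]:
            g.add_edge(p.signature_gene, p.gene, L=float(p.coexpression),
                       confidence=float(p.confidence))
    return DiscriminativeNetwork(graph=g, threshold=threshold)


def node_degrees(network: DiscriminativeNetwork) -> dict[str, tuple[int, int, int]]:
    """Per-gene (in_degree, out_degree, total)."""
    g = network.graph
    return {
        n: (g.in_degree(n), g.out_degree(n), g.in_degree(n) + g.out_degree(n))
        for n in sorted(g.nodes)
    }


def export_network(network: DiscriminativeNetwork, path: str, fmt: str = "edgelist") -> None:
    if fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "L", "confidence"])
            for u, v, L, conf in network.edges():
                w.writerow([u, v, repr(L), repr(conf)])
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, _, _ in network.edges():
                fh.write(f"{u}\tpredicts\t{v}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {SUPPORTED_FORMATS}")


def read_edge_list(path: str, threshold: float = 0.0) -> DiscriminativeNetwork:
    g = nx.DiGraph()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["source", "target"]:
            raise ValueError("edge list must start with a source/target header")
        for row in reader:
            u, v, L, conf = row
            g.add_edge(u, v, L=float(L), confidence=float(conf))
    return DiscriminativeNetwork(graph=g, threshold=threshold)
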