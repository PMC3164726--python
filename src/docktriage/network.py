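"""Bipartite drug-target interaction networks and Cytoscape export.

Nodes are proteins (``type=protein``) and drugs (``type=drug`` with an
approval ``status``); edges carry ``kind`` (known or predicted), whether
the pair docked with a good score, and the pair's best icm/pmf scores.
Networks are exported as SIF plus attribute sidecars, or as a single
GraphML document that round-trips losslessly.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DataError
from .scores import GOOD_SCORE_CUTOFF, KnownInteractions, ScoreMatrix

__all__ = ["build_network", "export_network", "read_network",
           "networks_equal"]


def build_network(matrix: ScoreMatrix, known: KnownInteractions,
                  predicted: set[tuple[str, str]],
                  good_cutoff: float = GOOD_SCORE_CUTOFF) -> nx.Graph:
    """Assemble the interaction network.

    Every known pair becomes a ``known`` edge (with ``good_score`` set
    from the matrix when the pair was docked); every predicted pair that
    is not already known becomes a ``predicted`` edge.  A predicted pair
    with no score in the matrix is a pipeline-ordering violation and
    raises.
    """
    net = nx.Graph(kind="drug-target")
    for protein in matrix.proteins:
        net.add_node(protein, type="protein")
    for drug in matrix.drugs:
        net.add_node(drug, type="drug",
                     status=known.drug_status.get(drug, "experimental"))

    def scores_of(pair):
        p, d = pair
        if p not in matrix.icm.index or d not in matrix.icm.columns:
            return None
        icm = matrix.icm.at[p, d]
        if pd.isna(icm):
            return None
        return float(icm), float(matrix.pmf.at[p, d])

    for p, d in sorted(known.pairs):
        for node, typ in ((p, "protein"), (d, "drug")):
            if node not in net:
                net.add_node(node, type=typ,
                             **({"status": known.drug_status.get(node,
                                                                 "experimental")}
                                if typ == "drug" else {}))
        sc = scores_of((p, d))
        attrs = {"kind": "known", "good_score": False}
        if sc is not None:
            attrs.update(icm=sc[0], pmf=sc[1],
                         good_score=bool(sc[0] <= good_cutoff))
        net.add_edge(p, d, **attrs)

    for p, d in sorted(predicted):
        if (p, d) in known.pairs:
            continue
        sc = scores_of((p, d))
        if sc is None:
            raise DataError(
                f"predicted pair ({p}, {d}) has no score in the matrix; "
                "prediction must follow aggregation")
        net.add_edge(p, d, kind="predicted", icm=sc[0], pmf=sc[1],
                     good_score=bool(sc[0] <= good_cutoff))
    return net


def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML or as SIF plus attribute sidecars.

    SIF lines read ``protein <kind> drug``; node and edge attributes go
    to ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(net.edges(data=True)):
                p, d = (u, v) if net.nodes[u].get("type") == "protein" else (v, u)
                fh.write(f"{p}\t{data['kind']}\t{d}\n")
        nodes = pd.DataFrame(
            [{"id": n, **attrs} for n, attrs in sorted(net.nodes(data=True))])
        nodes.to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t",
                     index=False)
        edges = pd.DataFrame(
            [{"protein_id": u if net.nodes[u].get("type") == "protein" else v,
              "drug_id": v if net.nodes[u].get("type") == "protein" else u,
              **attrs}
             for u, v, attrs in sorted(net.edges(data=True))])
        edges.to_csv(path.with_suffix(path.suffix + ".edges.tsv"), sep="\t",
                     index=False)
    else:
        raise DataError(f"unknown network format {format!r}; "
                        "use 'sif' or 'graphml'")


def read_network(path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        net = nx.Graph(kind="drug-target")
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        edges_path = path.with_suffix(path.suffix + ".edges.tsv")
        if nodes_path.exists():
            for row in pd.read_csv(nodes_path, sep="\t").to_dict("records"):
                node = row.pop("id")
                net.add_node(node, **{k: v for k, v in row.items()
                                      if not (isinstance(v, float)
                                              and math.isnan(v))})
        if edges_path.exists():
            for row in pd.read_csv(edges_path, sep="\t").to_dict("records"):
                p, d = row.pop("protein_id"), row.pop("drug_id")
                net.add_edge(p, d, **{k: v for k, v in row.items()
                                      if not (isinstance(v, float)
                                              and math.isnan(v))})
        else:
            with open(path) as fh:
                for line in fh:
                    p, kind, d = line.rstrip("\n").split("\t")
                    net.add_edge(p, d, kind=kind)
        return net
    raise DataError(f"unknown network format {format!r}")


def networks_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Node-, edge- and attribute-level equality of two networks."""
    if set(a.nodes) != set(b.nodes) or set(map(frozenset, a.edges)) != \
            set(map(frozenset, b.edges)):
        return False
    for n in a.nodes:
        if dict(a.nodes[n]) != dict(b.nodes[n]):
            return False
    for u, v in a.edges:
        if dict(a.edges[u, v]) != dict(b.edges[u, v]):
            return False
    return True
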