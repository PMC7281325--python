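"""Multi-omic network integration and hypergeometric gene-set enrichment.

Phospho markers and trastuzumab-independent genes are merged into one
undirected graph keyed by gene symbol. Phosphoprotein nodes carry the
A-contrast (resistant vs parental, untreated) signed fold-change vector per
time point with missing time points kept as explicit gaps; mRNA nodes carry
the transcript-level signed fold change; symbols found in both inputs
become a single ``both`` node. Optional protein-protein edges (TSV) and a
kinase symbol list annotate the graph. Gene-set enrichment uses the
upper-tail hypergeometric test with BH correction across terms.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

logger = logging.getLogger(__name__)

GRAPH_FORMATS = ("graphml", "cytoscape-json", "edge-tsv")


def build_network(
    marker_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    edges: Optional[pd.DataFrame] = None,
    kinases: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Merge marker and gene tables into an annotated graph.

    Parameters
    ----------
    marker_table
        Output table of :func:`phosmark.markers.select_markers` (needs
        ``gene_symbol``, ``site``, ``direction`` and ``fc_A_<tp>`` columns).
    gene_table
        Per-gene frame with columns ``gene`` and signed ``fold_change``.
    edges
        Optional frame with columns ``source``, ``target`` and optionally
        ``score`` / ``database``; edges touching absent symbols are dropped
        with a warning.
    kinases
        Symbols to flag as known kinases.
    """
    kinase_set = set(kinases or ())
    graph = nx.Graph()

    tp_cols = [c for c in marker_table.columns if c.startswith("fc_A_")]
    for _, row in marker_table.iterrows():
        symbol = row["gene_symbol"]
        fc_vector = {
            c[len("fc_A_") :]: (None if pd.isna(row[c]) else float(row[c]))
            for c in tp_cols
        }
        if symbol not in graph:
            graph.add_node(
                symbol,
                node_kind="phosphoprotein",
                sites={},
                mrna_fc=None,
                regulation=row["direction"],
                kinase=symbol in kinase_set,
            )
        graph.nodes[symbol]["sites"][str(row["site"])] = fc_vector

    for _, row in gene_table.iterrows():
        symbol = row["gene"]
        if symbol in graph:
            graph.nodes[symbol]["node_kind"] = "both"
            graph.nodes[symbol]["mrna_fc"] = float(row["fold_change"])
        else:
            graph.add_node(
                symbol,
                node_kind="mRNA",
                sites={},
                mrna_fc=float(row["fold_change"]),
                regulation="up" if row["fold_change"] >= 1 else "down",
                kinase=symbol in kinase_set,
            )

    if edges is not None:
        for _, row in edges.iterrows():
            a, b = row["source"], row["target"]
            if a not in graph or b not in graph:
                logger.warning("dropping edge (%s, %s): endpoint not in network", a, b)
                continue
            graph.add_edge(
                a,
                b,
                score=float(row.get("score", 1.0)),
                database=str(row.get("database", "file")),
            )
    return graph


def _hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    selected: Set[str],
    universe: Set[str],
    gene_sets: Mapping[str, Set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` within ``universe``.

    Each gene set is intersected with the universe before testing; terms
    with no annotated universe member are skipped. BH adjustment runs
    across all tested terms. Output is sorted by p then term name.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected symbols must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & universe
        K = len(members)
        if K == 0:
            continue
        overlap = members & selected
        k = len(overlap)
        rows.append(
            {
                "term": term,
                "universe": N,
                "annotated": K,
                "selected": n,
                "overlap": k,
                "p": _hypergeom_sf(k, N, K, n),
                "members": ";".join(sorted(overlap)),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "universe", "annotated", "selected", "overlap", "p", "members"]
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    return result[["term", "universe", "annotated", "selected", "overlap", "p", "q", "members"]]


def read_gmt(path) -> Dict[str, Set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: Dict[str, Set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_edge_list(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("source", "target"):
        if col not in frame.columns:
            raise ValueError(f"edge list missing column {col!r}")
    return frame


def _encode(graph: nx.Graph) -> nx.Graph:
    """JSON-encode every attribute so self-describing formats round trip."""
    encoded = nx.Graph()
    for node in sorted(graph.nodes):
        encoded.add_node(
            node,
            **{k: json.dumps(v, sort_keys=True) for k, v in sorted(graph.nodes[node].items())},
        )
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        encoded.add_edge(
            a, b,
            **{k: json.dumps(v, sort_keys=True) for k, v in sorted(graph.edges[a, b].items())},
        )
    return encoded


#: bookkeeping attributes injected by the Cytoscape JSON reader, not payload
_FORMAT_KEYS = ("name", "id", "value", "source", "target")


def _decode(graph: nx.Graph) -> nx.Graph:
    decoded = nx.Graph()
    for node in sorted(graph.nodes):
        attrs = {
            k: json.loads(v)
            for k, v in graph.nodes[node].items()
            if k not in _FORMAT_KEYS
        }
        decoded.add_node(node, **attrs)
    for a, b in graph.edges:
        attrs = {
            k: json.loads(v)
            for k, v in graph.edges[a, b].items()
            if k not in _FORMAT_KEYS
        }
        decoded.add_edge(a, b, **attrs)
    return decoded


def export_graph(graph: nx.Graph, path, fmt: str = "graphml") -> Path:
    """Write the network in GraphML, Cytoscape JSON or a plain edge TSV.

    GraphML and Cytoscape JSON are lossless: attributes are JSON-encoded
    strings (missing time points serialize as ``null``) and element order
    is deterministic.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_encode(graph), path)
    elif fmt == "cytoscape-json":
        payload = nx.cytoscape_data(_encode(graph))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif fmt == "edge-tsv":
        rows = [
            {"source": a, "target": b, **graph.edges[a, b]}
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges)
        ]
        pd.DataFrame(rows, columns=["source", "target", "score", "database"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {GRAPH_FORMATS}")
    return path


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Re-import a GraphML or Cytoscape JSON export (inverse of export_graph)."""
    path = Path(path)
    if fmt == "graphml":
        return _decode(nx.read_graphml(path))
    if fmt == "cytoscape-json":
        return _decode(nx.cytoscape_graph(json.loads(path.read_text())))
    raise ValueError(f"cannot re-import format {fmt!r}")
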