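"""Directed protein-interaction network: loading, restriction, weighting.

Edges are consensus-oriented (signal flows source -> target). Networks are
held as ``networkx.DiGraph``; self-loops are dropped on load and duplicate
edges collapsed, with counts logged. "Largest connected component" is taken
in the weak (undirected) sense by default so that pure-source receptors and
pure-sink transcription factors are retained; strong connectivity is
available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import networkx as nx

from .prep import NodeWeights

logger = logging.getLogger(__name__)

__all__ = [
    "load_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "annotate_weights",
    "export_graphml",
]


def load_edge_list(path: str | Path, drop_self_loops: bool = True) -> nx.DiGraph:
    """Parse a two-column (source, target) edge list into a directed graph.

    Lines starting with ``#`` are ignored. Duplicate edges are collapsed
    and self-loops dropped (by default); the counts of both are logged.
    A line with fewer than two whitespace/tab-separated fields raises with
    its line number.
    """
    g = nx.DiGraph()
    n_dup = 0
    n_self = 0
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed edge line {line!r} "
                    "(need at least two columns)")
            u, v = fields[0], fields[1]
            if u == v:
                if drop_self_loops:
                    n_self += 1
                    continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        warnings.warn(f"{path}: empty edge list", stacklevel=2)
    logger.info("load_edge_list: %d nodes, %d edges (%d duplicates collapsed,"
                " %d self-loops dropped)", g.number_of_nodes(),
                g.number_of_edges(), n_dup, n_self)
    return g


def write_edge_list(g: nx.DiGraph, path: str | Path) -> None:
    """Write the edge set as a sorted two-column TSV (round-trips with load)."""
    with Path(path).open("w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")


def largest_connected_component(g: nx.DiGraph, strong: bool = False) -> nx.DiGraph:
    """Subgraph induced on the largest (weakly) connected component.

    Ties in component size are broken toward the component containing the
    lexicographically smallest node, so the result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no connected component")
    comps = list(nx.strongly_connected_components(g) if strong
                 else nx.weakly_connected_components(g))
    max_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == max_size), key=min)
    return g.subgraph(best).copy()


def annotate_weights(g: nx.DiGraph, w: NodeWeights,
                     missing_policy: str = "floor") -> tuple[nx.DiGraph, NodeWeights]:
    """Attach per-condition node weights to the graph.

    Nodes absent from ``w`` either receive the observed minimum weight
    (``floor``, the default — unmeasured intermediate proteins can still
    carry signal through a path) or are removed together with their
    incident edges (``drop``). Returns the annotated graph and a weight
    map covering every remaining node.
    """
    if len(w) == 0:
        raise ValueError("empty weight map")
    if missing_policy not in ("floor", "drop"):
        raise ValueError("missing_policy must be 'floor' or 'drop'")
    missing = [n for n in g.nodes if n not in w]
    if missing_policy == "drop":
        out = g.copy()
        out.remove_nodes_from(missing)
        full = {n: float(w[n]) for n in out.nodes}
    else:
        out = g.copy()
        floor = min(w.weights.values())
        full = {n: float(w[n]) if n in w else float(floor) for n in out.nodes}
    logger.info("annotate_weights(%s): %d/%d nodes lacked a weight (policy=%s)",
                w.condition, len(missing), g.number_of_nodes(), missing_policy)
    nx.set_node_attributes(out, full, name=f"weight_{w.condition}")
    return out, NodeWeights(condition=w.condition, weights=full)


def export_graphml(g: nx.DiGraph, path: str | Path,
                   condition_specific_edges: set[tuple[str, str]] | None = None,
                   ) -> None:
    """Write GraphML with per-condition node weights and, optionally, a
    boolean ``condition_specific`` edge attribute."""
    out = g.copy()
    if condition_specific_edges is not None:
        flags = {e: (e in condition_specific_edges) for e in out.edges()}
        nx.set_edge_attributes(out, flags, name="condition_specific")
    nx.write_graphml(out, str(path))
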