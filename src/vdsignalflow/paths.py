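"""Signaling-path inference on a weighted directed interaction network.

Signal transduction is modeled as a sequential path on the PPI network: it
starts at a cell-membrane receptor, traverses intermediate proteins along
directed edges, and ends at a transcription factor. For every
receptor-TF pair, ALL shortest (fewest-hop) directed paths are enumerated;
each path is scored by the arithmetic mean of its nodes' expression
weights in a given condition; paths are pooled across pairs and ranked
globally. Comparing the top-ranked path sets of two conditions yields the
edges specific to one condition (e.g. interactions engaged only in
calcitriol-stimulated cells).

Enumeration builds the shortest-path DAG for a pair — the nodes u with
dist(source, u) + dist(u, target) == dist(source, target) — and walks it
depth-first choosing successors in sorted node order, so paths come out in
lexicographic order and a truncation cap keeps a deterministic prefix.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .prep import NodeWeights

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkPath",
    "RankedPathSet",
    "ComparisonReport",
    "all_shortest_paths",
    "score_path",
    "rank_paths",
    "condition_specific_edges",
    "compare_conditions",
]


@dataclass(frozen=True)
class NetworkPath:
    """An ordered receptor -> ... -> TF node sequence with optional score."""

    nodes: tuple[str, ...]
    score: float | None = None

    @property
    def length(self) -> int:
        """Hop count (number of edges)."""
        return len(self.nodes) - 1

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    def sort_key(self) -> tuple:
        """Descending score, then shorter length, then lexicographic nodes."""
        return (-(self.score if self.score is not None else 0.0),
                self.length, self.nodes)


@dataclass
class RankedPathSet:
    """Top-k scored paths for one condition, in deterministic total order."""

    condition: str
    paths: list[NetworkPath]
    k: int
    truncated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def edge_union(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for p in self.paths:
            out.update(p.edges)
        return out

    def node_union(self) -> set[str]:
        out: set[str] = set()
        for p in self.paths:
            out.update(p.nodes)
        return out

    def to_tsv(self) -> str:
        lines = ["rank\tscore\tlength\tnodes"]
        for i, p in enumerate(self.paths, start=1):
            lines.append(f"{i}\t{p.score:.10g}\t{p.length}\t"
                         + "|".join(p.nodes))
        return "\n".join(lines) + "\n"


def _bfs_dist(g: nx.DiGraph, source: str, reverse: bool = False) -> dict[str, int]:
    nbrs = g.predecessors if reverse else g.successors
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in nbrs(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(g: nx.DiGraph, source: str, target: str,
                       max_paths_per_pair: int = 10_000,
                       ) -> tuple[list[NetworkPath], bool]:
    """Enumerate every fewest-hop directed path from source to target.

    Returns ``(paths, truncated)``. Paths are emitted in lexicographic
    order of their node sequences; if more than ``max_paths_per_pair``
    shortest paths exist, the lexicographically first ones are kept and
    the truncation flag is set. An unreachable target yields an empty
    list (logged), not an error; ``source == target`` yields the single
    zero-length path.
    """
    if source not in g:
        raise ValueError(f"source {source!r} not in graph")
    if target not in g:
        raise ValueError(f"target {target!r} not in graph")
    if source == target:
        return [NetworkPath(nodes=(source,))], False
    dist_from = _bfs_dist(g, source)
    if target not in dist_from:
        logger.info("all_shortest_paths: %s cannot reach %s", source, target)
        return [], False
    dist_to = _bfs_dist(g, target, reverse=True)
    d = dist_from[target]

    def on_dag(u: str) -> bool:
        return (u in dist_from and u in dist_to
                and dist_from[u] + dist_to[u] == d)

    paths: list[NetworkPath] = []
    truncated = False
    stack: list[str] = [source]

    def dfs(u: str) -> bool:
        """Returns False once the cap is hit, aborting the walk."""
        nonlocal truncated
        if u == target:
            if len(paths) >= max_paths_per_pair:
                truncated = True
                return False
            paths.append(NetworkPath(nodes=tuple(stack)))
            return True
        for v in sorted(g.successors(u)):
            if on_dag(v) and dist_from[v] == dist_from[u] + 1:
                stack.append(v)
                ok = dfs(v)
                stack.pop()
                if not ok:
                    return False
        return True

    dfs(source)
    if truncated:
        logger.warning("all_shortest_paths: %s->%s truncated at %d paths",
                       source, target, max_paths_per_pair)
    return paths, truncated


def score_path(p: NetworkPath, w: NodeWeights) -> float:
    """Arithmetic mean of the path's node weights, endpoints included."""
    missing = [n for n in p.nodes if n not in w]
    if missing:
        raise ValueError(
            f"path nodes without a weight: {missing} — run annotate_weights "
            "first so every node carries the condition's expression value")
    return float(sum(w[n] for n in p.nodes) / len(p.nodes))


def rank_paths(g: nx.DiGraph, receptors: list[str], tfs: list[str],
               w: NodeWeights, top_k: int = 50,
               max_paths_per_pair: int = 10_000) -> RankedPathSet:
    """Pool all shortest paths over every receptor-TF pair and rank globally.

    Each path is scored by mean node expression; the pooled list is sorted
    by descending score with ties broken by shorter length, then
    lexicographic node tuple (a total, deterministic order), and the first
    ``top_k`` paths are returned. Receptor/TF IDs absent from the graph
    are skipped with a log message; if no pair is reachable at all an
    error is raised.
    """
    if not receptors or not tfs:
        raise ValueError("receptor and TF lists must be nonempty")
    rec = [r for r in receptors if r in g]
    tf = [t for t in tfs if t in g]
    skipped = (set(receptors) - set(rec)) | (set(tfs) - set(tf))
    if skipped:
        logger.info("rank_paths: skipping IDs absent from graph: %s",
                    sorted(skipped))
    pooled: dict[tuple[str, ...], NetworkPath] = {}
    truncated_pairs: list[tuple[str, str]] = []
    for r in sorted(rec):
        for t in sorted(tf):
            if r == t:
                continue
            pair_paths, truncated = all_shortest_paths(
                g, r, t, max_paths_per_pair=max_paths_per_pair)
            if truncated:
                truncated_pairs.append((r, t))
            for p in pair_paths:
                pooled.setdefault(p.nodes, p)
    if not pooled:
        raise ValueError("no receptor–TF path exists")
    scored = [NetworkPath(nodes=nodes, score=score_path(p, w))
              for nodes, p in pooled.items()]
    scored.sort(key=NetworkPath.sort_key)
    return RankedPathSet(condition=w.condition, paths=scored[:top_k],
                         k=top_k, truncated_pairs=truncated_pairs)


def condition_specific_edges(a: RankedPathSet, b: RankedPathSet,
                             ) -> set[tuple[str, str]]:
    """Edges used by a's top paths but by none of b's top paths."""
    return a.edge_union() - b.edge_union()


@dataclass
class ComparisonReport:
    """Two ranked path sets plus their edge-set differences."""

    ranked_a: RankedPathSet
    ranked_b: RankedPathSet
    specific_to_a: set[tuple[str, str]]
    specific_to_b: set[tuple[str, str]]
    shared_edges: set[tuple[str, str]]

    def to_dict(self) -> dict:
        def ranked(rs: RankedPathSet) -> dict:
            return {
                "condition": rs.condition,
                "k": rs.k,
                "truncated_pairs": sorted(rs.truncated_pairs),
                "paths": [{"nodes": list(p.nodes), "score": p.score}
                          for p in rs.paths],
            }

        return {
            "ranked_a": ranked(self.ranked_a),
            "ranked_b": ranked(self.ranked_b),
            "specific_to_a": sorted(self.specific_to_a),
            "specific_to_b": sorted(self.specific_to_b),
            "shared_edges": sorted(self.shared_edges),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        def ranked(rd: dict) -> RankedPathSet:
            return RankedPathSet(
                condition=rd["condition"], k=rd["k"],
                truncated_pairs=[tuple(p) for p in rd["truncated_pairs"]],
                paths=[NetworkPath(nodes=tuple(p["nodes"]), score=p["score"])
                       for p in rd["paths"]])

        return cls(
            ranked_a=ranked(d["ranked_a"]), ranked_b=ranked(d["ranked_b"]),
            specific_to_a={tuple(e) for e in d["specific_to_a"]},
            specific_to_b={tuple(e) for e in d["specific_to_b"]},
            shared_edges={tuple(e) for e in d["shared_edges"]})

    @classmethod
    def from_json(cls, path: str | Path) -> "ComparisonReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compare_conditions(g: nx.DiGraph, receptors: list[str], tfs: list[str],
                       w_a: NodeWeights, w_b: NodeWeights, top_k: int = 50,
                       max_paths_per_pair: int = 10_000) -> ComparisonReport:
    """Rank paths under two conditions and extract condition-specific edges.

    The path *set* is identical between conditions (the network does not
    change); what differs is the scoring and hence which paths make the
    top k, and therefore which edges each condition's active subnetwork
    uses exclusively.
    """
    ranked_a = rank_paths(g, receptors, tfs, w_a, top_k=top_k,
                          max_paths_per_pair=max_paths_per_pair)
    ranked_b = rank_paths(g, receptors, tfs, w_b, top_k=top_k,
                          max_paths_per_pair=max_paths_per_pair)
    ea, eb = ranked_a.edge_union(), ranked_b.edge_union()
    return ComparisonReport(ranked_a=ranked_a, ranked_b=ranked_b,
                            specific_to_a=ea - eb, specific_to_b=eb - ea,
                            shared_edges=ea & eb)
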