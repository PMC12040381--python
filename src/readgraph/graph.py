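"""The edit-distance graph and within-bucket edge detection.

Nodes are unique-read ids carrying (sequence, frequency) attributes; an
edge connects two reads whose edit distance lies in the working interval
and is weighted by that distance.  During construction the working
interval is always [1, dmax] — small-distance edges are what the
traversal stage walks over — and dmin is applied only at finalization.

A single global ``seen_pairs`` set deduplicates pair evaluations across
buckets and stages: a pair's distance is computed at most once no matter
how many buckets it co-occurs in.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .distance import EdgeCandidate, bounded_edit_distance
from .io import UniqueReadSet


class EditDistanceGraph:
    """Undirected weighted graph over read ids, plus construction state."""

    def __init__(self) -> None:
        self.g = nx.Graph()
        self.seen_pairs: set[tuple[int, int]] = set()
        self.distance_calls = 0  # instrumentation: pair evaluations
        self.stage_edges: dict[str, int] = {}

    # -- node/edge access -------------------------------------------------
    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def sequence(self, node: int) -> str:
        return self.g.nodes[node]["sequence"]

    def edges_with_distances(self) -> Iterable[tuple[int, int, int]]:
        for a, b, d in self.g.edges(data="distance"):
            yield a, b, d

    def edge_pairs(self) -> set[tuple[int, int]]:
        return {(min(a, b), max(a, b)) for a, b in self.g.edges()}

    def neighbors(self, node: int):
        return self.g.neighbors(node)


def init_graph(reads: UniqueReadSet) -> EditDistanceGraph:
    """One node per unique read, zero edges, empty seen-pairs."""
    graph = EditDistanceGraph()
    for rec in reads:
        graph.g.add_node(rec.id, sequence=rec.sequence, frequency=rec.frequency)
    return graph


def evaluate_pair(graph: EditDistanceGraph, a: int, b: int, dmax: int) -> bool:
    """Mark a pair seen, compute its bounded distance once, and insert an
    edge iff 1 <= d <= dmax.  Returns True if an edge was added."""
    if a == b:
        return False
    pair = (a, b) if a < b else (b, a)
    if pair in graph.seen_pairs:
        return False
    graph.seen_pairs.add(pair)
    graph.distance_calls += 1
    d = bounded_edit_distance(graph.sequence(pair[0]), graph.sequence(pair[1]),
                              dmax)
    if d is not None and 1 <= d <= dmax:
        graph.g.add_edge(pair[0], pair[1], distance=d)
        return True
    return False


def process_bucket(graph: EditDistanceGraph, bucket: Iterable[int],
                   dmax: int) -> int:
    """Evaluate every not-yet-seen unordered pair in a bucket; returns the
    number of edges inserted."""
    ids = sorted(bucket)
    added = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if evaluate_pair(graph, ids[i], ids[j], dmax):
                added += 1
    return added


def finalize(graph: EditDistanceGraph, dmin: int) -> EditDistanceGraph:
    """Remove edges of weight < dmin; the node set is unchanged."""
    if dmin < 1:
        raise ValueError(f"dmin must be >= 1, got {dmin}")
    drop = [(a, b) for a, b, d in graph.edges_with_distances() if d < dmin]
    graph.g.remove_edges_from(drop)
    return graph


def _as_pairs(edges) -> set[tuple[int, int]]:
    out = set()
    for e in edges:
        if isinstance(e, EdgeCandidate):
            out.add((e.id_a, e.id_b))
        else:
            a, b = e[0], e[1]
            out.add((min(a, b), max(a, b)))
    return out


def completeness(found, truth) -> float:
    """|found| / |truth| over edge pair sets; 1.0 when truth is empty.
    Fails loudly if found is not a subset of truth — every inserted edge is
    distance-verified, so a violation indicates a distance bug."""
    f, t = _as_pairs(found), _as_pairs(truth)
    if not f <= t:
        extra = sorted(f - t)[:5]
        raise AssertionError(
            f"found edges not in ground truth (distance bug?): {extra}")
    if not t:
        return 1.0
    return len(f) / len(t)


def pctc(e_x: int, e_10000: int, e_truth: int) -> float:
    """Change of completeness (E_x - E_10000) / E_truth between a run at
    large-bucket threshold x and the reference threshold-10,000 run."""
    if e_truth <= 0:
        raise ValueError("E_truth must be positive")
    return (e_x - e_10000) / e_truth
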