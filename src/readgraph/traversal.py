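"""Multi-hop neighbourhood traversal over the partially built graph.

After the two bucketing stages, some buckets can remain at or above the
large-bucket threshold ("rigid" bins).  Reads in those bins typically
already carry *some* edges; because exact edit distances obey the
triangle inequality, nodes a few hops away along small-weight edges are
good candidates for missing edges.  For each target node we breadth-first
visit every node within a hop budget (default 3 * dmax hops) and compute
the actual bounded edit distance for each not-yet-seen candidate pair —
the triangle inequality only nominates candidates, never assigns weights.
The sweep repeats until a pass adds no edge or the pass cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph import EditDistanceGraph, evaluate_pair
from .minimizers import BucketMap


@dataclass
class TraversalConfig:
    """hop_budget: maximum BFS depth in hops (None -> 3 * dmax);
    max_passes: sweeps over the target set (0 -> iterate to fixpoint)."""

    hop_budget: int | None = None
    max_passes: int = 2

    def budget(self, dmax: int) -> int:
        b = self.hop_budget if self.hop_budget is not None else 3 * dmax
        if b < 2:
            raise ValueError(f"hop_budget must be >= 2, got {b}")
        return b


def traverse_recover(graph: EditDistanceGraph, targets, dmax: int,
                     config: TraversalConfig | None = None) -> int:
    """BFS each target's <= hop_budget-hop neighbourhood, distance-check
    every unseen candidate pair, insert edges of weight in [1, dmax].
    Returns the total number of edges added over all passes."""
    config = config or TraversalConfig()
    budget = config.budget(dmax)
    targets = sorted(targets)
    total = 0
    passes = 0
    while True:
        passes += 1
        added = 0
        for t in targets:
            if t not in graph.g:
                continue
            reach = nx.single_source_shortest_path_length(
                graph.g, t, cutoff=budget)
            for v in sorted(reach):
                if v != t and evaluate_pair(graph, t, v, dmax):
                    added += 1
        total += added
        if added == 0:
            break
        if config.max_passes and passes >= config.max_passes:
            break
    return total


def residual_large_targets(minimizer_map: BucketMap, gomh_map: BucketMap,
                           large_threshold: int = 10_000) -> set[int]:
    """Reads belonging to sketch buckets that are still at or above the
    large threshold after re-bucketing (these descend from large minimizer
    buckets by construction)."""
    out: set[int] = set()
    for _, ids in gomh_map.buckets.items():
        if len(ids) >= large_threshold:
            out |= ids
    return out
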