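"""Pipeline orchestration: minimizer bucketing -> gOMH -> traversal.

The standard pipeline works on an internal interval [1, dmax]; dmin is
applied only when the graph is finalized, so small-distance edges remain
available as stepping stones for the traversal stage.  The whole run is
deterministic for a fixed master seed; the ``threads`` field is an
accepted hint only — computation is sequential, and the contract is that
any parallel execution must reproduce the sequential edge set exactly.

UMI mode (8-12 nt tags) differs in three ways: segmentation is
disallowed, stage-1 k is tuned for a single differing base, and the gOMH
and traversal stages run over the unique sequences of *normal* bins too
(a single minimizer round misses too many edges at these lengths).  When
a read has no more gapped k-mer candidates than there are permutations,
min-hash selection is skipped and every candidate becomes a bucket key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gomh import gomh_bucket, make_permutations
from .graph import EditDistanceGraph, finalize, init_graph, process_bucket
from .io import UniqueReadSet
from .minimizers import BucketMap, bucket_reads, derive_seed
from .params import BucketingMode, ParameterError, estimate_bucketing_params
from .traversal import TraversalConfig, residual_large_targets, traverse_recover

logger = logging.getLogger("readgraph")

STAGES = ("minimizer", "gomh", "traversal")


@dataclass
class PipelineConfig:
    dmin: int = 1
    dmax: int = 3
    mode: BucketingMode | str = BucketingMode.RANDOM_WHOLE
    large_threshold: int = 10_000
    traversal: TraversalConfig = field(default_factory=TraversalConfig)
    p2: float = 0.8
    pt: float = 0.6
    alpha: float = 0.5
    beta: float = 2.0
    m: int = 3
    n: int | None = None
    k0: int | None = None
    gomh_floor: int = 3
    master_seed: int = 0
    umi_mode: bool = False
    threads: int = 1  # hint only; execution is sequential

    def __post_init__(self) -> None:
        self.mode = BucketingMode(self.mode)
        if not (1 <= self.dmin <= self.dmax):
            raise ValueError(f"require 1 <= dmin <= dmax, got "
                             f"[{self.dmin}, {self.dmax}]")
        if self.dmax > 10:
            raise ValueError(f"dmax {self.dmax} exceeds the sanity cap of 10")
        if self.large_threshold < 2:
            raise ValueError("large_threshold must be >= 2")


def representative_length(reads: UniqueReadSet) -> int:
    """10th-percentile unique-read length: keeps the estimated k feasible
    for nearly all reads in variable-length sets."""
    lengths = [len(r.sequence) for r in reads]
    return int(np.percentile(lengths, 10, method="lower"))


def _log_bucket_histogram(stage: str, bmap: BucketMap) -> None:
    sizes = sorted((len(v) for v in bmap.buckets.values()), reverse=True)
    logger.info("%s: %d buckets, sizes top5=%s, %d large (>= %d)",
                stage, len(sizes), sizes[:5],
                sum(s >= bmap.large_threshold for s in sizes),
                bmap.large_threshold)


def run_pipeline(reads: UniqueReadSet, config: PipelineConfig
                 ) -> EditDistanceGraph:
    """Build the edit-distance graph of a read set (standard mode)."""
    if config.umi_mode:
        return run_umi_pipeline(reads, config)
    graph = init_graph(reads)
    if len(reads) == 0:
        graph.stage_edges = dict.fromkeys(STAGES, 0)
        return graph
    l_est = representative_length(reads)
    params = estimate_bucketing_params(
        l_est, config.mode, config.dmax, pt=config.pt, alpha=config.alpha,
        beta=config.beta, m=config.m, n=config.n, k0=config.k0,
        order_seed=derive_seed(config.master_seed, "minimizer-order"))
    logger.info("params: mode=%s k=%d w=%d (%s) n=%d",
                params.mode.value, params.k, params.w, params.window_unit,
                params.n)

    # Stage 1: minimizer bucketing, edges from normal buckets.
    mmap = bucket_reads(reads, params, config.large_threshold)
    _log_bucket_histogram("minimizer", mmap)
    for _, ids in mmap.normal_items():
        process_bucket(graph, ids, config.dmax)
    graph.stage_edges["minimizer"] = graph.number_of_edges()

    # Stage 2: gOMH re-bucketing of the unique reads of large buckets.
    large_ids = sorted(mmap.large_read_ids())
    gmap = BucketMap(large_threshold=config.large_threshold)
    if large_ids:
        perms = make_permutations(
            l_est, config.dmin, config.dmax, config.p2,
            floor=config.gomh_floor,
            master_seed=derive_seed(config.master_seed, "gomh"))
        gmap = gomh_bucket(((i, graph.sequence(i)) for i in large_ids),
                           perms, config.large_threshold, p2=config.p2)
        _log_bucket_histogram("gomh", gmap)
        for _, ids in gmap.normal_items():
            process_bucket(graph, ids, config.dmax)
    graph.stage_edges["gomh"] = graph.number_of_edges()

    # Stage 3: traversal over reads of buckets that are still large.
    targets = residual_large_targets(mmap, gmap, config.large_threshold)
    if targets:
        added = traverse_recover(graph, targets, config.dmax, config.traversal)
        logger.info("traversal: %d edges added for %d targets",
                    added, len(targets))
    graph.stage_edges["traversal"] = graph.number_of_edges()

    return finalize(graph, config.dmin)


def run_umi_pipeline(umis: UniqueReadSet, config: PipelineConfig
                     ) -> EditDistanceGraph:
    """Build the edit-distance graph of a UMI set (8-12 nt tags)."""
    if config.mode.segmented:
        raise ParameterError(
            "segmented bucketing is ineffective on short tags; use "
            "random_whole or miniception_whole in UMI mode")
    graph = init_graph(umis)
    if len(umis) == 0:
        graph.stage_edges = dict.fromkeys(STAGES, 0)
        return graph
    l_est = representative_length(umis)
    params = estimate_bucketing_params(
        l_est, config.mode, config.dmax, pt=config.pt, alpha=config.alpha,
        beta=config.beta, m=config.m, n=1, k0=config.k0, umi=True,
        order_seed=derive_seed(config.master_seed, "minimizer-order"))
    logger.info("umi params: mode=%s k=%d w=%d (%s)",
                params.mode.value, params.k, params.w, params.window_unit)

    mmap = bucket_reads(umis, params, config.large_threshold)
    _log_bucket_histogram("minimizer", mmap)
    for _, ids in mmap.normal_items():
        process_bucket(graph, ids, config.dmax)
    graph.stage_edges["minimizer"] = graph.number_of_edges()

    # Stage 2: gOMH over unique sequences of normal AND large bins.
    all_ids = sorted(mmap.member_ids())
    perms = make_permutations(
        l_est, config.dmin, config.dmax, config.p2, floor=config.gomh_floor,
        master_seed=derive_seed(config.master_seed, "gomh"))
    gmap = gomh_bucket(((i, graph.sequence(i)) for i in all_ids), perms,
                       config.large_threshold, p2=config.p2,
                       all_candidate_fallback=True)
    _log_bucket_histogram("gomh", gmap)
    for _, ids in gmap.normal_items():
        process_bucket(graph, ids, config.dmax)
    graph.stage_edges["gomh"] = graph.number_of_edges()

    # Stage 3: traversal over normal-bin members plus residual large bins.
    targets = set()
    for _, ids in mmap.normal_items():
        targets |= ids
    targets |= residual_large_targets(mmap, gmap, config.large_threshold)
    if targets:
        added = traverse_recover(graph, targets, config.dmax, config.traversal)
        logger.info("traversal: %d edges added for %d targets",
                    added, len(targets))
    graph.stage_edges["traversal"] = graph.number_of_edges()

    return finalize(graph, config.dmin)
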