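"""Synthetic read/UMI sets with planted near-duplicate structure, and
completeness evaluation against the brute-force oracle.

Real error-corrupted read sets are dominated by clusters of low-frequency
reads a few edits away from a common true sequence.  The generator
emulates that: uniform-random templates, each spawning variants at
1..dmax_plant random edits (substitution/insertion/deletion mix), with
per-read frequencies drawn from a truncated geometric law (p = 0.5,
cap 1,000) so singletons dominate.  Planted edits can compose or cancel,
so the ground truth is always *recomputed* with the exact brute-force
oracle — the construction list is never trusted as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import ground_truth_edges
from .graph import completeness as _completeness, pctc as _pctc
from .io import UniqueReadSet
from .pipeline import PipelineConfig, run_pipeline

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    num_templates: int = 400
    variants_per_template: int = 4
    read_length: int = 100          # fixed length; indels allowed only if
    allow_indels: bool = True       # allow_indels (length then varies)
    dmax_plant: int = 3
    edit_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # sub, ins, del
    frequency_p: float = 0.5        # geometric skew, truncated at freq_cap
    freq_cap: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dmax_plant < 1:
            raise ValueError("dmax_plant must be >= 1")
        if abs(sum(self.edit_mix) - 1.0) > 1e-9:
            raise ValueError("edit_mix must sum to 1")
        if not self.allow_indels and (self.edit_mix[1] or self.edit_mix[2]):
            raise ValueError("indel planting requires allow_indels")


PRESETS: dict[str, SyntheticSpec] = {
    # ~2,000 unique 100-mers in clusters of <= 3 planted edits: a
    # desk-scale stand-in for an error-laden short-read set.
    "reads-small": SyntheticSpec(num_templates=400, variants_per_template=4,
                                 read_length=100, dmax_plant=3),
    "reads-medium": SyntheticSpec(num_templates=800, variants_per_template=4,
                                  read_length=100, dmax_plant=3),
    # ~5,000 unique 12-mers with planted single-substitution partners.
    "umi-small": SyntheticSpec(num_templates=2_500, variants_per_template=1,
                               read_length=12, dmax_plant=1,
                               allow_indels=False, edit_mix=(1.0, 0.0, 0.0)),
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, template: str, n_edits: int,
            edit_mix, allow_indels: bool) -> str:
    """Apply n_edits edits at distinct random positions, in descending
    position order so indels do not shift pending edit positions."""
    kinds = rng.choice(3, size=n_edits, p=list(edit_mix))
    positions = rng.choice(len(template), size=min(n_edits, len(template)),
                           replace=False)
    seq = template
    for kind, pos in sorted(zip(kinds, positions), key=lambda t: -t[1]):
        if kind == 0 or not allow_indels:  # substitution
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq = seq[:pos] + str(rng.choice(choices)) + seq[pos + 1:]
        elif kind == 1:  # insertion
            seq = seq[:pos] + str(rng.choice(_BASES)) + seq[pos:]
        else:  # deletion
            if len(seq) > 1:
                seq = seq[:pos] + seq[pos + 1:]
    return seq


def generate_read_set(spec: SyntheticSpec) -> UniqueReadSet:
    """Deterministically expand a spec into a unique-read set with skewed
    frequencies; duplicate sequences collapse with summed frequency."""
    rng = np.random.default_rng(spec.seed)
    sequences: list[str] = []
    for _ in range(spec.num_templates):
        template = _random_seq(rng, spec.read_length)
        sequences.append(template)
        for _ in range(spec.variants_per_template):
            n_edits = int(rng.integers(1, spec.dmax_plant + 1))
            sequences.append(_mutate(rng, template, n_edits, spec.edit_mix,
                                     spec.allow_indels))
    raw: list[str] = []
    for seq in sequences:
        freq = min(int(rng.geometric(spec.frequency_p)), spec.freq_cap)
        raw.extend([seq] * freq)
    return UniqueReadSet.from_sequences(raw)


@dataclass
class CompletenessReport:
    """Pipeline-vs-oracle evaluation across large-bucket thresholds."""

    E_found: int = 0                 # edges found at threshold 10,000
    E_truth: int = 0
    completeness: float = 0.0
    per_stage_edges: dict[str, int] = field(default_factory=dict)
    pctc_table: dict[int, float] = field(default_factory=dict)
    completeness_by_threshold: dict[int, float] = field(default_factory=dict)


REFERENCE_THRESHOLD = 10_000


def evaluate_run(reads: UniqueReadSet, config: PipelineConfig,
                 thresholds: list[int] | None = None) -> CompletenessReport:
    """Run the pipeline at each large-bucket threshold against one oracle
    ground truth; pctc is relative to the threshold-10,000 run (added to
    the sweep if absent)."""
    thresholds = list(thresholds or [REFERENCE_THRESHOLD])
    if REFERENCE_THRESHOLD not in thresholds:
        thresholds.append(REFERENCE_THRESHOLD)
    truth = ground_truth_edges(reads, config.dmin, config.dmax)
    found: dict[int, set] = {}
    stages: dict[int, dict[str, int]] = {}
    for thr in sorted(set(thresholds)):
        cfg = PipelineConfig(
            dmin=config.dmin, dmax=config.dmax, mode=config.mode,
            large_threshold=thr, traversal=config.traversal, p2=config.p2,
            pt=config.pt, alpha=config.alpha, beta=config.beta, m=config.m,
            n=config.n, k0=config.k0, gomh_floor=config.gomh_floor,
            master_seed=config.master_seed, umi_mode=config.umi_mode)
        g = run_pipeline(reads, cfg)
        found[thr] = g.edge_pairs()
        stages[thr] = dict(g.stage_edges)
    ref = len(found[REFERENCE_THRESHOLD])
    report = CompletenessReport(
        E_found=ref,
        E_truth=len(truth),
        completeness=_completeness(found[REFERENCE_THRESHOLD], truth),
        per_stage_edges=stages[REFERENCE_THRESHOLD],
    )
    for thr, edges in found.items():
        report.completeness_by_threshold[thr] = _completeness(edges, truth)
        report.pctc_table[thr] = (_pctc(len(edges), ref, len(truth))
                                  if truth else 0.0)
    return report
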