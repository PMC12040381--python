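"""Bucketing-parameter estimation.

The minimizer stage is parameterized by a k-mer length k, a window size w
and (for the segmented modes) a segment count n.  These are chosen from
closed-form probability bounds on the chance that a pair of reads at edit
distance <= dmax shares an unmutated minimizer:

* ``p1_lower_bound`` — probability of drawing an unmutated k-mer from one
  segment when the dmax differing bases are spread evenly over n segments,
  p1 >= (S - k + 1 - (dmax/n) k) / (S - k + 1) with S = floor(l/n).
* ``collision_lower_bound`` — probability that at least one of the n
  segment minimizers is unmutated, P >= 1 - (dmax k / ((S-k+1) n))^n.
* ``select_k_segmented`` — largest k keeping the miss probability of a
  three-substitution segment below a threshold pt, subject to the k-mer
  space dwarfing the number of k-mer positions and segments holding more
  k-mers than mutated ones.
* ``select_k_miniception`` — k and w (in k-mers, w = ceil(beta*k)) matching
  the Miniception density bound 2/(w+1) to a wanted m minimizers per read.
* ``gomh_k`` — gapped k-mer length k' for the Order-Min-Hash stage at a
  target per-permutation collision probability p2 and distance dt.

All probability bounds clamp to [0, 1]; infeasible (k, dmax) combinations
would otherwise go negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


class BucketingMode(str, Enum):
    RANDOM_SEGMENTED = "random_segmented"
    RANDOM_WHOLE = "random_whole"
    MINICEPTION_WHOLE = "miniception_whole"
    MINICEPTION_SEGMENTED = "miniception_segmented"

    @property
    def segmented(self) -> bool:
        return self in (BucketingMode.RANDOM_SEGMENTED,
                        BucketingMode.MINICEPTION_SEGMENTED)

    @property
    def miniception(self) -> bool:
        return self in (BucketingMode.MINICEPTION_WHOLE,
                        BucketingMode.MINICEPTION_SEGMENTED)


class ParameterError(ValueError):
    """No feasible parameterization under the given constraints."""


@dataclass
class BucketingParams:
    """Full parameterization of one bucketing mode.

    window_unit is "bases" for random-minimizer modes (a window of w bases
    holds w - k + 1 k-mers) and "kmers" for Miniception (so the density
    bound 2/(w+1) keeps its usual meaning).
    """

    mode: BucketingMode
    k: int
    w: int
    window_unit: str  # "bases" | "kmers"
    n: int = 1
    alpha: float = 0.5
    beta: float = 2.0
    m: int = 3
    pt: float = 0.6
    k0: int | None = None  # Miniception inner k-mer length
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.n < 1:
            raise ParameterError(f"n must be >= 1, got {self.n}")
        if self.window_unit not in ("bases", "kmers"):
            raise ParameterError(f"bad window_unit {self.window_unit!r}")
        if self.window_unit == "bases" and self.w < self.k:
            raise ParameterError(
                f"window of {self.w} bases cannot hold a {self.k}-mer")
        if self.w < 1:
            raise ParameterError("window must be >= 1")
        if not (0 < self.pt <= 1):
            raise ParameterError(f"pt must be in (0, 1], got {self.pt}")
        if not (0 < self.alpha <= 1):
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.k0 is not None and not (1 <= self.k0 < self.k):
            raise ParameterError(f"k0 must satisfy 1 <= k0 < k, got {self.k0}")


@dataclass(frozen=True)
class ParamEstimate:
    p1_bound: float
    collision_bound: float
    chosen_k: int
    chosen_w: int


def _segment_len(l: int, n: int) -> int:
    return l // n


def p1_lower_bound(l: int, n: int, k: int, dmax: int) -> float:
    """Lower bound on the probability of selecting an unmutated k-mer from
    one of n segments when dmax substitutions are spread evenly."""
    s = _segment_len(l, n)
    positions = s - k + 1
    if positions < 1:
        raise ParameterError(f"no {k}-mer fits a segment of {s} bases")
    p1 = (positions - (dmax / n) * k) / positions
    return max(0.0, min(1.0, p1))


def collision_lower_bound(l: int, k: int, n: int, dmax: int) -> float:
    """Lower bound on the probability that two reads at edit distance dmax
    (evenly spread) share at least one unmutated segment minimizer."""
    s = _segment_len(l, n)
    positions = s - k + 1
    if positions < 1:
        raise ParameterError(f"no {k}-mer fits a segment of {s} bases")
    miss = (dmax * k) / (positions * n)
    return max(0.0, min(1.0, 1.0 - miss ** n))


def select_k_segmented(l: int, n: int, pt: float,
                       dmax_conservative: int = 5) -> int:
    """Largest k such that a three-substitution segment still keeps the
    unmutated-k-mer miss chance below pt, the segments hold comfortably
    more k-mer positions than dmax_conservative mutations cover, and the
    k-mer space dwarfs the number of k-mer positions (4^k > 10 (l-k+1))."""
    if not (0 < pt <= 1):
        raise ParameterError(f"pt must be in (0, 1], got {pt}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    s = _segment_len(l, n)
    best = None
    reasons = []
    for k in range(3, s + 1):
        positions = s - k + 1
        if not (3 * k / (positions * n) < pt):
            reasons.append(f"k={k}: 3k/((S-k+1)n) >= pt")
            continue
        if not (positions * n > dmax_conservative * k):
            reasons.append(f"k={k}: (S-k+1)n <= {dmax_conservative}k")
            continue
        if not (4 ** k > 10 * (l - k + 1)):
            reasons.append(f"k={k}: 4^k <= 10(l-k+1)")
            continue
        best = k
    if best is None:
        raise ParameterError(
            f"no feasible k for l={l}, n={n}, pt={pt}; "
            f"violations: {reasons[-3:] if reasons else 'k range empty'}")
    return best


def window_from_alpha(l: int, n: int, alpha: float) -> int:
    """Window size in bases, w = floor(alpha * floor(l/n))."""
    if not (0 < alpha <= 1):
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    return int(alpha * _segment_len(l, n))


def select_k_miniception(l: int, m: int, beta: float) -> tuple[int, int]:
    """(k, w in k-mers) minimizing |m/(l-k+1) - 2/(w+1)| with w = ceil(beta*k),
    subject to the window fitting the read (w + k - 1 <= l).  Ties toward
    smaller k; solved by exhaustive integer scan for reproducibility."""
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    if beta <= 1:
        raise ParameterError(f"beta must be > 1, got {beta}")
    best: tuple[float, int, int] | None = None
    for k in range(3, l):
        w = math.ceil(beta * k)
        if w + k - 1 > l:
            break
        gap = abs(m / (l - k + 1) - 2 / (w + 1))
        if best is None or gap < best[0]:
            best = (gap, k, w)
    if best is None:
        raise ParameterError(
            f"no k in [3, {l - 1}] admits a fitting Miniception window "
            f"(beta={beta}) for l={l}")
    return best[1], best[2]


def gomh_k(l: int, dt: int, p2: float) -> int:
    """Gapped k-mer length k' = (l+2)(1-p2) / (2 + dt - 2 p2), rounded to
    the nearest integer (half up) and clamped to [2, floor((l+1)/2)].

    The formula solves the gapped-k-mer collision bound
    p2 = (l - 2k' + 2 - dt k') / (l - 2k' + 2) for k' at equality.
    """
    if not (0 < p2 < 1):
        raise ParameterError(f"p2 must be in (0, 1), got {p2}")
    if dt < 1:
        raise ParameterError(f"dt must be >= 1, got {dt}")
    upper = (l + 1) // 2
    if upper < 2:
        raise ParameterError(f"read length {l} too short for any gapped 2-mer")
    kp = (l + 2) * (1 - p2) / (2 + dt - 2 * p2)
    kp_round = math.floor(kp + 0.5)
    return max(2, min(upper, kp_round))


def default_segment_count(l: int, dmax: int) -> int:
    """n = min(dmax, max(1, floor(l/32))): segments must hold several
    k-mers and the collision-bound model requires n <= dmax."""
    return max(1, min(dmax, max(1, l // 32)))


def select_k_umi(l: int, pt: float) -> int:
    """Stage-1 k for short tags (8-12 nt): largest k >= 3 with
    k/(l-k+1) < pt, i.e. the miss chance of a *single* differing base stays
    below pt.  Short tags rarely carry more than one error per window, and
    the sketching + traversal stages run on all bins in UMI mode anyway."""
    best = None
    for k in range(3, l + 1):
        if l - k + 1 >= 1 and k / (l - k + 1) < pt:
            best = k
    if best is None:
        raise ParameterError(f"no feasible UMI k for l={l}, pt={pt}")
    return best


def estimate_bucketing_params(
    l: int,
    mode: BucketingMode | str,
    dmax: int,
    *,
    pt: float = 0.6,
    alpha: float = 0.5,
    beta: float = 2.0,
    m: int = 3,
    n: int | None = None,
    k0: int | None = None,
    order_seed: int = 0,
    umi: bool = False,
) -> BucketingParams:
    """Derive a full :class:`BucketingParams` for one mode at read length l.

    For random-minimizer modes k comes from :func:`select_k_segmented` at
    the (default or overridden) segment count, and the window is
    floor(alpha * floor(l/n)) bases — also for the whole-read variant,
    where the same k remains valid over the un-segmented read.  Miniception
    modes take (k, w) from the density matching scan; the segmented variant
    substitutes the segment length and ceil(m/n) expected minimizers.
    """
    mode = BucketingMode(mode)
    n_est = n if n is not None else default_segment_count(l, dmax)
    if n_est < 1:
        raise ParameterError(f"n must be >= 1, got {n_est}")
    n_used = n_est if mode.segmented else 1

    if mode.miniception:
        if mode.segmented:
            seg = _segment_len(l, n_est)
            k, w = select_k_miniception(seg, max(1, math.ceil(m / n_est)), beta)
        else:
            k, w = select_k_miniception(l, m, beta)
        inner = k0 if k0 is not None else min(k - 1, max(3, k - w))
        inner = max(1, inner)
        return BucketingParams(
            mode=mode, k=k, w=w, window_unit="kmers", n=n_used,
            alpha=alpha, beta=beta, m=m, pt=pt, k0=inner,
            order_seed=order_seed)

    if umi:
        k = select_k_umi(l, pt)
    else:
        try:
            k = select_k_segmented(l, n_est, pt)
        except ParameterError:
            # Short reads (l below ~24): the three-substitution margin of
            # select_k_segmented is infeasible; fall back to the
            # single-difference rule also used for short tags.
            k = select_k_umi(l, pt)
    w = window_from_alpha(l, n_est, alpha)
    if w < k:
        raise ParameterError(
            f"window {w} bases (alpha={alpha}, l={l}, n={n_est}) cannot hold "
            f"a {k}-mer; raise alpha or lower n")
    return BucketingParams(
        mode=mode, k=k, w=w, window_unit="bases", n=n_used,
        alpha=alpha, beta=beta, m=m, pt=pt, order_seed=order_seed)
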