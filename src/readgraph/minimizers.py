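"""Minimizer sampling (random minimizer and Miniception) and read bucketing.

The k-mer ordering O is defined by a keyed 64-bit hash (blake2b with the
seed as key); comparison falls back to the k-mer string itself on equal
hash values, so the order is total.  Window shifting uses robust
winnowing: within a window the minimum-order k-mer is chosen (rightmost on
ties), and on a shift the minimizer only changes if a strictly smaller
k-mer enters or the current minimizer falls out of the window — a rule
that stabilizes selection on repeats.

Miniception restricts window minima to *charged* k-mers: those whose
minimum-order inner k0-mer (under an independently seeded inner order)
sits at the first or last offset.  Windows with no charged k-mer fall back
to the plain window minimum so that every window stays represented.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import UniqueReadSet
from .params import BucketingParams, BucketingMode

SHORT_READ_KEY = ("short",)


def order_hash(kmer: str, seed: int) -> int:
    """Deterministic 64-bit hash of a k-mer under a 64-bit seed."""
    h = hashlib.blake2b(kmer.encode(), digest_size=8,
                        key=(seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def derive_seed(master: int, *tags) -> int:
    """Derive an independent 64-bit seed from a master seed and tags by
    fixed mixing (keyed blake2b over the tag encoding)."""
    data = "\x1f".join(str(t) for t in tags).encode()
    h = hashlib.blake2b(data, digest_size=8,
                        key=(master & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def segment_read(sequence: str, n: int) -> list[str]:
    """Split into n parts: the first n-1 of exactly floor(l/n) bases, the
    last takes the remainder; concatenation reproduces the read."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    l = len(sequence)
    s = l // n
    parts = [sequence[i * s:(i + 1) * s] for i in range(n - 1)]
    parts.append(sequence[(n - 1) * s:])
    return parts


def _kmer_order(sequence: str, k: int, seed: int) -> list[tuple[int, str]]:
    return [(order_hash(sequence[i:i + k], seed), sequence[i:i + k])
            for i in range(len(sequence) - k + 1)]


def _rightmost_min(order: Sequence[tuple[int, str]], lo: int, hi: int) -> int:
    """Index of the rightmost minimum of order[lo:hi] under the total order."""
    best = lo
    for i in range(lo + 1, hi):
        if order[i] <= order[best]:
            best = i
    return best


def random_minimizer_occurrences(sequence: str, k: int, w_bases: int,
                                 seed: int) -> list[tuple[int, int]]:
    """Selected (k-mer position, key) occurrences under robust winnowing.

    A window spans w_bases bases (w_bases - k + 1 k-mers) and slides by one
    base; if the read is shorter than the window, the whole read is a
    single window.  Returns each occurrence at which the minimizer changed.
    """
    l = len(sequence)
    if l < k:
        return []
    order = _kmer_order(sequence, k, seed)
    wb = min(w_bases, l)
    span = wb - k  # window covers k-mer indices i .. i+span
    nwin = l - wb + 1
    cur = _rightmost_min(order, 0, span + 1)
    out = [(cur, order[cur][0])]
    for s in range(1, nwin):
        enter = s + span
        if cur < s:  # minimizer left the window: recompute
            cur = _rightmost_min(order, s, enter + 1)
            out.append((cur, order[cur][0]))
        elif order[enter] < order[cur]:  # strictly smaller enters
            cur = enter
            out.append((cur, order[cur][0]))
    return out


def random_minimizers(sequence: str, k: int, w_bases: int, seed: int) -> set[int]:
    """Set of distinct minimizer keys of a read (see occurrences variant)."""
    return {key for _, key in
            random_minimizer_occurrences(sequence, k, w_bases, seed)}


def _charged_flags(sequence: str, k: int, k0: int, inner_seed: int) -> list[bool]:
    """charged[i]: the minimum inner k0-mer of k-mer i (rightmost on ties)
    occurs at its first or last offset."""
    inner = _kmer_order(sequence, k0, inner_seed)
    nk = len(sequence) - k + 1
    last_off = k - k0
    flags = []
    for i in range(nk):
        best = _rightmost_min(inner, i, i + last_off + 1)
        flags.append(best == i or best == i + last_off)
    return flags


def miniception_occurrences(sequence: str, k: int, w_kmers: int, k0: int,
                            seed: int) -> list[tuple[int, int]]:
    """Selected (k-mer position, key) occurrences under Miniception.

    Each window of w_kmers consecutive k-mers contributes its minimum-order
    charged k-mer (rightmost on ties), falling back to the plain window
    minimum when no k-mer in the window is charged.
    """
    l = len(sequence)
    if l < k:
        return []
    if not (1 <= k0 < k):
        raise ValueError(f"require 1 <= k0 < k, got k0={k0}, k={k}")
    order = _kmer_order(sequence, k, seed)
    charged = _charged_flags(sequence, k, k0, derive_seed(seed, "inner", k0))
    nk = len(order)
    wk = min(w_kmers, nk)
    seen: set[int] = set()
    out: list[tuple[int, int]] = []
    for j in range(nk - wk + 1):
        best = None
        for i in range(j, j + wk):
            if charged[i] and (best is None or order[i] <= order[best]):
                best = i
        if best is None:  # charged-free window: plain minimum
            best = _rightmost_min(order, j, j + wk)
        if best not in seen:
            seen.add(best)
            out.append((best, order[best][0]))
    return out


def miniception_minimizers(sequence: str, k: int, w_kmers: int, k0: int,
                           seed: int) -> set[int]:
    return {key for _, key in
            miniception_occurrences(sequence, k, w_kmers, k0, seed)}


@dataclass
class BucketMap:
    """hash-key -> set of read ids, with a large-bucket classification.

    Keys are namespace-tagged tuples so keys from different stages never
    collide: ("m", key) for minimizer buckets, ("short",) for reads too
    short to yield a k-mer, ("g", perm_index, value) for sketch buckets.
    """

    buckets: dict = field(default_factory=dict)
    large_threshold: int = 10_000

    def __post_init__(self) -> None:
        if self.large_threshold < 2:
            raise ValueError("large_threshold must be >= 2")

    def add(self, key, read_id: int) -> None:
        self.buckets.setdefault(key, set()).add(read_id)

    def is_large(self, key) -> bool:
        return len(self.buckets[key]) >= self.large_threshold

    def normal_items(self):
        """(key, ids) of buckets below the large threshold, key-sorted."""
        return [(k, v) for k, v in sorted(self.buckets.items())
                if len(v) < self.large_threshold]

    def large_items(self):
        return [(k, v) for k, v in sorted(self.buckets.items())
                if len(v) >= self.large_threshold]

    def large_read_ids(self) -> set[int]:
        out: set[int] = set()
        for _, ids in self.large_items():
            out |= ids
        return out

    def member_ids(self) -> set[int]:
        out: set[int] = set()
        for ids in self.buckets.values():
            out |= ids
        return out


def read_minimizer_keys(sequence: str, params: BucketingParams) -> set[int]:
    """All distinct minimizer keys of one read under a mode; empty if the
    read (or every segment) is too short to hold a k-mer."""
    segments = (segment_read(sequence, params.n)
                if params.n > 1 else [sequence])
    keys: set[int] = set()
    for seg in segments:
        if len(seg) < params.k:
            continue
        if params.mode.miniception:
            keys |= miniception_minimizers(
                seg, params.k, params.w, params.k0, params.order_seed)
        else:
            keys |= random_minimizers(
                seg, params.k, params.w, params.order_seed)
    return keys


def bucket_reads(reads: UniqueReadSet, params: BucketingParams,
                 large_threshold: int = 10_000) -> BucketMap:
    """Assign every read to one bucket per distinct minimizer key; reads
    yielding no k-mer at all go to a single dedicated short-read bucket."""
    bmap = BucketMap(large_threshold=large_threshold)
    for rec in reads:
        keys = read_minimizer_keys(rec.sequence, params)
        if not keys:
            bmap.add(SHORT_READ_KEY, rec.id)
        else:
            for key in keys:
                bmap.add(("m", key), rec.id)
    return bmap
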