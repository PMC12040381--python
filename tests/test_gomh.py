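import numpy as np
import pytest
from hypothesis import given, strategies as st

from readgraph import (gapped_kmers, gomh_bucket, gomh_k, gomh_value,
                       make_permutations)
from readgraph.gomh import GOMH_SHORT_KEY, GomhPermutation, combine_hash
from .conftest import random_sequence, substitute

dna = st.text(alphabet="ACGT", min_size=3, max_size=80)


class TestGappedKmers:
    def test_worked_example(self):
        # The two stride-2 3-mers of AGCTAGT starting at offsets 0 and 1
        # are ACA and GTG; the full list has l - 2k + 2 = 3 entries.
        out = gapped_kmers("AGCTAGT", 3)
        assert out == ["ACA", "GTG", "CAT"]
        assert "ACA" in out and "GTG" in out
        assert len(out) == 7 - 2 * 3 + 2

    def test_homopolymer(self):
        assert gapped_kmers("AAAAAA", 2) == ["AA", "AA", "AA", "AA"]

    def test_too_short_returns_empty(self):
        assert gapped_kmers("ACGT", 3) == []

    @given(seq=dna, kp=st.integers(2, 10))
    def test_count_formula_and_stride(self, seq, kp):
        out = gapped_kmers(seq, kp)
        l = len(seq)
        if l < 2 * kp - 1:
            assert out == []
        else:
            assert len(out) == l - 2 * kp + 2
            for i, gk in enumerate(out):
                assert gk == "".join(seq[i + 2 * j] for j in range(kp))


class TestGomhValue:
    def test_golden_combine_values(self):
        assert combine_hash(0, "AA", 1) == 10112150037160445558
        assert combine_hash(0, "AA", 2) == 15063085362212791768
        assert combine_hash(5, "ACA", 1) == 14779061760842167182

    def test_occurrence_counter_distinguishes_repeats(self):
        # AAAAAA yields four identical gapped 2-mers whose hash inputs
        # differ only in the occurrence counter.
        perm = GomhPermutation(seed=0, kprime=2, dt=1)
        vals = {combine_hash(0, "AA", c) for c in range(1, 5)}
        assert len(vals) == 4
        assert gomh_value("AAAAAA", perm) == min(vals)

    def test_deterministic(self):
        perm = GomhPermutation(seed=42, kprime=3, dt=2)
        s = "ACGTACGTACGT"
        assert gomh_value(s, perm) == gomh_value(s, perm)

    def test_value_is_attained(self, rng):
        perm = GomhPermutation(seed=9, kprime=4, dt=1)
        for _ in range(20):
            seq = random_sequence(rng, 40)
            items = gapped_kmers(seq, 4)
            occ, hashes = {}, []
            for it in items:
                occ[it] = occ.get(it, 0) + 1
                hashes.append(combine_hash(9, it, occ[it]))
            assert gomh_value(seq, perm) == min(hashes)

    def test_sentinel_for_too_short(self):
        assert gomh_value("ACG", GomhPermutation(seed=0, kprime=5, dt=1)) is None

    def test_distance1_selection_and_collision_bounds(self, rng):
        # p2 = (l - 2k' + 2 - dt k') / (l - 2k' + 2) = 84/90 bounds the
        # probability that the sketch minimum of ONE read avoids the
        # mutated gapped k-mers.  The pair-collision frequency is lower
        # (the partner read's freshly hashed k-mers can shadow the shared
        # minimum) but is bounded below by both reads selecting an
        # unmutated minimum, i.e. by p2^2.
        l, kp = 100, 6
        p2 = (l - 2 * kp + 2 - kp) / (l - 2 * kp + 2)
        perms = [GomhPermutation(seed=int(rng.integers(2 ** 31)),
                                 kprime=kp, dt=1) for _ in range(50)]
        unmut_hits = coll_hits = trials = 0
        for _ in range(100):
            s1 = random_sequence(rng, l)
            pos = int(rng.integers(l))
            s2 = substitute(rng, s1, [pos])
            mutated_starts = {pos - 2 * j for j in range(kp)}
            items = gapped_kmers(s1, kp)
            for perm in perms:
                v1, v2 = gomh_value(s1, perm), gomh_value(s2, perm)
                coll_hits += v1 == v2
                occ: dict = {}
                argmin, best = 0, None
                for i, it in enumerate(items):
                    occ[it] = occ.get(it, 0) + 1
                    h = combine_hash(perm.seed, it, occ[it])
                    if best is None or h < best:
                        argmin, best = i, h
                unmut_hits += argmin not in mutated_starts
                trials += 1
        se = np.sqrt(p2 * (1 - p2) / trials)
        assert unmut_hits / trials >= p2 - 3 * se
        lo = p2 ** 2
        se2 = np.sqrt(lo * (1 - lo) / trials)
        assert coll_hits / trials >= lo - 3 * se2


class TestMakePermutations:
    def test_one_per_dt(self):
        perms = make_permutations(100, 1, 5, 0.8)
        assert [p.dt for p in perms] == [1, 2, 3, 4, 5]
        assert all(p.kprime == gomh_k(100, p.dt, 0.8) for p in perms)

    def test_floor_repetition(self):
        perms = make_permutations(100, 1, 1, 0.8, floor=3)
        assert [p.dt for p in perms] == [1, 1, 1]
        assert len({p.seed for p in perms}) == 3

    def test_deterministic_for_master_seed(self):
        a = make_permutations(100, 1, 3, 0.8, master_seed=77)
        b = make_permutations(100, 1, 3, 0.8, master_seed=77)
        assert a == b
        c = make_permutations(100, 1, 3, 0.8, master_seed=78)
        assert a != c

    def test_count_invariant(self):
        for dmin, dmax, floor in [(1, 5, 3), (1, 1, 3), (2, 3, 4)]:
            perms = make_permutations(80, dmin, dmax, 0.8, floor=floor)
            assert len(perms) == max(dmax - max(1, dmin) + 1, floor)


class TestGomhBucket:
    def test_identical_reads_cobucket_under_every_permutation(self, rng):
        seq = random_sequence(rng, 50)
        perms = make_permutations(50, 1, 3, 0.8)
        bmap = gomh_bucket([(0, seq), (1, seq)], perms)
        assert all(ids == {0, 1} for ids in bmap.buckets.values())
        assert len(bmap.buckets) == len(perms)

    def test_planted_pairs_cobucket_with_high_frequency(self, rng):
        l = 100
        perms = make_permutations(l, 1, 3, 0.8, master_seed=5)
        reads, pairs = [], []
        for i in range(250):
            s1 = random_sequence(rng, l)
            s2 = substitute(
                rng, s1, rng.choice(l, size=int(rng.integers(1, 4)),
                                    replace=False))
            reads += [(2 * i, s1), (2 * i + 1, s2)]
            pairs.append((2 * i, 2 * i + 1))
        bmap = gomh_bucket(reads, perms)
        member = {}
        for key, ids in bmap.buckets.items():
            for i in ids:
                member.setdefault(i, set()).add(key)
        hit = sum(bool(member[a] & member[b]) for a, b in pairs)
        assert hit / len(pairs) >= 0.9

    def test_unrelated_reads_rarely_cobucket(self, rng):
        perms = make_permutations(100, 1, 3, 0.8, master_seed=6)
        reads = [(i, random_sequence(rng, 100)) for i in range(60)]
        bmap = gomh_bucket(reads, perms)
        shared = 0
        member = {}
        for key, ids in bmap.buckets.items():
            for i in ids:
                member.setdefault(i, set()).add(key)
        total = 0
        for i in range(60):
            for j in range(i + 1, 60):
                total += 1
                shared += bool(member[i] & member[j])
        assert shared / total < 0.05

    def test_splitting_power_on_forced_large_bucket(self, rng):
        # 2,000 otherwise-random reads sharing one minimizer-length core:
        # at least one sketching permutation must cut the maximum bucket
        # size by >= 10x.  (A single permutation can collapse by chance
        # when the shared core's minimal gapped k-mer draws a tiny hash;
        # such residual large bins are the traversal stage's job.)
        core = random_sequence(rng, 14)
        reads = []
        for i in range(2_000):
            s = random_sequence(rng, 100)
            pos = int(rng.integers(0, 86))
            reads.append((i, s[:pos] + core + s[pos + 14:]))
        perms = make_permutations(100, 1, 3, 0.8, master_seed=3)
        bmap = gomh_bucket(reads, perms)
        per_perm_max = {}
        for (_, idx, _v), ids in bmap.buckets.items():
            per_perm_max[idx] = max(per_perm_max.get(idx, 0), len(ids))
        assert min(per_perm_max.values()) <= 2_000 / 10

    def test_short_reads_routed_whole(self):
        perms = [GomhPermutation(seed=1, kprime=5, dt=1)]
        bmap = gomh_bucket([(0, "ACGT")], perms)
        assert bmap.buckets == {GOMH_SHORT_KEY: {0}}

    def test_all_candidate_fallback_counts(self):
        # 11-mers with k'=4 have 11 - 8 + 2 = 5 gapped candidates; with
        # 5 permutations the fallback buckets once per distinct candidate.
        seq = "ACGTACGTACG"
        perms = [GomhPermutation(seed=i, kprime=4, dt=1) for i in range(5)]
        assert len(gapped_kmers(seq, 4)) == 5
        bmap = gomh_bucket([(7, seq)], perms, all_candidate_fallback=True)
        cands = set(gapped_kmers(seq, 4))
        assert set(bmap.buckets) == {("ga", 4, c) for c in cands}
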