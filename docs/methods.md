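# Methods

## Model and scope

`readgraph` constructs, for a set of short DNA/RNA sequences over
{A, C, G, T, N} (U mapped to T on input), the undirected graph whose
nodes are the unique sequences (with observed frequency as a node
attribute) and whose edges connect pairs at Levenshtein distance within
[dmin, dmax], weighted by that distance. All candidate pairs are verified
with an exact threshold-bounded distance computation (edlib's banded
bit-vector global alignment; a pair is dismissed without alignment when
the length difference alone exceeds dmax). The heuristics therefore
control *recall only*: the found edge set is a subset of the brute-force
ground truth by construction, and completeness |E_found|/|E_truth| is the
single quality measure. N is an ordinary fifth symbol (N↔N costs 0,
N↔anything-else costs 1) and reads containing it are processed like any
other — the simplest rule consistent with keeping N in the alphabet.

Construction always works on the interval [1, dmax]; dmin > 1 is applied
only at finalization, because small-weight edges are the stepping stones
the traversal stage walks over.

A global seen-pairs set deduplicates evaluations across buckets and
stages, so permuting bucket processing order cannot change the result and
no pair's distance is ever computed twice. Execution is sequential; the
`threads` config field is accepted as a hint with the contract that any
parallel schedule must reproduce the sequential edge set exactly.

## Stage 1: minimizer bucketing

The k-mer ordering is a keyed 64-bit blake2b hash; ties (only possible
for equal hash values) fall back to lexicographic order on the k-mer
string, making the order total, and the rightmost minimal occurrence is
chosen within a window. Window shifting uses robust winnowing. A read
joins one bucket per *distinct* minimizer key; this multiplies bucket
memberships but maximizes the chance that a similar pair co-buckets, and
the seen-pairs set absorbs the redundancy. Reads (or segments) too short
to hold a k-mer go to a single dedicated short-read bucket that is
processed like any other.

Parameter defaults, all CLI-exposed:

| parameter | default | role |
|---|---|---|
| pt | 0.6 | cap on 3k/((S−k+1)n), drives k for random modes |
| α | 0.5 | window w = ⌊α·⌊l/n⌋⌋ bases, random modes |
| m | 3 | wanted minimizers per read, Miniception k selection |
| β | 2.0 | Miniception window w = ⌈β·k⌉ (in k-mers) |
| p2 | 0.8 | per-permutation gOMH collision target |
| n | min(dmax, max(1, ⌊l/32⌋)) | segment count, segmented modes |
| large threshold | 10 000 | bucket size at which a bin is "large" |

At l = 100, dmax = 3 these yield k = 12, w = 16, n = 3 (segmented
random), the same k for whole-read random (the segmented estimate remains
valid over the unsegmented read, with w computed from the segment size),
and k = 25, w = 50 k-mers for Miniception. The window unit differs by
scheme deliberately: a window of w *bases* holds w − k + 1 k-mers (random
modes), while the Miniception density bound 2/(w+1) counts w in k-mers.

Two selection rules beyond the closed forms:

- The "k-mer space must dwarf the k-mer positions" condition is
  operationalized as 4^k > 10·(l − k + 1). For reads shorter than ~24 nt
  this margin is unsatisfiable for any k compatible with the pt cap, so
  parameter estimation falls back to the single-difference rule (largest
  k ≥ 3 with k/(l − k + 1) < pt) — the same rule used for UMIs, and the
  appropriate model when a window rarely contains more than one error.
- Miniception's inner length defaults to k0 = max(3, k − w) clamped to
  ≤ k − 1, with an independently derived inner seed. Windows with no
  charged k-mer fall back to the plain window minimum so every window
  stays represented (completeness is preferred over density purity; the
  measured density, 0.93× the bound at (k=25, w=50), stays below 2/(w+1)
  regardless).

## Stage 2: gapped Order-Min-Hash

Large buckets cannot be split by the very substring their members share,
so their unique reads (deduplicated across buckets) are re-bucketed by an
order-sensitive sketch over gapped k-mers. One permutation is created per
target distance dt in [dmin, dmax], with fresh seeds cycled in when the
interval yields fewer than 3 permutations. The sketch is single-pass: a
running per-string occurrence counter feeds the hash, so repeated gapped
k-mers hash distinctly and no second pass or partial sorting is needed.
k′ is re-derived from each read's own length (it is a function of l),
clamped at 2 with a warning for very short reads.

Note that p₂ bounds the probability that *one read's* sketch minimum
avoids its mutated gapped k-mers; the pair-collision probability is lower
(≈ p₂², since the partner's freshly hashed k-mers can shadow the shared
minimum — measured 0.889 vs p₂ = 0.933 at l = 100, k′ = 6, dt = 1).
Multiple permutations close the gap. A related tail effect: when the
shared core's minimal gapped k-mer happens to draw a very small hash, one
permutation can collapse most of a forced-collision bucket into a single
bin; in practice at least one permutation (the one whose gapped span
exceeds the shared core) splits such buckets by orders of magnitude, and
any residual large bins fall through to the traversal stage, which exists
for exactly this case.

## Stage 3: neighbourhood traversal

For reads of bins still large after sketching, a BFS from each target
node (ascending-id order, 2 passes by default, stopping early when a pass
adds nothing; hop budget 3·dmax) nominates every node within the budget
as a candidate, and each unseen candidate pair is distance-verified. The
budget is measured in hops, not accumulated path weight — the natural
reading of "a few times dmax away" on a graph whose edges all weigh
≤ dmax — and both the multiplier and the pass cap are configurable,
including a fixpoint mode (max_passes=0) that provably completes
connected components. The triangle inequality motivates the candidate
set; it never determines a weight.

## UMI mode

8–12 nt tags leave no room for segmentation (it is rejected with an
explanation). Stage-1 k uses the single-difference rule (k = 4 at
l = 11–12, pt = 0.6); and because one minimizer round misses many edges
at these lengths, the sketching *and* traversal stages run over the
unique sequences of normal bins as well, not only large ones. When a
read's gapped k-mer candidate count (l − 2k′ + 2) does not exceed the
permutation count, min-hash selection is pointless and the read is
bucketed once per distinct candidate instead.

## Synthetic benchmark

The generator emulates the structure that makes real error-laden read
sets graph-friendly: uniform-random templates, each spawning variants at
j ~ U{1..dmax_plant} edits (80% substitution, 10% insertion, 10% deletion
by default; substitution-only for fixed-length UMI sets) at distinct
random positions, with frequencies from a geometric law (p = 0.5,
truncated at 1 000) so singletons dominate. Ground truth is always
*recomputed* by the brute-force oracle, never read off the construction —
planted edits can compose or cancel. What the generator does **not**
emulate: position-dependent error profiles, PCR amplification chains
(errors-on-errors), quality scores, and genomic repeat structure. Passing
completeness bands on this benchmark therefore demonstrates the
bucketing/recovery machinery under spread-out edits — close to the
worst case for minimizer survival — but not performance on any
particular instrument's error spectrum.

Default problem sizes are desk-scale by design: ~2 000 unique 100-mers
(reads presets) and ~5 000 unique 12-mers (UMI preset), small enough that
the quadratic oracle and several full pipeline runs complete in minutes
on one CPU. One consequence is structural: buckets never reach the 10 000
default large-bucket threshold at these sizes, so the sketching and
traversal stages are exercised by dedicated forced-collision fixtures and
by the UMI mode (which runs them on normal bins) rather than by the
read presets.

## Known limitations

- Miniception whole-read mode is sparse by design (m ≈ 3 bucket keys per
  read at k = 25): on the synthetic presets, where distance-3 pairs carry
  evenly spread edits and no bucket is large enough to trigger the
  recovery stages, its completeness is far below the other modes
  (~0.65 vs ≥ 0.99). At production scale large buckets form and the
  sketching stage closes most of the gap; at desk scale prefer the
  random-minimizer modes or Miniception with segmentation.
- No reverse-complement canonicalization: reads are compared as literal
  strings.
- The brute-force oracle and `evaluate_run` are intended for ≤ ~5 000
  unique reads.
- Bounds (p₁, P, p₂) assume evenly distributed differences; clustered
  real-data errors make them conservative.
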