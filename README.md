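# readgraph

Edit-distance graphs over large sets of unique short reads and UMIs,
without the quadratic all-pairs scan.

## The problem

Error correction, deduplication and UMI collapsing all start from the same
object: given a read set *R*, find every pair of unique reads whose
Levenshtein distance lies in a small interval [*d*min, *d*max] (typically
[1, 3–5] for reads, [1, 1–2] for 8–12 nt molecular tags), and assemble the
pairs into an undirected graph — nodes are unique reads annotated with
their observed frequency, edges are weighted by the exact edit distance.
Brute force costs O(|R|²) distance computations and is impractical beyond
a few hundred thousand unique reads.

`readgraph` builds the graph heuristically with three cascaded stages,
each catching pairs the previous one missed:

1. **Minimizer bucketing.** Each read is assigned to one bucket per
   distinct minimizer — the smallest k-mer under a seeded hash ordering
   within a sliding window (robust winnowing: the minimizer changes only
   when a strictly smaller k-mer enters or the current one leaves the
   window). Four modes: random minimizer or the density-bounded
   Miniception scheme, each over the whole read or over *n* independent
   read segments. Exact distances are computed only within buckets below
   a size threshold (default 10 000). Parameters come from closed-form
   collision bounds: for segment length *S* = ⌊*l*/*n*⌋,

   p₁ ≥ (S − k + 1 − (*d*max/*n*)·k) / (S − k + 1),
   P ≥ 1 − (1 − p₁)ⁿ,

   with k the largest value keeping 3k/((S−k+1)·n) below a threshold
   probability p_t, and w = ⌊α·S⌋. Miniception instead matches its
   density bound 2/(w+1) to a wanted m minimizers per read via
   m/(l−k+1) ≈ 2/(w+1), w = ⌈β·k⌉.

2. **Gapped Order-Min-Hash (gOMH).** Reads stuck in large buckets share a
   substring, so minimizers cannot split them further. They are
   re-bucketed by a locality-sensitive sketch over *gapped* k-mers (k
   bases at stride 2; a read of length l has l − 2k′ + 2 of them). One
   single-pass permutation per target distance d_t hashes each gapped
   k-mer together with a seed and its running occurrence count and keeps
   the minimum; k′ = (l+2)(1−p₂)/(2 + d_t − 2p₂) targets a per-permutation
   collision probability p₂.

3. **Neighbourhood traversal.** For buckets that stay large even after
   sketching, each member's ≤ 3·*d*max-hop BFS neighbourhood in the
   partially built graph nominates candidate partners (justified by the
   triangle inequality on exact distances); every candidate pair is then
   distance-verified — the triangle inequality never assigns weights.

The working interval is always [1, *d*max]; edges below *d*min are removed
only at finalization, so small-distance edges remain available as
stepping stones for the traversal. Every reported edge is an exactly
computed distance: the heuristics only decide *which* pairs get checked,
so the found edge set is always a subset of the ground truth and quality
is a single number — completeness, the fraction of brute-force edges
recovered.

## Worked example

Generate a synthetic benchmark — 2 000 unique 100-mers in clusters of
planted ≤ 3-edit variants with skewed frequencies — then build, and score
against the brute-force oracle:

```bash
readgraph simulate --preset reads-small -o sim --seed 3
readgraph build -i sim/reads.fasta -o built --dmin 1 --dmax 3 \
    --mode random_whole --seed 3
readgraph ground-truth -i sim/reads.fasta -o gt --dmax 3
readgraph evaluate --found built/edges.tsv --truth gt/truth_edges.tsv
```

which prints:

```
2000 nodes, 2469 edges; per-stage edges: {'minimizer': 2469, 'gomh': 2469, 'traversal': 2469}
2000 unique reads, 2469 ground-truth edges
found=2469 truth=2469 completeness=1.0000
```

All 2 469 pairs at edit distance 1–3 were recovered (completeness 1.0),
and here the minimizer stage alone found them — the gOMH and traversal
counts show the per-stage progression, which only grows on sets large
enough to form ≥ 10 000-read buckets. `built/nodes.tsv` holds
(id, sequence, frequency), `built/edges.tsv` holds
(id_a, id_b, edit_distance); outputs are byte-identical for a fixed
`--seed`. Use `build-umi` for 8–12 nt tag sets (it additionally runs the
sketching and traversal stages over normal-sized bins, where a single
minimizer round misses too many edges), `params` to inspect the estimated
(k, w, n, k′), and `--mode`/`--pt`/`--alpha`/`--beta`/`--m`/`--p2` to
override any tuning parameter.

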