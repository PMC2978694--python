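# Methods

## Coordinate conventions

Domain alignments live in a fixed 71-column frame; columns are 1-based.
Columns 15/16 are the specificity pair, 17–20 the recognition-helix
tetramer used for the subgroup restriction (TVSR), 51/54 the structural
hinge residues. All nucleotide coordinates are 0-based half-open on the
sense strand of the named region. A 14-bp site is two 7-bp half sites;
half-site position NT-k of the left arm sits at site index 7−k, and the
right arm occupies indices 7–13 as the reverse complement of a half site in
the same coordinates, so the right arm's (NT-5, NT-4) are read on the
complementary strand at indices 11/10. Sites with the central inserted base
(NT-2bis, 15 bp) are normalized by deleting index 7 before quartet
extraction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular genome:

* **Domains.** Per family, one random consensus residue per column; each
  sequence matches it with probability 0.7 (per-column conservation noise),
  with the specificity/structural columns overwritten deterministically.
* **Regions.** Strict regions are i.i.d. background nucleotides (default
  uniform 0.25 each, configurable to skewed compositions) of ≤200 bp;
  extended regions are always 250 bp — upstream padding, the strict slice,
  and 50 bp of "coding" background — so a planted site has identical
  coordinates in both up to the strict offset.
* **Sites.** The half-site backbone is `T G (NT-5) (NT-4) A (var) C`:
  NT-6 = G and the central C are fixed, NT-7 = T and NT-3 = A match with
  per-position identity 0.9 (otherwise a uniform draw from the other three
  bases), NT-2 is uniform. The (NT-5, NT-4) slots come from the planted
  code. Each half site is sampled independently, so planted sites are
  palindromic in expectation but not letter-perfect — matching how real
  operators scatter around their consensus.
* **Degeneracy.** Per class: `none` (one palindrome), `sym_intrinsic`
  (each half site drawn independently from the class entries — palindromes
  and mixtures all populated), `asym_intrinsic` (each monomer prefers the
  dominant half with probability √p, so the dominant-*palindrome* fraction
  is p), `extrinsic` (each TF locked to one palindrome of a partition; no
  mixtures can occur). The three benchmark scenarios map onto these:
  shared high affinity = independent equiprobable halves (mixture mass
  1/2); preferential = monomer preference p (default 0.85; at p = 1 the
  output degenerates to pure palindromes with no mixtures); exclusive = two
  pseudo-TFs with disjoint palindromes.

What the generator does **not** emulate: operon structure, phylogenetic
autocorrelation between family members (sequences are exchangeable within a
class), skewed genome compositions by default, or multi-site operons with
cooperative spacing. Passing benchmarks therefore demonstrate that the
machinery recovers the planted structure under the stated noise model, not
that it would perform identically on genomes with strong compositional bias
or correlated paralogs.

## Footprint stage (palindromic Gibbs sampler)

Zero-or-one site per region; the Bernoulli occupancy prior is set so the
prior expected site total equals the configured value (default: the number
of regions, which drives the prior to its always-occupied limit; the code
caps it at 0.999). The motif model is a position frequency matrix with a
background-weighted pseudocount (1 by default), averaged with its reverse
complement before every use — the model matrix equals its own reverse
complement exactly at all times. Chains (default 4) of 1600 sweeps with a
400-sweep burn-in are run from independent random initializations; every
25 sweeps a joint phase-shift move proposes translating all sites by up to
half a motif width, sampled by joint model score.

**Phase polish.** A palindromic motif admits self-consistent shifted
states: a coherent ±1 drift and its strand mirror score identically under a
strand-symmetric model, and a ±7 shift swaps half sites. Pooled sampling
does not always escape these, so the reporting stage realigns the kept
sites greedily (leave-one-out, within half a width) restarted from every
global shift of the configuration, keeping the maximum-likelihood result.

**Confidence and filters.** A region's site is the modal sampled start
(pooled over chains, leftmost tie-break); its confidence is the pooled
fraction of post-burn-in samples within ±2 bp of it, and sites under the
40% cutoff are dropped. Because the sampler must place a site in every
region, a chance palindrome can still be reported consistently on pure
background; each kept site must therefore also beat the *best-window* score
distribution of 25 mononucleotide-shuffled copies of its own region
(p ≤ 0.05). This max-statistic check removes most, not all, chance motifs:
the residual selection bias operates at the level of the motif itself
(the best pattern across all regions), and is controlled statistically only
by the refinement stage's empirical null. On pure background the stage
reports confident sites in a small minority of regions in most runs, versus
essentially all regions when a motif is planted.

## Refinement stage

The PWM uses the constant-pseudocount rule, frequency = (count + B/4) /
(N + B) with B = 1, scored as log₂(frequency/background). The candidate
pool is fixed once: every window of the extended regions (best strand per
window; strands are equivalent for palindromic PWMs) scoring at least the
minimum seed-site score. Each iteration draws a fresh null of 10⁵ scores by
scanning whole-region mononucleotide shuffles, keeps candidates with
add-one empirical p < 10⁻³, resolves overlaps greedily (best score first,
≥50% overlap suppressed), rebuilds the PWM from the kept set and rescores —
until the kept set repeats (or 50 iterations). Final sites carry
Z = (score − null mean)/null SD and must pass Z ≥ 4. The pseudocount, null
size, α, Z floor and the fixed (non-retightened) candidate threshold are
all configuration parameters; the defaults above were chosen as standard
values of the respective estimators and are deliberately exposed because
results should be robust to them.

## Mutual information

Plug-in estimator in bits over paired columns, gap pairs deleted pairwise;
no small-sample bias correction by default (a first-order Miller–Madow
correction sits behind a flag). Constant columns give exactly 0. The
plug-in estimator's positive bias grows with column cardinality and shrinks
with the number of paired rows, so the covariation map is meaningful at
family scale (hundreds of domain/site pairs) and the benchmarks run it
there; on a few dozen pairs the maximum over all cells is noise-dominated.

## Degeneracy classification

F counts the 136 unordered quartet combinations (16 palindromic + 120
mixed). S is the subset of cells over-represented against the genomic
background (cell probability q_a² or 2·q_a·q_b; binomial upper tail;
Benjamini–Hochberg at 0.05 over the full 136-cell family, so a lone site in
an otherwise empty cell cannot reach significance). Classification:

1. **Extrinsic.** For each pair of significant palindromic cells, the
   expected mixture probability under independent half-site pairing is
   2·r_a·r_b with r estimated from the significant palindrome counts; a
   binomial lower tail (BH at the same level) flags significantly missing
   mixtures.
2. **Blocks.** Half-site types appearing in S are joined by significant
   mixture cells and by non-extrinsic significant palindrome pairs;
   extrinsic relations separate components.
3. **Intrinsic.** Within a block of k half types (n = sites whose quartet
   lies in the block), each palindrome is tested against the block-uniform
   expectation n/k² (binomial upper tail, BH). Any significant excess makes
   the block asymmetric with the largest such palindrome dominant
   (relations rendered minor→dominant); otherwise the block is symmetric.

The tie-break for the dominant palindrome is by count, then lexicographic.
The symmetric scenario is the null of both sub-tests, so its labelling
accuracy is 1 − type-I error (~92–97% at FDR 0.05) and does not increase
with the number of sites; detection power for the preferential and
exclusive scenarios does, and is the quantity checked for monotonicity.

## Code table

Per-class associations are the S-matrix palindromic cells with their
counts. The consensus logo weights classes, not sites: each class
contributes its majority-base consensus once (ties to the alphabetically
first base, logged), so populous classes cannot dominate. Triads count TFs
in the class, TFs with at least one surviving site, and surviving sites.

## Problem sizes and determinism

The standard benchmark study is 6 classes × 8 TFs, 150-bp strict regions,
site rate 0.8, swept over 10 seeds (~3 minutes on one CPU); the
mutual-information benchmark uses 6 × 60 domains with one known site each;
scenario labelling uses 100 replicates per scenario at n ∈ {10, 40, 160}.
Every stage takes an explicit seed and is deterministic given it; pipeline
reruns with the same configuration produce byte-identical outputs.

## Known limitations

* The footprint stage's false positives on motif-free region sets are
  only partially suppressed (see above); the refinement null is the real
  gate.
* Gap handling in the MI stage is pairwise deletion, appropriate because
  the curated frame rarely has gaps at the specificity columns; alignments
  with systematic gaps would need the gap-as-symbol variant.
* The degeneracy tests assume sites are exchangeable within a class; TF
  identity is used only by the extrinsic construction of the generator,
  not by the classifier (counts only), so dominance cannot be attributed
  to specific TFs.
* The spurious-nucleotide post-filter applied in some curation protocols is
  exposed only as a user-supplied predicate hook, not implemented.
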