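# Methods

## Problem and model

Long exact repeats confound short-read variant discovery.  `mcrkit` models
this with three connected components:

1. **Multi-copy sequence (MCS) discovery.**  A *seed* is a 300-bp window,
   tiled at 1-bp steps across every chromosome, that occurs exactly (no
   mismatches or indels) at two or more genomic loci; reverse-complement
   occurrences count by default.  Runs of consecutive seeds whose
   occurrences shift in lockstep merge into maximal shared blocks, and
   blocks with identical interval extents fuse into one MCS *group*: a
   shared sequence of length ≥ 300 bp plus every locus — a multi-copy
   region (MCR) — spelling it.  Matching is done by genome-wide exact
   window indexing (2-bit rolling codes), so *all* occurrences are
   enumerated with no multi-hit cap.
2. **A simulation study.**  SNVs are planted at one per kb in MCRs and in
   flanking control regions of matched total length; reads are drawn
   wgsim-style from the resulting diploid haplotypes over a factorial grid
   of read lengths {75, 150} × depths {10, 30, 50, 100}× with 20
   replicates per strategy (160 datasets); a seed-and-verify mapper with a
   strict unique-mapping filter and a threshold pileup caller recover
   variants, which are scored per stratum as accuracy = TP/(TP+FP),
   fp_rate = FP/(TP+FP), fn_rate = FN/(TP+FN).
3. **Enrichment testing.**  Overlap of MCRs with a feature set is compared
   against matched random regions (same number, same length multiset,
   non-overlapping, chromosome chosen ∝ length) over 1000 shuffles, with a
   per-shuffle 2×2 chi-squared — χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) —
   and an add-one two-sided empirical permutation p as the headline value.

## Merge semantics and maximality

For each unordered locus pair co-occurring in a seed, maximal runs of
window positions whose paired occurrences shift in lockstep (+1/+1 for
same-orientation pairs, +1/−1 for opposite) become blocks of length
`last_offset − first_offset + w`.  Blocks sharing identical interval
extents fuse into one group, so each group carries a constant locus set
and every reported group is maximal: extending all loci by one base on
either side breaks sequence identity or leaves the genome.  When a
sub-segment of a repeat has extra copies elsewhere, the full-length pair
remains one group and the higher-copy sub-block forms a second,
overlapping group; genome coverage is computed on the union.  Windows
containing `N` never participate in a match, so an `N` inside a repeat
splits it into its exact N-free sub-blocks.  A brute-force oracle
recomputes the identical decomposition by per-pair longest-common-
extension and is held to exact set equality with the finder in the tests.

## Synthetic genomes

Backgrounds are i.i.d. bases at GC 0.41 (human-like), so planted
duplications are the only repeats at window scale: the chance that two
300-mers collide in a ≤ 1 Mb background is < 1e-80, which makes
truth-vs-found comparisons sharp set equalities.  Planted copies are
dispersed (intra-/inter-chromosome, either strand) or tandem, each copy
flanked by ≥ 1 kb of background.  The bases immediately adjacent to the
copies of a group are made pairwise-distinct (up to 4 dispersed copies;
outer boundaries for tandem arrays), so no shared block extends past a
planted boundary through a chance 1-bp flank match — without this, a
planted L-mer is reported as L+1 or more with probability ≈ 1/2 per
group, and exact truth recovery would hold only up to boundary noise.
Per-copy divergence (default 0) exists solely to verify that non-exact
copies are never reported full-length.

What the generator does *not* emulate: real repeat families (Alu/LINE),
indel divergence, CNV dosage, GC-coverage bias, quality-score error
profiles.  Passing tests therefore demonstrate the *mechanism* — the
unique-mapping filter starving exact repeats of coverage — not calibrated
human-genome error rates.

## Read simulation, mapping and calling

* Insert size: normal, mean 400 sd 50 (midpoint of the 300–500 bp
  industry range), truncated to ≥ 2× read length; redraw-based truncation.
* Base error: uniform per-base substitution, default 0.01; constant
  Phred 35 qualities (the error model is positional, not quality-driven),
  so no quality-based read filter is applied.
* Heterozygous fraction 0.5; het variants land on one uniformly chosen
  haplotype, recorded per variant.
* Mapping: exact 31-mer anchors at both ends of both mates, candidate
  pairing constrained to fragment lengths within mean ± 4 sd, scored by
  total mismatches with a per-read cap of ceil(0.04 × read length); a
  windowed mate rescue handles mates whose anchors all carry errors.  A
  pair is retained only when exactly one concordant placement attains the
  minimum mismatch score — strict co-optimality, no mapping-quality
  heuristics.  Pairs fully interior to an exact repeat copy always tie
  across copies and are discarded; pairs with one mate reaching unique
  flank are disambiguated.  This is the mechanism that removes retained
  coverage from repeat interiors and drives the false-negative excess in
  MCRs.
* Calling: per-site thresholds depth ≥ 4, alt count ≥ 2, alt fraction
  ≥ 0.2; genotype hom at fraction ≥ 0.8; lexicographic alt tie-break.
  Calls outside both strata are tallied under an `other` stratum so
  mis-placed false positives are never dropped.

## Grid orchestration and problem sizes

Per-cell seeds derive from `SeedSequence([base_seed, read_length, depth,
replicate])`, making cells independent, bit-reproducible and resumable.
The default experiment uses two 500 kb chromosomes with ten 2-copy exact
duplications of 2–5 kb.  Fragments are sampled only from the evaluation
strata padded by the maximum fragment length (`restrict_to_strata`),
which preserves the per-base target depth inside every stratum while
skipping background sequence that can contribute no calls there; the
whole-genome sampler remains available (`restrict_to_strata=False`) and
is the default for the standalone simulator API.  These sizes keep the
full 160-dataset grid at desk scale while leaving dozens of planted
variants per stratum and replicate.

## Statistics

* Accuracy/FP/FN identities (accuracy + fp_rate = 1; |TP|+|FP| = calls,
  |TP|+|FN| = truth) hold by construction and are property-tested.
* Undefined ratios (empty called set) are reported as missing, never 0.
* Strategy comparisons use the classical pooled-variance two-sample
  t-test on per-replicate values; identical zero-variance groups get
  p = 1 by convention.  TP matching ignores genotype by default;
  genotype concordance is reported separately.
* The enrichment empirical p is the add-one two-sided permutation p,
  `min(1, 2·min(r_ge, r_le))` with `r_x = (1 + #{shuffles x observed}) /
  (n_sims + 1)`; a saturated statistic (every shuffle ties the observed
  count) yields p = 1.  Per-shuffle chi-squared tests are calibrated: with
  features themselves drawn from the shuffling law, p < 0.001 occurs at
  rate ≈ 0.001 (verified within binomial bounds in the tests).

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; VCF positions render
  1-based; BED stays 0-based.  1-based inclusive spans convert as
  `end1 − start1 + 1 = length`.
* Window enumeration uses exact 2-bit big-integer rolling codes (no hash
  collisions); the mapper index packs 31-mers into uint64.
* Palindromic self-matches (a window equal to its own reverse complement)
  are excluded from pair formation; they cannot arise in practice at
  window length 300 on non-degenerate sequence.
* Tandem arrays of ≥ 3 copies decompose into the overlapping shifted
  blocks that maximal-repeat semantics dictate (e.g. two overlapping 2L
  loci plus an L pair for a 3-copy array), not into three truth intervals;
  truth-recovery equality is asserted for dispersed configurations.
* An MCR occupying a whole chromosome gets no flank (warning); a
  chromosome shorter than the maximum fragment is excluded from read
  sampling (warning); unknown chromosomes in VCF extraction are skipped
  and counted (warning).

## Known limitations

* The mapper's uniqueness is exact co-optimality; aligners that pick one
  of several equal placements (mapping quality 0) leak mis-placed reads
  into repeat copies and so show *false-positive*-driven accuracy loss in
  MCRs beyond the coverage-starvation effect modelled here.
* Desk-scale synthetic genomes (≤ 1 Mb) cannot reproduce genome-scale
  repeat catalogues; the finder itself scales linearly in windows but the
  brute-force oracle is quadratic and guarded to 200 kb.
* Indels are neither planted nor called; gapped alignment is out of scope.
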