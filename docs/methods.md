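# Methods

## The problem

Whole-genome bisulfite sequencing (WGBS) reads carry methylation information
in their C/T pattern: bisulfite converts unmethylated cytosines to uracil
(sequenced as T) and leaves methylated cytosines intact, so the fraction of
C reads at a cytosine estimates its methylation level. Bisulfite-read
mappers disagree substantially, however — three-letter mappers (Bismark,
BS-seeker2 style) collapse C/T before alignment and tend to leave difficult
reads unmapped, while wild-card mappers (BSMAP style) accept C-or-T matches
and tend to place more reads, more of them wrongly — and their behavior
shifts with read length, per-base error rate, read T density (itself a
function of methylation), and repeat content. `methylmerge` merges the
per-cytosine calls of several mappers into one consensus level and ships
the simulation framework used to characterize when and why that helps.

## Consensus model

At cytosine position *i*, mapper *j* reports counts N^c_ij (unconverted C)
and N^t_ij (converted T); its level is M_ij = N^c_ij / (N^c_ij + N^t_ij)
and its depth N^d_ij = N^c_ij + N^t_ij. Over the mappers covering *i*:

* **Ave**: arithmetic mean of the M_ij.
* **wAve**: Σ_j W_ij M_ij with W_ij = N^d_ij / Σ_j N^d_ij. Depth acts as a
  confidence proxy: a mapper that placed more reads at the position carries
  more weight, tying the consensus to mapping rate.
* **pwAve**: Σ_j W^p_ij M_ij with W^p_ij ∝ f(N^d_ij; λ_j), f the Poisson
  pmf and λ_j mapper *j*'s mean depth over all reference cytosines
  (uncovered positions counting zero). A depth typical for that mapper is
  trusted; an anomalously high one — the signature of reads piling onto a
  mismapping hotspot — is down-weighted.

A mapper covers a position when its depth is ≥ `min_depth` (default 1 for
simulated data, 5 recommended for real data); a position is emitted when at
least `min_mappers` (default 2) mappers cover it. Uncovered mappers are
excluded from every sum and from weight normalization, so each merged level
is a convex combination of covering-mapper levels. Two deliberate readings
of ambiguous conventions:

* The weighted forms are Σ W·M with W summing to one, with no further
  division by the number of covering mappers; only Ave divides by n_i.
  Dividing the already-normalized weighted sum by n_i would shrink levels
  n-fold and could not produce near-identical Ave/wAve accuracies.
* n_i counts mappers by *coverage*, not by "level > 0": a mapper confidently
  reporting an unmethylated site is evidence, not absence. The literal
  level-based count is available via `count_zero_level=False`.
* At partially covered sites weights are normalized over covering mappers
  only — the only choice that keeps merged levels in [0, 1].

Poisson pmfs are evaluated in log space (shifted by the max before
exponentiation), so high depths cannot underflow; if every pmf is exactly
zero (λ = 0 with positive depth everywhere) the integrator falls back to
depth weights and logs a warning.

## Simulation test bed

The simulator replaces a reference genome, a read simulator and the mapper
binaries with a seeded, self-contained pipeline whose ground truth is known
exactly.

**Reference and truth.** A single synthetic chromosome is tiled by 500-bp
blocks (the truth granularity). Sequence is i.i.d. uniform A/C/G/T with 75%
of CG dinucleotides subsequently disrupted, leaving ~6–9 forward-strand
CpGs and ~100 CpH sites per block — the CpG scarcity of a mammalian
chromosome (observed/expected CpG ≈ 0.2–0.3). This matters: with uniform
sequence's ~31 CpGs per block, per-block sampling noise is so small that
depth pooling — the mechanism the consensus exploits — becomes invisible.
A configurable fraction of blocks (default 10%) are near-identical copies
of one shared motif (2% divergence per copy), a stand-in for an
interspersed repeat family. Each block draws independent uniform [0, 1]
truth levels for CpG and CpH.

**Reads.** Per block, `reads_per_block` reads of fixed length start
uniformly inside the block (never straddling boundaries). Each reference C
in a read is retained as C with probability equal to the block's truth
level for its context, else written as T; substitution errors then hit
every base independently at the condition's error rate, replacing it with a
uniformly chosen different base (no indels, no quality curve — a uniform
error model). Reads are forward-strand by default. The default campaign is
the full factorial: lengths {100, 50} bp × error {0, 2, 4, 6, 8}% × 10
replicates = 100 read sets, with 50×100-bp or 100×50-bp reads per block so
mean coverage is 10 in every condition.

**Realized truth.** Detection is scored against what the reads actually
carry, not the drawn target: per block and context, the realized truth is
the unweighted mean over covered cytosines of each cytosine's retained
fraction. This convention matches the block detected level (also an
unweighted mean over cytosines), so a perfect mapper on error-free reads
recovers it exactly — a calibration the test suite asserts. The read-pooled
ratio is recorded alongside (`pooled_mcg`/`pooled_mch`).

**Mapper emulation.** Each read is unmapped, mapped correctly, or mapped to
a uniformly chosen wrong position. The mapping probability is
`base_map_rate − error_sensitivity·(errors/length) − repeat_unmap_penalty·[repeat]`,
and, conditional on mapping, the mismap probability is
`mismap_rate_base + error_mismap_sensitivity·(errors/length) +
t_density_sensitivity·(T fraction) + repeat_mismap_penalty·[repeat]`, both
clamped to [0, 1]. Mapped reads — right or wrong — deposit their base
observations on every forward-strand reference C under the alignment
(C counts methylated, T unmethylated, other bases ignored), so mismapped
reads create the scattered noise calls that consensus integration must
absorb. λ is estimated from the deposited depth over all reference
cytosines.

**Presets.** Three profiles encode the characteristic phenotypes of the
popular mappers at mean coverage 10:

| preset | base rate | rate slope vs error | base mismap | mismap slope vs error | T-density slope | repeat effect |
|---|---|---|---|---|---|---|
| bismark-like | 0.96 | 8.0 | 0.001 | 0.2 | 0 | unmap +0.30 |
| bsmap-like | 0.99 | 8.5 | 0.015 | 0.15 | 0.12 | mismap +0.25 |
| bsseeker2-like | 0.90 | 0.5 | 0.025 | 0 | 0.10 | unmap +0.20 |

These reproduce the documented orderings: the wild-card mapper maps the
most clean reads with the worst accuracy; its rate and the bismark-like
rate collapse at high error (correct-mapping rates near 30% at 8% error,
consistent with a triple-mapper correct-overlap collapsing to a few
percent) while the bsseeker2-like mapper barely responds to error; T-rich
(hypomethylated) reads are preferentially mismapped by the bsmap- and
bsseeker2-like mappers but not the bismark-like one; repeat-derived reads
go unmapped under the three-letter-style presets and get mismapped under
the wild-card one. The linear rate response cannot honor both the
low-error and high-error overlap anchors simultaneously; the high-error
end was preferred since it drives the headline comparisons. Stronger
T-density couplings (0.3–0.5) were examined and rejected: they inject more
level-dependent noise than the unbiased component can correct, which is
not the regime the consensus method is described to operate in.

## Evaluation

* **Mapping rate** = mapped/total reads; **mapping accuracy** =
  correctly placed/mapped — both from the emulator's truth labels, reported
  in percent.
* **Block detected level**: unweighted mean of covered per-cytosine merged
  levels of one context class (CG, or CH = CHG ∪ CHH) inside the block,
  undefined when no cytosine qualifies.
* **d-accuracy** = 100·(1 − |realized truth − detected|) per block, averaged
  over blocks where both sides are defined. Blocks without detection are
  excluded rather than scored zero; quantity is measured separately by
  d-amount.
* **d-amount**: the number of cytosine positions at or above the depth
  threshold (for integrated calls, positions that satisfied the
  covering-mapper rule).
* Paired one-sided Wilcoxon signed-rank tests compare per-block d-accuracy
  vectors (zero differences dropped; exact null up to 25 informative pairs,
  normal approximation with continuity correction beyond).
* Pearson correlations relate per-condition d-accuracy to mapping rate and
  accuracy across benchmark rows.

## Multi-sample comparison

Samples are binned into fixed-size blocks (10 kb default for real-scale
data), each bin the unweighted mean of its covered cytosines of one
context; pairwise distance is 1 − Spearman ρ over pairwise-complete bins
(average ranks for ties; a complete-bins-only mode exists), clustered
agglomeratively (UPGMA default, single/complete available) and serialized
to Newick with ultrametric half-height branch lengths. At desk scale the
synthetic cohort test bins at the 500-bp truth granularity: a 50–100-kb
synthetic genome offers too few 10-kb bins for stable rank correlation, and
coarser binning would average away the block-scale tissue signature that
the cohort generator plants.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run 100–200-block genomes
(50–100 kb), coverage 10, with 3–5 replicates per seeded campaign and 5–10
seeds per claim — sizes at which every headline comparison is stable while
a full run stays in the minutes range. Ave/wAve/pwAve agree with
independent brute-force oracles to 1e-12; weight vectors sum to 1 within
1e-9; merged levels are convex combinations of inputs by construction.
Positions, coordinates and strands are 1-based and strand-specific
everywhere except bedGraph export (converted on write). Integer CT counts
are preferred over fractional effective counts when reading BSMAP
methratio files.

## Limitations

* The emulator treats reads independently given their covariates; real
  mapper failures correlate through local sequence in richer ways (e.g.
  families of homologous repeats attracting each other's reads).
  Mismapped reads land uniformly rather than at homologous loci.
* Uniform substitution errors stand in for quality-curve-based error
  profiles; no indels, adapters, PCR duplicates or paired ends.
* Reads are forward-strand (directional protocol); the both-strand path is
  untested against any reference behavior.
* Real-mapper absolute accuracies (e.g. printed benchmark tables of the
  original mappers) are outside what a desk-scale emulation can reproduce;
  the package asserts directions and mechanisms, not those absolute values.
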