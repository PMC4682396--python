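# methylmerge

Consensus methylation calling from multiple bisulfite-read mappers, with a
seeded simulation framework for validating when and why the consensus
helps.

## Why

In whole-genome bisulfite sequencing (WGBS), unmethylated cytosines are
read as T and methylated ones as C, so the C fraction at a cytosine
estimates its methylation level. But the estimate depends on which
bisulfite-read mapper produced the alignments: three-letter mappers
(Bismark, BS-seeker2) and wild-card mappers (BSMAP) trade mapping rate
against accuracy differently, and both trade-offs shift with read length,
error rate, read T density and repeat content. Pipelines that must combine
samples of heterogeneous read quality inherit mapper-dependent biases.

`methylmerge` merges per-cytosine calls from several mappers into a single
consensus level per position. With M_ij = N^c_ij/(N^c_ij + N^t_ij) the
level reported by mapper *j* at position *i*, and N^d_ij its depth:

* **Ave**  = (1/n_i) Σ_j M_ij — the plain average,
* **wAve** = Σ_j W_ij M_ij,  W_ij = N^d_ij / Σ_j N^d_ij — depth-weighted,
* **pwAve** = Σ_j W^p_ij M_ij,  W^p_ij ∝ f(N^d_ij; λ_j) — weighted by the
  Poisson pmf at the mapper's genome-wide mean depth λ_j, down-weighting
  anomalous local depths (mismapping pile-ups),

where sums run over the n_i mappers covering the position and a position is
emitted only when n_i ≥ k (default k = 2). Readers are included for the
Bismark cytosine report and coverage formats, BS-seeker2 CGmap, BSMAP
methratio, and a lossless unified TSV.

The package also contains the full validation bed: synthetic
CpG-depleted references with block-wise methylation truth, a bisulfite
read generator with controlled length/error conditions, a parametric
emulator of mapper behavior (rate/accuracy responses to read error, T
density and repeats), detection scoring (d-accuracy, d-amount, paired
Wilcoxon tests, metric correlations), and multi-sample block clustering
with 1−Spearman distances.

## Worked example

Simulate a 50-block (25 kb) genome at coverage 10 with 4% read error,
emulate the three mapper presets, merge their calls, and score everything
against the known block truth:

```
$ methylmerge simulate --n-blocks 50 --read-length 100 --error-rate 0.04 \
      --seed 11 --outdir sim
INFO methylmerge.cli: bismark-like: lambda=6.149, 5629 called positions
INFO methylmerge.cli: bsmap-like: lambda=6.008, 5676 called positions
INFO methylmerge.cli: bsseeker2-like: lambda=8.099, 5746 called positions
wrote simulation to sim

$ methylmerge integrate sim/calls.*.tsv -k 2 -d 1 -o integrated.tsv
integrated 5693 positions -> integrated.tsv

$ methylmerge evaluate --truth sim/truth.tsv integrated.tsv \
      sim/calls.bismark-like.tsv sim/calls.bsmap-like.tsv \
      sim/calls.bsseeker2-like.tsv -o report
              source context  d_accuracy  d_amount  n_blocks_scored
          integrated      CG   96.973859      5693               50
  calls.bismark-like      CG   96.530184      5629               50
    calls.bsmap-like      CG   95.026387      5676               50
calls.bsseeker2-like      CG   96.961671      5746               50
```

Reading the output: each emulated mapper missed or misplaced a different
subset of reads (λ is its realized mean depth; called positions its
d-amount). The depth-weighted consensus over positions covered by ≥2
mappers detects CpG methylation within 3.03 points of the per-block truth
on average (d-accuracy 96.97, on the 0–100 scale), above every individual
mapper — the noisy wild-card mapper trails at 95.03 — while also emitting
more positions (5,693) than the most conservative mapper (5,629). The same
operations are available as library functions (`integrate_positions`,
`run_condition`, …) for use without the CLI.

`methylmerge compare` bins integrated samples into fixed-size blocks,
computes 1−Spearman distances and writes a Newick tree; in the shipped
two-tissue synthetic cohorts it groups samples by tissue truth rather than
by read condition.

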