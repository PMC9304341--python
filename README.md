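# atacdiff

Fragment-level ATAC-seq analysis toolkit: V-plot modeling of nucleosome
structure, a sample-conditioned variational autoencoder for differential
chromatin accessibility, motif deviation scores, and open/closed region
grouping — driven end to end by a seeded synthetic fragment generator with
known ground truth.

## What it does

- **`atacdiff.fragments`** — BED3+ fragment I/O (gzip-transparent), Tn5
  insertion-offset correction (+4 bp left / −5 bp right), sub-nucleosomal vs
  mono-nucleosomal size classification (threshold 150 bp), per-bp coverage
  tracks and bedGraph round-tripping.
- **`atacdiff.peaks`** — coverage-threshold peak caller (maximal runs with
  coverage ≥ 10, fixed-width summit-centered intervals), interval union,
  conservation-score filtering (> 0.8), degenerate-consensus motif scanning
  on both strands (e.g. `(A/C/G)AGGAA(G/A)T`), 640-bp motif-centric windows.
- **`atacdiff.vplots`** — per-region V-plots (fragment midpoint × length
  histograms; 640 bp × [50, 370) by default), aggregation to densities,
  size-partitioned signal tracks, depth-normalized accessibility-ratio
  tracks, and a Gaussian-kernel nucleosome-occupancy proxy.
- **`atacdiff.seatac`** — a conditional VAE over V-plots (multinomial
  decoder, K = 5 diagonal-Gaussian latent, Adam lr = 0.01 with cosine
  warmup schedule) implemented directly in NumPy with hand-written
  backpropagation; a χ²(K) test on pooled latent posteriors; BH adjustment;
  a central nucleosomal-density log ratio; and region ranking/selection at
  `p_adj < 0.05 and log ratio < −0.2`.
- **`atacdiff.chromvar`** — motif deviation scores against accessibility-
  matched random background interval sets, per-motif variability with
  permutation p-values, PCA of deviations, hierarchical-clustering orders.
- **`atacdiff.grouping`** — four-way 00/01/10/11 open/closed region codes
  against two reference samples, and annotation-enrichment proportions.
- **`atacdiff.synthetic_data`** — seeded generator producing nucleosome-aware
  paired-end fragment data (positioned dyads, NFRs, condition-specific
  displacement, per-sample fragment-size batch shifts) with truth tables.
- **`atacdiff.cli`** — pipeline orchestration with a manifest, per-stage
  seeds fanned out from one root seed, and a rendered report.

## CLI

```sh
atacdiff run --outdir run1 --seed 7          # full synthetic pipeline
atacdiff simulate --outdir sim --seed 7      # fragments + truth table only
atacdiff fragments sim/A_rep1.fragments.bed --out shifted.bed
atacdiff callpeaks shifted.bed --out peaks.bed --chrom chrS --start 0 --end 400000
atacdiff vplot shifted.bed regions.bed --out aggregate.tsv
atacdiff train --fragments A_rep1=... --fragments A_rep2=... \
               --fragments B_rep1=... --fragments B_rep2=... \
               --regions regions.bed --out model.npz
atacdiff test --model model.npz --treatment B_rep1=... --treatment B_rep2=... \
              --control A_rep1=... --control A_rep2=... \
              --regions regions.bed --out differential.tsv
atacdiff group --regions regions.bed --peaks-a a.bed --peaks-b b.bed --out groups.bed
atacdiff deviations --counts counts.tsv --membership membership.tsv --out dev.tsv
atacdiff report run1
```

`atacdiff run` writes, under the run directory: simulated fragment BEDs and
truth TSV, Tn5-shifted fragments, per-sample peak BEDs and coverage
bedGraphs, the union interval set, deviation/variability/PCA tables, group
codes and enrichment, the trained model, the ranked differential TSV, a
`manifest.json` and a human-readable `report.md`.

## Notes

- Coordinates are 0-based half-open (BED convention) throughout.
- All randomness flows from explicit seeds; training is deterministic per
  seed on a given platform (floating-point results may differ across BLAS
  backends).
- The VAE is pure NumPy (no deep-learning framework required); encoder and
  decoder are small dense stacks sized for desk-scale grids.
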