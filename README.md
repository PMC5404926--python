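# startpipe

Analysis pipeline for base-resolution nascent transcription start-site
(Start-seq) data and its companion assays, built for studies that ask
whether a chromatin perturbation (e.g. a histone H3K36 point mutant in
*Drosophila*) changes transcription initiation, cryptic intragenic
initiation, antisense transcription, or pre-mRNA splicing fidelity.

It is aimed at genomics researchers who have strand-specific 5'-end
sequencing data plus standard gene models, and who want every step — from
alignments to classified TSS tables — to be explicit, deterministic and
testable. A synthetic-data generator with a ground-truth manifest makes
every stage verifiable without any external download.

## What it computes

- **Base-resolution initiation signal.** Each fragment contributes +1 at
  the 5'-most base of its mate-1 (or unpaired) read; signal is kept per
  strand at single-base resolution.
- **Spike-in normalization.** With spike read totals $t_s$, each sample is
  scaled by $f_s = \mathrm{median}_s(t_s)/t_s$, so totals stay on a
  typical-library scale and depth differences cancel exactly.
- **TSS calling and classification.** Bases with pooled normalized signal
  ≥ a threshold are merged within a small distance into single-base TSSs.
  A call within ±50 nt of an annotated TSS on the same strand is an
  observed TSS (obsTSS); everything else is a novel unannotated TSS
  (nuTSS), classified as exonic / intronic / intergenic (union-exon rule)
  and sense / antisense relative to its resident gene, and mapped onto a
  scaled gene axis (body → [0,1], ±1 kb flanks → [−0.5,0) and (1,1.5]).
- **Differential TSS usage.** Per TSS,
  $\log_2\!\frac{\bar x_{mut}+c}{\bar x_{ctrl}+c}$ and the absolute change
  $\bar x_{mut}-\bar x_{ctrl}$ on the normalized scale; MA-style binned
  means with a tie-corrected Spearman correlation; antisense read counts
  per gene with ChIP-peak proximity flags; union-exon FPKM.
- **ChIP-density stratification.** Mean signal per bp in fixed windows,
  3'UTRs, and scaled metagenes; features are cut into deciles (1 = lowest
  density, 10 = highest) and expression change is summarized per decile.
- **Splicing fidelity.** At every exon-exon junction, junction reads *j*
  (gap matching the intron exactly) and non-junction reads *n* (contiguous
  through the donor boundary) give the retention ratio $R = n/(j+n)$;
  junctions need > 20 reads per condition to be powered, and
  $\Delta R = R_{mut} - R_{ctrl}$ is defined only when both are. Event
  tables (Bayes factor + 3 replicate ΔPSI values) are flagged significant
  iff BF > 10 with a consistent ΔPSI sign in every replicate.

## Worked example

```sh
startpipe demo --seed 1 --out demo_out
```

simulates 100 genes on two 500 kb chromosomes, two samples (`hwt` control
at depth 1.0 with 1000 spike reads, `k36r` mutant at depth 1.2 with 1200),
150 annotated + 50 cryptic initiation sites, junction reads with known
retention fractions, a 3'-skewed ChIP track and 200 splicing events; runs
every stage; and prints the ground-truth recovery report:

```json
{
 "nutss_recall": 1.0,
 "nutss_precision": 1.0,
 "nutss_labels_match": true,
 "norm_factors": {"hwt": 1.1, "k36r": 0.916667},
 "retention_max_abs_error_vs_realized": 0.0,
 "retention_mean_abs_error_vs_rho": 0.019193,
 "event_filter_agreement": 1.0,
 "gene_log2fc_spearman_est_vs_truth": 0.887801,
 "checks": { ... all true ... }
}
```

Reading it: all 50 simulated cryptic sites were called and classified
correctly (recall and precision 1.0, labels matching); the spike factors
are median(1000, 1200)/spike: 1.1 and 0.9166…; retention ratios equal the
realized simulated counts exactly and sit ~0.02 from the underlying
retention probabilities (binomial sampling at the simulated depths); the
event filter reproduces the manifest exactly; and per-gene fold-change
estimates rank-correlate 0.89 with the simulated effects. `demo_out/`
holds the TSV/BED/bedGraph artifacts of every stage plus `pipeline.log`
and `recovery.json`; running the same seed twice gives byte-identical
trees.

Other subcommands (`simulate`, `quantify`, `call-tss`, `classify`, `diff`,
`antisense`, `stratify`, `metagene`, `splicing`) run single stages on
files, so a slice of a full run can be reproduced or re-parameterized in
isolation; see `startpipe --help`.

## Layout

- `src/startpipe/io_formats.py` — GFF3/BED12/bedGraph/SAM/tabular readers
  and writers, 0-based half-open internally, strict validation.
- `src/startpipe/synthetic_data.py` — the generator and its manifest.
- `src/startpipe/startseq_signal.py` — 5'-end counting, spike
  normalization, windows.
- `src/startpipe/tss_catalog.py` — TSS calling and classification.
- `src/startpipe/differential.py` — fold changes, antisense counts, FPKM.
- `src/startpipe/chip_stratify.py` — densities, deciles, metagenes.
- `src/startpipe/splicing_fidelity.py` — junction counting, R/ΔR, event
  filters.
- `src/startpipe/pipeline.py`, `cli.py` — orchestration and the CLI.
- `docs/methods.md` — models, parameter choices and limitations.
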