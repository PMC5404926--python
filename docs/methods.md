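# Methods

## Scope and data model

The pipeline quantifies strand-specific transcription initiation at
single-base resolution from Start-seq-style alignments, normalizes between
samples with exogenous spike-in reads, calls and classifies initiation
sites against a gene model, compares genotypes, stratifies expression
change by ChIP density, and measures splice-junction retention. All
coordinates are 0-based half-open internally; conversion to 1-based closed
GFF3 happens only at file boundaries, so no stage ever reasons about
inclusive endpoints.

## Initiation signal

The initiation base of a fragment is the 5'-most aligned base of its
mate-1 (or unpaired) read — leftmost block start on the plus strand,
rightmost block end − 1 on the minus strand. This follows Start-seq
library chemistry, which places the cap at mate 1's 5' end. Mate-2 records
are ignored; unmapped, secondary and supplementary alignments are skipped
at read time. No duplicate collapsing is performed: whether deduplication
is appropriate depends on library construction (UMIs), and silently
removing reads would bias the single-base counts the rest of the pipeline
relies on.

Spike-in reads are recognized by a reference-name prefix (default
`spike_`), mirroring how spike genomes are concatenated onto references in
practice, and are tallied but excluded from genomic signal.

## Spike normalization

Sample *s* with spike total *t_s* is scaled by
`f_s = median_s(t_s) / t_s`. The median numerator (rather than a fixed
constant) keeps normalized values on a typical-library scale and is robust
to one aberrant library; normalizing an already-normalized set with equal
spike totals is the identity. Normalization is undefined (an error) when a
sample has zero spike reads. Any upstream wet-lab calibration of spike
amounts (e.g. to DNA content) is assumed to be folded into the spike
counts themselves.

## TSS calling and classification

Calling operates on pooled across-sample normalized signal so that both
genotypes share one TSS universe; per-sample signal is then re-read at the
called bases. Candidate bases need pooled signal ≥ `min_signal` (default
3 normalized reads); candidates within `merge_dist` (default 5 nt) on one
strand merge into a cluster represented by its maximum base (ties resolve
to the 5'-most base) carrying the summed signal. Both thresholds are
recorded in output headers — they are explicit, reproducible stand-ins for
a calling rule that published Start-seq analyses usually leave unstated.

A call within ±`match_tol` (default 50 nt, half the 100 nt window
conventionally used to display obsTSS signal) of a same-strand annotated
TSS is an obsTSS, assigned to the nearest such TSS (equidistant ties to
the 5'-most). Everything else is a nuTSS. Context uses the union-exon
rule — a base in any transcript's exon of any gene is exonic, else
intronic if inside any gene span, else intergenic — and the resident gene
is chosen with exonic priority, then by nearest annotated TSS, then
lexicographically (a deterministic tie-break). Orientation is sense iff
the call strand equals the resident gene strand; intergenic calls carry no
orientation. Scaled positions map the gene body to [0,1] along the
transcription direction and each 1 kb flank linearly onto [−0.5,0) and
(1,1.5]; positions beyond the flank clamp to ±boundary and are flagged.

## Differential statistics

Differential TSS usage is deliberately a simple normalized-ratio
statistic: `log2((mean_mut + c)/(mean_ctrl + c))` with pseudocount c = 1
normalized read (explicit, since no published value exists), plus the
exact absolute change. Dispersion-modelled testing is out of scope; its
tabular output can be substituted wherever a log2fc column is consumed.
Smoothed MA curves are replaced by binned means over control-level ranks
plus a tie-corrected Spearman correlation — deterministic and directly
testable; when either variable is constant the correlation is defined as
0. A read counts as antisense to a gene when any aligned block overlaps
the gene span on the opposite strand; peak proximity is a gap of at most
`peak_dist` (default 1 kb) between gene span and peak interval. FPKM uses
a union-exon model, assigning each fragment by the midpoint of its 5'-end
block with matching strand, with the denominator equal to the fragments
assigned to any gene.

## ChIP density and stratification

Density is always mean signal per bp — never a sum — so truncated windows
and 3'UTRs of different lengths are comparable; truncation at chromosome
ends is flagged. Decile stratification ranks features ascending (value
ties broken by feature id) and cuts 10 contiguous rank blocks whose sizes
differ by at most one, larger blocks at lower deciles; decile 1 is lowest
density. Per-decile summaries use exact order statistics with the midpoint
rule for the median and quartiles. Metagene profiles length-normalize each
gene body into `body_bins` (default 100) mean-per-bp bins with fixed-width
flank bins (1 kb / 20 bins), reverse minus-strand genes, and average
genes without weighting; a constant track therefore yields that constant
in every bin exactly. ChIP/input correction is not performed internally —
tracks are consumed as provided, because input-correction pipelines vary.
Up/unchanged/down gene groups are plain log2fc thresholds from the config,
not significance calls.

## Splicing fidelity

Junctions are enumerated once per distinct (chrom, strand, donor,
acceptor) over all transcripts. A read is a junction read *j* for a
junction when one of its inter-block gaps covers exactly the intron
(donor+1 … acceptor−1) with ≥ `min_overhang` (default 4 nt, configurable —
a sensible aligner-style guard, since published descriptions rarely state
one) aligned bases on both sides; it is a non-junction read *n* when a
single contiguous block covers the donor boundary with the same overhang.
Anchoring *n* at the donor only avoids double-counting a retained intron
at both of its boundaries. A read increments at most one of {j, n} per
junction, with the junction match taking priority. R = n/(j+n) is computed
per condition with replicates pooled (per-replicate counting is available
by passing replicate-keyed read sets); the power filter is strictly more
than 20 total reads, and ΔR is defined only when both conditions pass it.
Event significance is exactly "combined Bayes factor > 10 AND all three
replicate ΔPSI values strictly one sign" (a zero breaks consistency); PSI
estimation itself is consumed from upstream tools or the simulator, never
reimplemented. The severity summary counts significant events with
|combined ΔPSI| ≥ 0.25 per event type, with fraction 0 when a type has no
significant events.

## Synthetic data

The generator emulates the data shapes of a whole-larvae histone-mutant
study: two 500 kb chromosomes carrying 100 non-overlapping multi-exon
genes with ≥ 1 kb gaps, 3'UTRs at the strand-appropriate terminal exon,
one control and one mutant sample (depth multipliers 1.0 / 1.2, spike
counts tracking depth: 1000 / 1200), 50 cryptic sites kept > 60 nt from
every annotated TSS, per-site strengths uniform in 0.4–1.6 × a 50-read
mean (so every site clears 5 × the calling threshold), uniform background
at 5 × 10⁻⁵ reads per strand-base, Poisson count noise (recorded in the
manifest), exact spike emission, Binomial(T, ρ) intron-retaining reads at
per-junction retention fractions drawn from 0–0.15, a deterministic
ChIP-like track ramping 5'→3' (value ∝ 1 + 2f, exons weighted 2×,
background 0.1), and 200 splicing events of which 20% satisfy the
significance rule by construction. Site effects are drawn from
{−1, 0, +1} log2 units. Every non-background read id names its generating
element, so recovery tests are exact where the construction is exact
(spike factors, event flags, realized junction counts) and quote binomial
or Poisson standard errors where it is stochastic.

All randomness flows from one seed through named integer substreams, one
per component and **sample** — never per condition label — so outputs are
byte-identical across runs and platforms, and relabelling which condition
is "control" in the analysis negates log2fc, absolute change and ΔR
exactly without touching a single read. The mutant effect itself is part
of the simulation (applied to samples whose condition is `mut`), while the
comparison direction is an analysis setting (`ctrl_condition` /
`mut_condition` in the pipeline config).

What the generator does not emulate: nucleotide sequences and
mappability, PCR duplicates, replicate-level overdispersion beyond
Poisson, paired-end mate structure (reads are emitted unpaired; the
mate-1 rule is exercised by unit tests), and any coupling between ChIP
density and expression effects (effects are drawn independently).
Passing tests therefore demonstrate correctness of the computations and
calibration under these stated models, not robustness to alignment
artifacts or biological covariance structure in real data.

## Numerical and format choices

Tables serialize floats at 6 significant digits (stable diffs; the
matching reader round-trips records losslessly at that precision), with
`NA` for missing values and sorted JSON for map-valued fields. bedGraph
output is run-length encoded with zero runs omitted. Logs contain stage
names and record counts only — no timestamps — so full runs diff cleanly.
Default problem sizes (100 genes × 2 × 500 kb, ~25 k reads per sample,
junction depths 50–150, acceptance checks at T = 10⁴ × 100 seeds) keep a
full run in tens of seconds on one CPU; they are the package's chosen
study scale, and the genome-scale numbers of a real experiment (thousands
of nuTSSs, > 10⁸ reads) are deliberately not reproduced at desk scale.

## Known limitations

Interval queries are linear scans over per-chromosome gene lists —
appropriate at the built-in scale, replaceable by an interval tree for
genome-scale annotations. BAM/CRAM input is out of scope (SAM and a
tabular block format are supported; conversion is one `samtools view`
away). The obs/nu match tolerance, calling threshold and merge distance
materially shape nuTSS counts on real data and should be reported with
any result, which is why every output header embeds them.
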