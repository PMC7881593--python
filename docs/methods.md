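# Methods

## The signal model

A genomic bin with tumor copy number `c` observed in cfDNA with tumor
fraction `f` on a diploid background contributes expected relative depth
`(2 + f·(c − 2)) / 2`; its expected log2ratio is therefore
`log2(1 + f·(c/2 − 1))`, clipped below at −4 so the homozygous-deletion
limit (c=0, f=1) stays finite. All calling thresholds in the package are
statements about this quantity.

The simulator draws per-bin counts with mean

    mu_i = N · w_i · b_i · (2 + f·(c_i − 2)) / Z

where `N` is the genome-wide read total, `w_i` the bin-width share, `b_i` a
multiplicative regional bias, and `Z` normalizes so `Σ mu_i = N`. Noise is
Poisson by default; a negative-binomial option (`variance = mu + d·mu²`)
is exposed because real nanopore depth is overdispersed. Fragment lengths
come from a two-lognormal location mixture parameterized by its modes
(169 bp mononucleosomal, 320 bp dinucleosomal shoulder; a lognormal with
log-sigma `s` and mode `m` has `mu = ln m + s²`).

What the generator emulates: depth-proportional CNV signal and its dilution
by tumor fraction, cohort-shared multiplicative depth artifacts, count
noise at 2–30 M reads, bimodal cfDNA fragment sizes. What it does not:
GC-content and mappability *tracks* (biases are free regions, not tied to
sequence), germline variation, basecalling errors, within-sample
fragment-size/copy-number coupling. Passing tests therefore demonstrate the
pipeline's statistical behavior under the stated noise model, not
robustness to every bias structure of real sequencing runs.

## Binning and counting

Default bins are 100 kb on GRCh38 autosomes + chrX (~30,300 bins). Each
retained primary alignment increments exactly one bin by its leftmost
mapped position — with bins 600× longer than cfDNA fragments the choice of
anchor is immaterial. Defaults: MAPQ ≥ 1 (drop multi-mappers; mapping
ambiguity is the dominant artifact source), duplicates kept (PCR-free
nanopore cfDNA), unmapped/secondary/supplementary excluded. Subsampling is
binomial thinning per bin, the exact in-silico equivalent of uniform read
subsampling; merging is bin-wise summation (the merged-control construction).

## Normalization

*Nocontrol*: `r_i = log2(c_i / m)` with `m` the median count over usable
autosomal bins. The median keeps the center robust to a large CNV burden
under the copy-neutral-majority assumption; the documented failure mode is
genome-doubled samples. *Paired*: `r_i = log2((t_i/T)/(k_i/K))` over
mutually usable bins, then re-centered to zero median; any bias present in
both samples cancels exactly, which is the entire mechanism of artifact
suppression. Usable bins exclude: zero counts (masked, never
pseudo-counted — fabricating depth at 100-kb scale distorts exactly the
sparse bins that matter at extreme subsampling), chrY (sex-confounded and
artifact-rich), and truncated chromosome-end bins (proportionally fewer
reads would masquerade as focal losses). chrX is normalized against the
autosomal median and flagged; no sex inference is attempted. A
GC/mappability correction hook was considered and deliberately left out:
shared artifacts are handled by paired mode and the recurrence mask instead.

## Segmentation

Per chromosome, the exact minimizer of squared error plus `β` per segment,
over all partitions with segments of ≥ `min_bins` bins (default 3 —
suppresses single-bin segments that the ±0.04/±0.10 thresholds would
otherwise promote). The solver is optimal-partitioning dynamic programming
with pruning; a candidate changepoint shown to be dominated at step `j` is
discarded only from step `j + min_bins` on, so pruning remains exact under
the minimum-length constraint. Ties break toward lower cost, then fewer
segments, then the earlier last changepoint, recursively — a deterministic
total order mirrored by the exhaustive-enumeration oracle in the tests.
Segment means are arithmetic means of member-bin log2ratios. Chromosomes
shorter than `min_bins` usable bins form a single segment.

Default penalty: `β = 2·σ̂²·ln(n)` per chromosome (a BIC-type choice), with
`σ̂ = median(|diff r|) / (0.6745·√2)` estimated from successive differences,
insensitive to the sparse true changepoints. At 2 M reads this operating
point is conservative: a lone 30-Mb single-copy gain at tumor fraction 0.10
(per-bin shift 0.070 against per-bin noise ≈ 0.19) is carved out in only
~77% of replicates; smaller multipliers trade missed splits for mis-localized
ones without robustly improving 90%-reproducible detection (measured rates
at f = 0.10: 0.77, 0.87, 0.92, 0.87, 0.67 for k = 2, 1.5, 1.25, 1.0, 0.75),
so the standard k = 2 is kept rather than tuned to the peak of a noisy
sweep. At 10 M reads the titration's 90%-reproducible detection limit for
that event is tumor fraction 0.075. The penalty and `min_bins` are exposed
flags.

## Calling, masking, gene tiers

Calls require `|seg_mean| ≥` 0.10 (nocontrol) or 0.04 (paired) — the paired
threshold can be this much tighter because shared artifacts, which reach
roughly ±0.10 in nocontrol profiles, cancel against the merged control.
The artifact mask flags bins whose bin-level segment mean reaches 0.10 in
absolute value in ≥ 2 healthy samples; calls with > 50% masked bins are
dropped and counted. Gene values are overlap-length-weighted means of
covering segment means; tiers are `neutral` below |0.10|, `low_amp`/
`low_del` in [0.10, 0.30), `high_amp`/`high_del` at ≥ 0.30 (low tier
inclusive at 0.10, exclusive at 0.30). The bundled gene BED carries
approximate GRCh38 spans for recurrently altered lung-cancer loci and is
plain editable text; the assembly is a property of the file, not the code.

## Evaluation procedures

Concordance compares per-bin (segment-mean) vectors over mutually usable
bins: Pearson r, plus the fraction of bins whose three-state class (gain ≥
threshold, loss ≤ −threshold, else neutral) agrees; a tolerance-band
variant (|a−b| ≤ tol) is available, class agreement is the default. The
class threshold defaults to the mode's calling threshold and is recorded in
every report. Confusion metrics collapse gains and losses to one "altered"
class (mirroring truth-set designs where a reference platform defines the
positives); zero-denominator ratios are reported as undefined, never 0.
The titration marks an event detected when a sign-correct call reciprocally
overlaps it by ≥ 50%, and reports the minimal fraction with detection rate
≥ 0.9 — both cutoffs are explicit parameters, since "detected" admits many
definitions and this one is a deliberate, documented construction.

Problem sizes used by the shipped studies: titrations run 8 fractions × 20
replicates (160 pipeline executions) on the ~30,300-bin genome at 2 M test
reads against a merged 4 × 5 M-read control; the subsampling study runs
10 replicates each at 10 M/2 M/0.5 M reads; the artifact-suppression study
runs 20 replicates of a 5-sample cohort at 5 M reads. These sizes give
Monte-Carlo standard errors well inside the margins being tested while
keeping each study in the minutes range on a single CPU.

## Numerical and API choices

- Bin membership for events and bias regions uses the bin-midpoint rule —
  simple, unambiguous for partial overlaps, and brute-force testable.
- Non-shared bias regions attach to exactly one cohort sample, so their
  cohort recurrence count is 1 by construction (shared regions recur in
  every sample).
- All stochastic operations take explicit seeds (`SimConfig.seed` or a
  generator); identical configuration reproduces bit-identical output.
- Count and ratio tables are 0-based half-open TSV with metadata in `#`
  headers and round-trip losslessly; segments use SEG-style TSV; calls use
  BED+score; the pipeline writes a JSON manifest with config, versions and
  per-stage record counts.

## Known limitations

- No GC/mappability/replication-timing correction; real-data artifact
  structure beyond shared multiplicative biases is out of scope.
- Median centering mis-calibrates genome-doubled samples.
- chrX handling is descriptive (flagged), not sex-aware.
- The segmentation penalty controls a sensitivity/specificity trade-off
  that shallow depths make sharp; near the detection limit, breakpoint
  localization error of a few bins is statistically irreducible.
- Batch processing only; no streaming/real-time analysis.
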