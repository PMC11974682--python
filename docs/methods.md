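# Methods

## Scope and model of the data

`tailprofiler` operates strictly downstream of basecalling, alignment,
signal-level poly(A) tail estimation and neural barcode demultiplexing. Its
unit of observation is a sequenced read with (i) a transcript assignment
(one contig per read; upstream multi-mappers are assumed resolved), (ii) an
estimated tail length in nucleotides, (iii) a tail-segmentation QC tag, and
(iv) optionally a barcode call with an assignment confidence in [0, 1].
Barcodes carry either the sample identity of a multiplexed library
(resolved to condition and replicate through a design table) or the
3'-terminal chemistry class of a splint-duplex capture mix (BC1 unmodified
poly(A), BC2 mono-U, BC3 oligo-U, BC4 terminal G — a fixed correspondence
the package refuses to remap).

## Read-level filtering

A read enters the analysis only if its tail length parsed as a finite
non-negative number, its QC tag is `PASS`, a barcode call exists, and the
demultiplexing confidence is **strictly greater than 0.85**. The phrase
"confidence above 0.85" is read as the demultiplexer's per-read assignment
confidence with a strict inequality; when no demux table is supplied
(an unmultiplexed library) the barcode-related filters are skipped.
Duplicate read ids in demux tables keep the highest-confidence row (ties:
first row, with a warning); duplicates in tail tables keep the first row.
Every dropped read is counted under exactly one reason (invalid tail, QC
fail, no demux call, low confidence, in that order), so the per-reason
counts always sum to input − output, and filtering is idempotent.

## Per-transcript statistics

- **Prefilter.** A transcript is analysed when at least one condition has
  ≥ `min_reads` (default 10) reads in ≥ `min_replicates` (default 2)
  replicates. The filter is monotone in both thresholds.
- **Windows.** Tail-length windows are half-open, [30, 120) nt ("~60-nt")
  and [120, 210) nt ("~150-nt"), so a read of exactly 120 nt belongs to one
  window only. Window occupancy is a percentage of the transcript's reads
  in that replicate; reads outside all windows are allowed, so window
  percentages need not sum to 100.
- **Differential tail length.** The test compares per-replicate mean tails
  between conditions with a two-tailed Welch (unequal-variance) t-test —
  the replicate, not the read, is the unit of inference, which is the
  conservative reading of a three-replicate design. The plain "t-test" is
  taken as Welch because at n = 3 the equal-variance assumption is
  untestable and Welch is the safer common default. A pooled read-level
  variant exists behind `level="read"` for exploration. Degenerate groups
  (both variances zero) get p = 1 when the means agree and p = 0 otherwise,
  keeping constant synthetic fixtures classifiable. Classification uses raw
  p ≤ 0.05 (the boundary is inclusive); BH-adjusted q-values are reported
  alongside but do not drive the default class.
- **Window-fraction change.** `log2((mean_B% + 0.1) / (mean_A% + 0.1))`
  over condition means of replicate percentages. The 0.1-percentage-point
  pseudocount caps the fold change of windows empty in one condition at
  ~log2(1000) while biasing typical values (tens of percent) negligibly;
  the formula itself is a package choice since only the quantity, not its
  definition, is standard.
- **Density profiles.** Per replicate, tails are binned at 5-nt resolution
  on [0, 350) nt (longer tails fold into the last bin so each replicate
  sums to 100%). The condition curve is a locally weighted polynomial
  regression (degree 2, tricube weights, span 0.3) fitted through all
  replicate bin points; degree 2 is used so peak heights are not flattened,
  and the smoother is implemented in-package because the common lowess
  implementations are degree-1. Read weighting is the default; a
  transcript-weighted variant (each transcript's own histogram averaged
  with equal weight) is available since "mean percentage of transcripts"
  admits both readings.

## Integration with stability and translation classes

External differential-accumulation and differential-translation tables
(transcript id, log2FC, p, BH q) are consumed, not recomputed — the
negative-binomial Wald machinery and translational-efficiency models that
produce them are deliberately out of scope. Transcripts are grouped `up`
(q ≤ 0.05, log2FC > 0), `down` (q ≤ 0.05, log2FC < 0) or `others`;
down-regulation across a transcriptionally silent transition is read as
instability, up-regulation as stability. The boundary is inclusive
(q ≤ 0.05) and configurable. Transcripts absent from a label table default
to `others`, so labels always partition the analysed set. Group
comparisons use Kruskal–Wallis (average-rank ties, chi-square
approximation) with two-sided Wilcoxon rank-sum post-hoc tests Bonferroni
adjusted over all group pairs (adjusted p = min(1, p × #pairs)); the
post-hoc choice is the package's, as only "Kruskal–Wallis with Bonferroni"
is standard. Associations between two transcript metrics use an OLS fit on
finite pairs (≥ 3 required; zero variance in x reported as undefined) plus
per-group medians of both variables. Poly(A) polymerase targets are the
transcripts classed `−` between wild type and a catalytically dead mutant,
sorted by effect size then p.

## Synthetic data generator

The generator reproduces the statistical structure of the study design so
the pipeline is testable without sequencing data; it simulates no signal,
no sequence and no capture chemistry beyond class proportions.

- **Tail mixtures.** Tails are drawn from zero-truncated normal mixtures.
  Component modes at 60, 150 (and 180) nt are the observed cell-type
  regimes; sds default to 15 nt (60-component) and 20 nt (150/180), and
  additive measurement noise of sd 5 nt emulates signal-level estimator
  scatter (no empirical error model is published; both are flagged
  modelling choices). Dominant components carry weight 0.9 by default,
  reflecting the strongly unimodal per-cell-type density profiles and the
  near-complete per-transcript shifts seen in sorted cells.
- **Counts.** Reads per transcript and replicate are negative binomial
  with mean 50 and dispersion 0.3 (var = μ + 0.3 μ²), chosen so the
  10-read prefilter is exercised on both sides; a dispersion of 0 gives
  fixed depth for calibration scenarios.
- **Artefacts.** QC failures and low-confidence reads are planted as
  exactly `round(rate · n)`-sized disjoint random subsets (defaults 5%
  each); low-confidence reads draw uniform confidences in [0.30, 0.85),
  others in [0.90, 1.00).
- **Terminal-modification mix.** The ten-duplex library is simulated
  multinomially at the printed bench proportions (90 / 3 / 2.40 / 0.45 /
  0.08 / 0.08 / 3 / 0.75 / 0.20 / 0.05%, renormalised since the printed
  column sums to 100.01% from rounding).
- **Count tables.** Planted up/down/others classes emit log2FCs drawn
  N(±2, 0.3²) (others: N(0, 0.3²)); p is the two-sided normal tail of the
  observed effect at that known standard error and q is BH over all
  transcripts. This is a caricature of a differential-expression output —
  adequate for testing the classifier, not a count model.
- **Determinism.** All randomness flows from one master seed through
  numpy's PCG64; child streams are spawned from `SeedSequence(seed)` in a
  fixed order (one per condition × replicate). Identical (truth, seed)
  pairs regenerate byte-identical files; truth manifests serialise to JSON
  alongside every dataset.
- **Scenarios.** `make_spermiogenesis_scenario` plants a majority (80%)
  tail-lengthening spermatocyte→round-spermatid transition, ~1%
  shorteners, stability-resolved elongation profiles, and a small target
  set (sentinels `Odf1-like`, `Smcp-like`, `Insl3-like` among 10) whose
  mixture weight flips from 150- to 60-dominant in the mutant genotype.
  `null_truth` and `recovery_truth` provide calibration fixtures.

### What passing tests do and do not show

The generator captures replicate structure, mixture-shaped tail
distributions, overdispersed counts and demultiplexing artefacts; it does
not capture transcript-length-dependent capture bias, alignment errors,
isoform ambiguity, batch effects, or correlated noise between replicates.
Calibration results (type-I error, recovery rates) therefore validate the
statistics under the stated model, not the behaviour of any particular
sequencing run.

## Problem sizes and numerical checks

The test suite validates: exact agreement of window percentages with
brute-force per-read counting (1,000 reads); Welch p-values against an
independent reference implementation to |Δp| < 1e-10 (100 random 3-vs-3
cases); a null false-positive rate in [0.03, 0.07] on 2,000 transcripts at
3 vs 3 replicates × 50 reads; recovery of all 10 planted targets among
1,000 transcripts at 50 reads/replicate; recovery of analytic mixture
window masses within ±3 percentage points for ≥ 95% of 400 transcripts at
200 reads × 3 replicates (the analytic mass integrates the truncated
mixture against the noise kernel, an oracle independent of the sampling
path); and group separation (Kruskal–Wallis p < 1e-6, ordered medians)
under a planted +20-point window-occupancy offset. These sizes were chosen
as the smallest at which the binomial/normal error bounds above are
meaningful; the full suite runs in well under a minute.

## Known limitations

- The differential tail test assumes replicate means are approximately
  normal; at very low read counts (just past the prefilter) this is rough.
- Window fractions are compared descriptively; no compositional model is
  fitted across windows.
- Terminal-modification analysis stops at class counts; uridylation-length
  structure within BC3/BC4 is simulated but not statistically modelled.
- The LOESS smoother is evaluated on the histogram grid only and has no
  uncertainty band.
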