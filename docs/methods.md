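# Methods

## The read-depth model

A cfDNA WES sample is reduced to a vector of per-bin read counts RC(*i*)
over variable-length bins that each contain exactly 50 uniquely mappable
bases inside the capture target, restricted to autosomes 1–22 (sex
chromosomes differ systematically between sexes and are excluded). Bins are
built by scanning the target/mappable intersection left to right and cutting
after every 50th mappable position; a trailing run shorter than 50 cannot
satisfy the definition and is dropped. GC ratio is computed over the full
bin footprint [start, end) — not only the mappable positions — because the
bias acts on fragments spanning the whole region; all-N bins are masked.
Coordinates are 0-based half-open internally, BED in/out, SEG out in the
conventional 1-based inclusive form.

Counting assigns each primary, non-duplicate read with mapping quality ≥ 1
to the bin containing its *leftmost aligned position*, so every read counts
exactly once and count totals are conserved. At 50-mappable-base bin scale
the choice between start-position and any-overlap assignment is immaterial;
the start rule is the standard one in read-depth CNV callers.

## Normalization chain

Three profiles per sample, all on the ratio scale with neutral copy state 1:

1. **NRC_raw(i) = RC(i) / median(RC)** — the median over unmasked bins (an
   even-length median is the mean of the central pair). This leaves the
   shared capture-efficiency pattern intact.
2. **NRC_corrected(i) = median_j( NRC_raw,test(i) / NRC_raw,ctrl_j(i) )**
   over a panel of healthy-subject profiles. The elementwise ratio cancels
   the capture pattern; the median over controls is robust to any single
   aberrant control. Bins masked in any panel member, or with a panel value
   below epsilon = 1e-6, are masked rather than imputed.
3. **NRC_GC,corrected(i) = median_j( r_j(i) / f_j(i) )** where
   r_j = test/control_j and f_j is a LOESS fit of r_j against bin GC ratio.
   The LOESS is fitted *per control on that control's ratio vector* — the
   ratio embeds the test sample, so the fit absorbs exactly the residual
   GC trend of that test/control pair. Fits use tricube-weighted local
   linear regression on the span-nearest neighbors (statsmodels lowess)
   with span 0.3 and 2 bisquare robustness iterations; the robustness
   passes keep CNA-bearing bins from bending the GC curve. The span is
   configurable; 0.3 is wide enough that a 500-bin event cannot dominate
   any neighborhood at desk scale, narrow enough to track a smooth unimodal
   bias. Fitted values are clamped at epsilon before division and bins
   whose fit hits the clamp are masked, so the masked set grows
   monotonically along the chain.

Because each stage divides by a quantity proportional to the sample's own
scale, the GC-corrected profile is invariant to global rescaling of the
test sample's counts (verified to 1e-6).

### Diagnostics

Residual GC bias is quantified as the per-pair correlation (Pearson and
Spearman) between NRC and GC before and after correction, compared by a
paired two-sided Wilcoxon signed-rank test (exact null up to n = 25,
zero differences dropped, ties mid-ranked). For pattern-level comparisons
the signals can first be denoised with a translation-invariant wavelet
transform: cycle spinning over min(n, 32) circular shifts, Haar basis, soft
thresholding of detail coefficients at the universal threshold
sigma·sqrt(2 ln n) with sigma estimated as MAD(finest details)/0.6745. The
basis and threshold are our choices; any reasonable TI shrinkage gives the
same qualitative picture.

## Segmentation

Circular binary segmentation on log2(NRC) (neutral 0, symmetric gains and
losses; ratio-scale means are 2^mean). Per chromosome, the best split is
the arc (contiguous window of the circularized bin sequence) maximizing

    T = |mean(arc) − mean(rest)| / (s · sqrt(1/k + 1/(n−k)))

with s the standard deviation of the segment after trimming fraction 0.025
from each tail. Every circular split equals some linear window of length
k ≤ n/2, so the search is exhaustive over those windows; ties break to the
leftmost, then shortest arc. Significance is assessed by permutation of bin
order: the best-arc statistic is recomputed for randomly permuted copies
and the segment splits when the permutation p-value is ≤ alpha. Defaults —
alpha 0.01, 10,000 permutations, trim 0.025, no undo step — mirror the
documented defaults of the reference R implementation of CBS; we implement
the pure-permutation test rather than its hybrid tail approximation, so
agreement is by contract (verified against exhaustive-search oracles), not
bit-for-bit.

Permutations stop early once a 95% Clopper–Pearson interval for the
p-value lies entirely on one side of alpha — a clear split is accepted
after ~300–460 permutations and a clear null rejected after a few dozen —
and the decision is deterministic given the seed (one RNG stream per
chromosome, consumed in a fixed order). Permutation statistics are computed
in single precision for throughput; a permutation that reproduces the
observed arrangement must count as a tie, so exceedances are counted with a
1e-4 relative slack. Masked bins are skipped: segments span them
positionally but `n_bins` counts unmasked members only. Segment means are
arithmetic means of member log2 values.

## Calling and the detection threshold

The detection threshold is an empirical null from the panel of normals:
each panel member in turn is treated as a test sample against the remaining
members, run through the full normalization + CBS chain, and the absolute
segment means from all runs are pooled; the threshold is the 99.5th
percentile of that pool. Since test and controls are all normals, any
segment mean in the pool is technical noise.

Two safeguards, both package defaults at the pipeline level and both
configurable:

* **Marker support** (`min_bins`, default 10 ≈ 500 mappable bases): segments
  supported by fewer bins are excluded from the null pool and never called.
  Occasional few-bin outlier clusters reach |log2| of 0.5 and more in pure
  noise; ten markers is the customary minimum in copy-number calling and is
  still far below the size of any real focal CNA.
* **Threshold floor** (`threshold_floor`, default 0.15): the LOO percentile
  is taken as max(percentile, floor). On clean data the pooled null can fall
  to ~0.03 log2, well below the noise level of an independent sample. The
  floor encodes the empirical detection limit of cfDNA read-depth analysis —
  a 4-copy amplification at ~11% tumor fraction produces |log2| ≈ 0.14, and
  below that ctDNA level copy-number signal is obscured by normal cfDNA —
  making the caller deliberately conservative rather than nominally
  calibrated.

A segment is a gain when mean ≥ +t, a loss when mean ≤ −t; equality counts
as exceeding. The threshold is global across samples (a per-sample variant
is a config flag). Genes are annotated by any-overlap (≥ 1 bp) with an
exceeding segment, inherit its direction, are flagged as conflicts when they
touch both a gain and a loss, and are reported not-assessable (never
neutral) on chromosomes absent from a profile.

### Inspection cost

For review efficiency we rank a profile's segments by descending |log2
mean| (ties in genomic order) and accumulate genomic length and segment
count until the first segment overlapping a target gene is included; if no
segment overlaps the gene the totals cover the whole profile with
`found = False`. The metric is monotone: raising the |mean| of a
gene-overlapping segment can only move it earlier in the ranking.

## Cohort aggregation and reference ranking

Per-sample SEG profiles are projected onto fixed windows (default 0.5 Mbp,
anchored at 0 per chromosome, final short window kept) as the
length-weighted mean of overlapping segment means; uncovered windows are
undefined, and the projection conserves the length-weighted genome mean to
1e-6. Samples average per window into a cohort profile (undefined windows
drop out per window, not per profile). Against each reference profile the
Spearman correlation is computed on pairwise-complete windows (average
ranks on ties; references with fewer than 10 complete windows are skipped),
transformed as z = atanh(rho)·sqrt(n−3) with a two-sided normal p-value,
and Benjamini–Hochberg-adjusted across the K references compared. We
average per-sample window values rather than pooling segments before
windowing, so every sample contributes equally regardless of its segment
count. Intra-patient reproducibility is the within-patient pairwise
Spearman rho on window values, summarized by median and IQR.

## Synthetic data

The generator produces the statistical structure the pipeline assumes, on a
pseudo-genome (default 4 chromosomes, ~10,000 bins of ~10 kb mean span) so
no external reference is ever needed:

* **Shared capture pattern** e_i = exp(capture_sd · AR1(phi = 0.9)), drawn
  once per cohort. capture_sd = 0.6 reproduces inter-sample raw-count
  correlations near 0.95; the AR(1) autocorrelation reflects the regional
  coherence of real capture efficiency and is what makes *raw* profiles
  shatter into hundreds of spurious segments, as real uncontrolled cfDNA
  profiles do.
* **GC bias**: multiplier 1 + a·(1 − ((gc − 0.45)/0.25)²), floored at 0.1,
  with per-sample amplitude a ~ N(0.3, 0.15) truncated at 0. Bin GC is a
  clipped AR(1) process centered at 0.55: exome capture skews GC-rich, so
  the unimodal bias (peaking near GC 0.45) is falling — hence monotone —
  over most of the observed range. Under these defaults a normal-vs-panel
  run shows median |Spearman rho(NRC, GC)| ≈ 0.16 before GC correction and
  ≈ 0.005 after.
* **Counts**: negative binomial with size 50 (cfDNA WES counts are
  overdispersed relative to Poisson) around mean depth 200 per bin.
* **Tumors**: bins inside an event of tumor copy number c have their mean
  multiplied by (1 − TF) + TF·c/2; the truth SEG records
  log2((1 − TF) + TF·c/2) per event. Events are bin-aligned and
  non-overlapping.

What the generator does *not* emulate: fragment-size structure, mappability
variation beyond the bin definition, focal–arm-level event hierarchies,
subclonal mixtures, and real exome geometry (hg19 coordinates, chromosome
count). Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not performance on any particular
real dataset.

## Problem sizes and numerical choices

Benchmark experiments run at desk scale, chosen so the full suite completes
comfortably on one CPU: GC-null runs use 2,000-bin panels; CBS oracle
signals are ≤ 200 bins with exhaustive brute-force comparators; parameter
recovery and cost ordering use 8,000-bin genomes (4 × 2,000), depth 200,
events of 120–650 bins; ranking uses 6,000 bins at 0.5 Mbp windows.
Epsilon for positivity clamps is 1e-6 throughout; LOESS requires ≥ 10
points and a neighborhood of ≥ 3; Wilcoxon tests switch from exact to
normal approximation above n = 25; single-bin chromosomes become single
segments; a degenerate all-zero null pool yields threshold 0 with a
warning.

## Known limitations

* The GC correction is one-dimensional; a joint GC × mappability model
  would capture residual structure it cannot.
* The permutation CBS is contract-equivalent, not bit-compatible, with the
  hybrid-approximation reference implementation.
* The detection threshold construction is a stand-in for an unpublished
  formula; its floor makes calling conservative by design, and tumor
  fractions below ~10% are expected to go undetected.
* Reference ranking treats references as fixed profiles; no uncertainty is
  propagated from the reference cohorts themselves.
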