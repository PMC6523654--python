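# Methods

## Model

Replication timing is inferred from the read-depth contrast between a
flow-sorted S-phase fraction and a G1 baseline. Writing `p(x) ∈ [0, 1]` for
the expected replicated fraction at locus `x` in the sorted S population, the
relative S-phase sampling density is `1 + p(x)` (copy number between 1x and
2x), while G1 is uniform-copy everywhere. The pipeline estimates an affine
transform of `p(x)`; the final z-normalization (autosomal mean 0, SD 1) makes
the absolute scale immaterial, so profiles are reported in genome-wide SD
units.

The estimator proceeds on windows of constant G1 read count rather than
constant width: G1 depth absorbs mappability and copy-number structure, so
windows are narrow where coverage is good and wide where it is poor, and the
per-window S/G1 ratio is directly comparable across the genome.

## Pipeline stages and the choices behind them

**Read representation.** One record per fragment (the full pair), coordinates
0-based half-open. The read-1 5′ coordinate is the fragment's position for all
counting; the mate 5′ coordinate is the opposite endpoint.

**Duplicate marking.** Single-end mode groups on (chrom, read-1 5′, strand);
paired mode adds the mate 5′ coordinate. One survivor per group: highest MAPQ,
ties by lowest start, then end, then strand, then input order — the full-
coordinate tie-break makes the surviving *fragment set* invariant under input
shuffling (with a mapq/start-only tie-break, two distinct fragments in one
single-end group could swap survivorship with input order).

**Filtering order** is dedup → MAPQ (default threshold 20, configurable; the
underlying criterion for "poorly mapped" is aligner-specific, and a MAPQ
cutoff is the portable proxy) → coverage filters. Duplicates must not inflate
bin coverage, and coverage should be judged on reads that could actually be
used.

**Coverage filters.** Fixed bins from coordinate 0 (100 Kb for the
high-coverage filter, 500 Kb for the low). Thresholds are nearest-rank
percentiles over non-empty bins genome-wide: the high filter excludes bins
strictly above the count at ascending rank ⌈0.99·n⌉ (the "top 1%" reading),
the low filter excludes bins strictly below the count at rank ⌊0.005·n⌋+1.
Strict inequalities make an all-tied genome a no-op and give exactly 1% /
0.5% exclusion when all counts are distinct. The exclusion mask is the union
over both fractions of a sample and is applied to both: a bin untrustworthy
in either fraction must not contribute to the S/G1 ratio at all (a bin
excluded in only one fraction would otherwise leave windows spanning a region
where one numerator is artificially empty, producing localized spurious
excursions).

**Windows.** Within each contiguity segment, window *i* covers usable G1
reads `[100·i, 100·i + 200)`; start = first read position, end = one past the
last, midpoint = median read position (robust to skewed placement). Segments
break at annotated assembly gaps, excluded bins, and read deserts longer than
1 Mb. The 100-read step is fixed by the window arithmetic: 10 consecutive
windows spanning 1100 distinct reads forces `200 + 9·s = 1100`.

**Raw statistic.** S count in the window interval divided by the usable G1
count in that interval, scaled to profile mean 1. The G1 denominator is 200
everywhere except where tied (repeat-collapsed) coordinates place extra reads
inside the interval; using the interval count keeps the ratio unbiased there,
whereas bare S counts inflate 1.5–2x inside synthetic centromeres.

**Outlier filter.** Per segment, an optimal penalized piecewise-constant fit
(dynamic programming over all partitions) with the noise variance plugged in
at 0.04 (squared raw-ratio units) and penalty `2σ²·log n` per piece — the
known-variance BIC rate. A minimum piece size of 5 windows prevents an
isolated outlier from claiming a private piece (it must instead stand out
against its piece's mean). Windows deviating more than `3σ = 0.6` from their
piece mean are removed; segments under 5 windows pass through. Genuine copy-
number steps are absorbed by a changepoint and survive; isolated spikes are
removed. The DP is verified in the tests against exhaustive partition
enumeration (small n) and an independently coded memoized recursion (n=200).

**Smoothing.** `scipy.interpolate.make_smoothing_spline` minimizes
`Σ(yᵢ−f(xᵢ))² + λ∫f″²`; the fidelity-weight convention used here
(`p·Σ(…)² + (1−p)·∫f″²`, x in bp, default `p = 1e-16`) maps to
`λ = (1−p)/p`. At the default window density this gives an effective
smoothing bandwidth of tens of kb. Numerically the fit is solved in
unit-range x (the penalty rescales exactly as `s⁻³` under `x → x/s`); when
the rescaled λ exceeds 1e4 the exact λ→∞ limit (the least-squares line) is
returned, since the true solution is within ~1e-6 of it there while the
banded solver itself degrades. Tied midpoints are averaged before fitting;
segments with fewer than 5 distinct midpoints pass through unsmoothed (the
solver's minimum support).

**Normalization.** Mean/SD (population SD, ddof = 0) computed over autosomal
windows (chromosome names not in {X, Y, M/MT}, configurable); the transform
is applied to every window including sex chromosomes. Idempotent.

**Autocorrelation QC.** Each segment is linearly resampled to a uniform grid
(default 100 Kb); r(lag) pools pairs across segments. Genuine RT signal stays
strongly autocorrelated over megabases; white noise does not.

## Centromere analyses

Inclusion requires an *average* density of ≥ 10 G1 windows per Mb over the
whole centromere (total member windows / length in Mb), membership by window
midpoint — the simplest unambiguous reading of "contains". Included
centromeres are divided into 100 equal bins; bin values are means of member
windows and empty bins stay missing rather than interpolated (interpolation
would manufacture signal exactly where mappability failed). The
cross-centromere aggregate is the bin-wise mean with a min/max envelope over
non-missing entries. Pericentromere overlays use a three-part frame — 50
flank bins of width flank/50 on each side (default flank 5 Mb, truncated at
chromosome ends) around the 100 centromere-body bins — so profiles anchor to
centromere boundaries before averaging. No re-smoothing is applied after
binning.

## Cross-sample statistics

Two samples never share windows (each sample's windows come from its own G1
reads), so profiles are matched by linear interpolation onto a 10 kb grid
restricted to loci covered by segments in both samples. Correlations are
Pearson r per region: whole chromosomes with the centromere excised (both
arms pooled under one region id), individual centromeres, and nulls. The
size-matched null draws, per iteration and requested length, an interval
uniformly over all non-centromeric placements genome-wide; the window-count-
matched null draws contiguous runs of exactly k shared grid points. Observed
and null r-distributions are compared with a two-sample KS test plus an SD
ratio; fewer than 5 observations on either side is refused. Defaults: 1000
draws, minimum 3 shared grid points per reported r.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline must survive,
not sequencing chemistry (no bases, qualities, errors, or aligner).

* **Genome**: `n` chromosomes (default 2 × 10 Mb) with one mid-placed
  centromere (default 1 Mb) modelled as a tandem repeat array (unit 171 bp,
  50 distinguishable units).
* **Truth**: timing at evenly spaced control points (default 20/chromosome)
  is a stationary Gaussian process with a squared-exponential kernel of
  correlation length 2 Mb, standardized per chromosome, cubic-spline
  interpolated to a 1 kb grid. This matches the multi-megabase
  autocorrelation of real profiles; amplitude 0 gives a flat landscape. The
  replicated fraction is the rank-rescale of timing into [0.05, 0.95] —
  monotone, and bounded away from the degenerate limits so recovery tests
  retain dynamic range. Note that on finite toy chromosomes the *empirical*
  ACF at lags of several Mb fluctuates around zero (sampling noise ~0.2), so
  only decay to that noise floor — not a strict ordering of long-lag
  estimates — is a property of the generator.
* **Reads**: fragment positions uniform (G1) or ∝ 1+p (S); counts per
  chromosome multinomial in the total sampling mass; fragment lengths normal
  (default 400 bp ± 10%, truncated at one 100 bp read length); strands
  random. Defaults of 1M fragments per fraction give ~9,000 windows on the
  default genome.
* **Repeat collapse**: each array exposes its `n_distinct_units` alignable
  anchors *spaced evenly across the array*; a fragment starting in the array
  is reported at its nearest anchor (mate keeps the true fragment length) and
  receives MAPQ 0 with probability 0.85. Even spacing keeps centromeric
  coverage spread out — as probabilistically assembled centromere reference
  models do — so the high-coverage filter does not trivially erase the whole
  centromere, while still producing the signature phenomenon: many fragments
  with identical read-1 coordinates but distinct mates.
* **Duplicates**: PCR (rate 0.02) and optical (0.01) duplicates are exact
  endpoint copies of a source fragment; the two labels are statistically
  identical here because the pipeline treats them identically.
* Every record keeps its true origin and an artifact-class label, and all
  randomness flows through one seeded generator (identical seed ⇒ identical
  output).

**What passing tests do and do not show.** The generator reproduces
mappability-driven window widths, repeat collapse, duplicate confusion, and
smooth RT structure; it does not model GC bias, copy-number variants,
S-phase substage composition (uniform sampling within S, i.e. density
∝ 1+p, is the simplest consistent model and is a modelling choice, not an
observed fact), aligner-specific MAPQ behaviour, or real α-satellite
sequence. Recovery of r ≈ 0.996 on synthetic data therefore validates the
pipeline's arithmetic and robustness to these artifact classes, not its
performance on any particular library preparation.

## Problem sizes

Default test/acceptance conditions: 2 × 10 Mb genome, 1M + 1M fragments
(≈ 9,000 windows; a full simulate-and-profile run takes a few seconds); the
cross-sample analyses use a 4 × 5 Mb genome, four samples at 400k + 400k
fragments, and 1000 null draws. These sizes make every stage's statistical
checks well-powered while keeping a complete run interactive.

## Known limitations

* The changepoint routine is a penalized piecewise-constant fit, not a port
  of MATLAB `segment` (an adaptive AR segmentation whose full
  parameterization is not recoverable); only the plug-in variance 0.04 and
  the 3σ rule are anchored, and equivalence is established against
  enumeration oracles, not against MATLAB.
* Ploidy is taken as declared; no ploidy estimation or correction beyond the
  uniform-copy G1 baseline.
* No origin calling, no early/late two-fraction log-ratio mode, and no
  satellite-family annotation.
* Single-end mode degrades centromeres by design (that contrast is the
  point); it is provided for re-analysis, not recommended use.
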