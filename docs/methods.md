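# Methods

This note documents the statistical procedures implemented in `survscan`,
their assumptions, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Copy-number preprocessing

Raw per-marker copy estimates are modelled as a true segment copy level
plus heavy marker-level noise.  Two transforms are applied before any
testing:

* **Local median smoothing** (default window 10 markers).  For each sample
  independently, marker *i* is replaced by the median of the raw values in
  a centred window — ⌊(w−1)/2⌋ markers to the left, the rest to the right —
  truncated at chromosome boundaries, so windows never mix chromosomes.
  Missing values are excluded from each median; an all-missing window stays
  missing.  Centred truncation is the least-biased convention for a running
  median; window 1 disables smoothing.  Larger windows suppress more noise
  but blur focal alterations shorter than the window.
* **Mode-to-2 ploidy scaling** (off by default).  Tumour ploidy is unknown;
  a hyperdiploid genome read against a diploid reference looks like
  genome-wide loss.  The modal copy level of each sample is estimated as
  the midpoint of the fullest bin of a fixed-width histogram (0.1-copy
  bins spanning [0, 8], edges offset by −0.05 so that multiples of 0.1 are
  bin midpoints — a profile sitting at exactly 3.0 copies yields mode 3.0),
  and the profile is multiplied by 2/mode.  At least 20 non-missing values
  are required, and a mode ≤ 0.2 copies is rejected as degenerate.  The
  estimate is quantized at half a bin width (±0.05 copies), which bounds
  the scale-equivariance error at ~2.5% for near-diploid samples.
  Scaling acts on the raw profile (whose histogram carries the ploidy
  signal), smoothing afterwards.

Group assignment at a marker is by fixed inclusive thresholds on the
(smoothed) copy number: Deletion ≤ 1.5, Gain ≥ 2.5, "No change" strictly
between; missing values are unassignable and drop out of that marker's
test only.

## Survival statistics

All samples missing the (time, event) pair are omitted from every
analysis and the omitted count is reported alongside the results.

**Kaplan–Meier.**  The product-limit estimator per group; at each distinct
event time with *d* events among *n* at risk the survival multiplies by
(1 − d/n).  Censored-only times update the risk set but not the curve.
Per-group expected events come from the log-rank decomposition over the
pooled event times, so ΣObs = ΣExp across groups holds exactly on every
dataset — a built-in accounting identity the tests exercise.

**k-sample log-rank.**  Full-covariance version: the observed-minus-
expected vector on g−1 groups against the summed hypergeometric
covariance, chi-square with g−1 degrees of freedom (g = nonempty groups
among complete cases), with a generalized inverse when the covariance is
singular.  The conservative sum-of-variances variant is not used because
it miscalibrates 3-group tests.  A *display gate* accompanies every
result: the p-value is considered reportable only when at least two
groups have ≥ 5 expected events; below that the chi-square approximation
is unreliable.  The statistic is always computed and stored regardless.

**Cox proportional hazards.**  Newton–Raphson on the partial likelihood,
starting at β = 0, stopping when the log-likelihood changes by < 1e-8
(max 50 iterations) and then taking one final polishing step, which makes
β̂ agree with well-converged reference implementations to better than
1e-6 relative error.  Tied event times use the Breslow approximation by
default (simplest to verify; Efron is available via `ties="efron"`).
Standard errors come from the inverse observed information; the reported
marker score is z = β̂/SE of the copy-number term, also in multivariate
fits with adjustment covariates.  Step-halving guards against overshoot;
a fit whose per-SD coefficient exceeds 50 in magnitude is flagged as a
monotone likelihood (separation) and reported as non-converged, never as
a score.  A score test statistic at β = 0 is recorded as well (it is the
asymptotic twin of the 2-group log-rank, which the tests check by
simulation).

## The genome scan

One of every `stride` (default 10) consecutive markers is tested, the
grid restarting at the first marker of each chromosome — deterministic
and chromosome-respecting, and nested: doubling the stride tests a subset
of the same markers with identical scores.  Smoothing makes neighbouring
markers' statistics redundant, which is what justifies the stride.
Scores: −log₁₀ p for log-rank (3 ⇔ p = 0.001), signed z for Cox.  Markers
with fewer than two nonempty groups, degenerate covariates or
non-converged fits carry a *missing* score — never zero, which would be a
valid (maximally null) score value.

The scan operates on the already-preprocessed matrix; preprocessing is a
single explicit pipeline step performed when the `GenomeSurvivalScan`
model is constructed.  Permutation reruns therefore execute literally the
same scan code on permuted inputs.

## MaxT permutation

Two schemes simulate the global null:

* **clinical** — one uniform permutation of the (time, event) pairs
  across all samples per replicate; copy data untouched.
* **blocks** — per sample independently, K−1 distinct breakpoints drawn
  uniformly from the L−1 internal boundaries of the genome-ordered
  profile; the K blocks are rearranged by a uniform permutation with
  within-block order intact.  This preserves the local correlation
  structure of the copy numbers while decoupling genome position from
  the phenotype.  Blocks may span chromosome boundaries (the profile is
  ordered by chromosome then position and partitioned as a whole).
  The permutation is applied to the smoothed matrix: re-smoothing a
  block-permuted raw profile would alter values near the K−1 new
  junctions, but leave the other L−K+1 windows — and hence the tested
  statistic's input distribution — unchanged, so permuting the smoothed
  values is the cheaper equivalent.

For each of B permuted datasets the identical scan is rerun and the
maximal score recorded; the ⌈αB⌉-th largest of the B maxima is the
genome-wide threshold at level α (with B = 100, α = 0.05: the 5th
largest), and the add-one empirical genome-wide p is
(1 + #{perm max ≥ observed max})/(B + 1), never exactly zero.  B must be
at least ⌈1/α⌉ for the order statistic to exist.

**Which scores enter the maximum.**  The maximum (and region calling) is
taken over *eligible* markers only: log-rank markers passing the
expected-events display gate, Cox markers with converged fits.  Without
the gate, markers with a one-or-two-sample extreme group dominate the
null maxima — a singleton group whose member dies first produces
χ² ≈ n and a −log₁₀ p in the tens — and the threshold becomes useless
for detection.  The gate is applied identically to the observed and
every permuted scan, so observed and permuted maxima remain exchangeable
under the null and family-wise error control is untouched (verified by
the type-I-error simulation below).  The full ungated score track is
still written to the scan table.

Reproducibility: a master seed spawns one child seed sequence per
permutation (`SeedSequence.spawn`); within a permutation, per-sample
draws are taken sequentially from that permutation's generator.  Equal
seeds give bit-identical maxima and thresholds.

Significant regions are maximal runs of consecutive tested markers at or
above the threshold within a chromosome, reported as 1-based inclusive
intervals with peak marker and score; missing or ineligible scores break
runs.

## Expression clustering and cluster K-M

Genes are filtered by coefficient of variation (sd/mean within
[0.5, 1000] by default, the classic convention; configurable), gene rows
standardized, and samples clustered agglomeratively on 1 − Pearson
correlation distance with average linkage (complete and centroid
available); scipy's deterministic lowest-index tie-breaking applies.  A
constant sample column is rejected by name before standardization, since
its correlations are undefined.  Branch "selection" replaces interactive
clicking: cluster node ids or a height cut yield per-sample labels, and
the labelled clusters are compared with the same Kaplan–Meier + log-rank
machinery (including the expected-events gate and the omitted-sample
report).  Selection is pure label plumbing — passing the same labels
directly gives identical results.

## The synthetic-data generator

The generator emulates a myeloma-style SNP-array cohort and defines the
default study conditions used throughout the tests:

* **Demo study** — 200 samples; 2,000 markers over 4 chromosomes of 500
  (100 kb spacing); one 50-marker deletion region (markers 101–150 of
  chromosome 1) to 1 copy, carried by 40% of samples; Gaussian copy noise
  sd 0.35; survival exponential with baseline rate λ₀ = ln 2/36 (null
  median 36 time units) multiplied by exp(β) = 3 for carriers; independent
  uniform(0, 120) censoring.
* **Null study** — 100 samples, 500 markers, no planted region.

Carrier sets use an exact count, round(fraction × n) drawn without
replacement, so group sizes match the stated fraction.  The exponential
baseline keeps everything checkable in closed form: carrier median event
time ln 2/(λ₀·HR) = 12, and the null censored fraction
(1 − e^{−λ₀C})/(λ₀C) ≈ 0.39.  Optionally an expression matrix with
planted sample clusters is produced (log-normal signal, a signature gene
subset shifted between groups on the log scale, optional per-group
hazard effect) for the clustering workflow.  Equal seeds give
byte-identical output files.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate about real arrays: linkage-disequilibrium structure
and wavy regional noise, allele-specific intensities, batch and GC
effects, subclonal (fractional) copy numbers, non-exponential hazards,
informative censoring, and missing genotype calls.  Results on real data
depend on upstream normalization quality in ways these simulations
cannot probe.

## Simulation suite sizes and calibration choices

* The genome-wide type-I error of clinical-permutation MaxT is estimated
  on 200 null datasets (500 markers, 100 samples, stride 10, 200
  permutations each), expecting the rejection fraction in [0.02, 0.10]
  around the nominal 0.05.  This suite scans the *raw* profiles
  (window 1): under a pure-noise null, median smoothing shrinks the
  marker-level sd from 0.35 to ≈ 0.35·1.253/√10 ≈ 0.14, so virtually no
  sample crosses the 1.5/2.5 thresholds and the grouped statistic being
  calibrated would be undefined at almost every marker.  With raw
  profiles ≈ 7.6% of samples fall in each extreme group and the test is
  well defined.  This choice follows from the variance arithmetic, not
  from any observed test outcome.
* Power/localization uses 50 replicates of the demo study, both scan
  methods, clinical permutation with B = 50 at α = 0.05 per replicate —
  the planted hazard ratio of 3 sits far above any plausible threshold,
  so the modest B costs little.
* Parameter recovery fits the true carrier indicator on 10 seeds and
  expects β̂ within 3·SE of ln 3 in at least 9 (the strict all-of-10
  reading fails ~3% of the time under the model itself).
* The reference cross-check runs 50 random small instances (n ≤ 30,
  integer times with heavy ties) against R `survival`'s `survdiff` and
  `coxph(ties = "breslow")` in a single batched Rscript call, requiring
  relative agreement below 1e-6; tie-free instances are additionally
  checked against lifelines (Efron = Breslow without ties).

## Known limitations

* Single-marker tests only; no region-level statistic, no interaction
  scans, no step-down minP or FDR-based calling.
* Cox: no time-varying covariates, stratification, interval censoring or
  competing risks.
* The expected-events gate is a hard threshold; markers just below it
  contribute nothing to the genome-wide maximum.
* Block permutation assumes exchangeability of genome blocks across
  positions; strong genome-wide trends (e.g. uncorrected GC waves) would
  violate it.
* The mode estimator uses a fixed 0.1-copy bin; profiles with broad,
  flat histograms can have an unstable mode.
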