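# Methods notes

This note records the models behind each stage, the defaults and why,
what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Synthetic data: what it emulates

All generators work on the log2 scale with Gaussian noise, matching the
distributional shape of RMA-normalized microarray intensities, and every
generator returns the planted truth next to the data. Fixed seeds give
bit-identical output (one `numpy` Generator per call).

**Time course.** The layout mirrors a tet-off induction experiment: two
inducible clones (E10, E14) sampled ± tetracycline at 6/12/24/48 h and
two control lines (P2, U937T) ± tet at 48 h — 20 samples. Baselines are
uniform on [4, 12] log2 units; regulated probes carry a planted −tet
effect whose full size (|log2 FC| uniform on [1, 4] by default) is
reached at 24 h, with a 0.3/0.7 ramp at 6/12 h emulating rapid
induction. Tet withdrawal itself perturbs expression in *every* cell
line — controls included — as a per-(probe, line) N(0, 0.1) shift on the
−tet columns, so the background-exceedance rule is genuinely exercised,
plus N(0, 0.05) measurement noise per cell. Not emulated: probe-level
(PM/MM) structure, batch effects, intensity-dependent variance,
cross-hybridization. Passing recovery tests therefore shows the filter
logic is right, not that it is robust to array artefacts.

**Cohorts.** The splitter gene is a two-component Gaussian mixture
(defaults: 200 patients at N(4, 0.5²), 20 at N(9, 0.5²) — a ~9% high
fraction, comparable to the published AML cohorts) and the response gene
is baseline − delta·1[high] + N(0, 0.5), delta = 1 log2 unit by default.
Real cohort expression is neither Gaussian nor homoskedastic and the
true EVI1-high fractions ranged 5.6–16.2%; the mixture is the cleanest
substrate on which cutoff and test behaviour can be verified against
ground truth.

**Promoters, annotations, Ct tables.** IID background sequence at a set
GC content with PWM consensus sites planted verbatim; per-(gene, term)
Bernoulli annotations with one term optionally enriched inside a
designated study set; Ct tables with the housekeeping gene at 20
cycles, the target at 25, a −log2(fold) shift in the treated condition
and N(0, sd) noise per technical replicate.

## Regulated-gene filter

Intensity, fold-change, and background rules as in the README. Open
choices, decided as follows:

- The exceedance exponent reads the effect as |log2 FC| at 48 h and the
  control effect as max(|log2 FC at 48 h|) over P2 and U937T, compared
  on the log2 scale. This is the only reading under which a minimum
  two-fold gene can pass with near-zero control effects; base (10) and
  divisor (3) are exposed as parameters.
- A single consistent sign is required across both clones at 24 h and
  48 h ("induced or repressed" is one direction, not either per time
  point).
- Per-gene collapse keeps the probe with the largest mean |log2 FC| at
  48 h over the clones; ties break on the lexicographically smallest
  probe id, for determinism.
- 6 h and 12 h fold changes are carried through for reporting but take
  part in no criterion.

A property worth knowing: the control-effect bound implied by the rule,
eff·10^(−eff/3), *shrinks* as the effect grows — 0.47 log2 units at
eff ≈ 1.3, 0.30 at eff = 3, 0.19 at eff = 4. Under Gaussian background
(SD 0.1) the rule therefore starts excluding genuinely regulated probes
once planted effects exceed ~3 log2 units, by design: a very large
induction must be matched by an essentially silent control. Perfect
sensitivity/specificity holds when planted effects sit near the
two-fold criterion (tests use 1.5–2.0 log2 units), and the filter always
equals a brute-force per-probe reference regardless of noise.

## Cohort dichotomization and resampling test

- KDE: `scipy.stats.gaussian_kde`, Silverman bandwidth by default
  (exposed), evaluated on 512 points spanning [min − 3h, max + 3h].
- Cutoff: interior strict local minima of the density (left-strict,
  right-non-strict to resolve plateaus deterministically). One minimum:
  take it. Several: among those with density < 5% of the maximum,
  the smallest x above the dominant (global-maximum) mode — the minimum
  closest to the low-expression distribution. None qualifying:
  `none_found`, a signal rather than an exception. Values equal to the
  cutoff go to the low group.
- Resampling: n_high patients drawn from the low group *without*
  replacement per iteration (subsampling of distinct patients; a
  with-replacement mode is available behind a flag), 10,000 iterations
  by default, SD with the n−1 denominator, Z = −M/SD exact by
  construction, p = 2(1 − Φ(|Z|)). A degenerate run (SD = 0) reports
  Z = 0, p = 1 with a flag.
- Calibration: the statistic is mildly anticonservative because SD
  measures only the subsampling variability of the low group, not the
  sampling variance of the high-group mean: under the null at the
  default design the measured type-I error is ≈ 0.076 at α = 0.05
  (3,000 simulated cohorts). Interpret borderline p-values accordingly.

## Motif scanning

ci(l) = (100/ln 4)·Σ_b f(b,l)·ln f(b,l) + 100 (0·ln 0 := 0), so a
uniform column weighs 0 and an invariant one 100. Window score as in the
README; an N contributes 0 in the numerator while the denominator is
unchanged, so unknown bases penalize rather than veto. Frequencies are
used as given (pseudocount 0 by default; `PWM.from_counts` accepts one).
Coordinates are 0-based half-open on the forward strand; reverse-strand
windows are scored on the reverse complement and reported in forward
coordinates. The core-similarity pre-filter of the classical
implementation is not applied (hook left in place). Threshold
calibration takes the smallest observed window score t at which
background hits (both strands) fall to ≤ rate·length; with a degenerate
matrix that scores everything 1 the target rate is unreachable and the
result is flagged. The synthetic PWM generator splits the non-dominant
mass unevenly (Dirichlet) precisely so that window scores are nearly
continuous and the calibrated rate lands close to its target.

## GO enrichment and qPCR

Term-for-term only: each term tested independently with the exact
hypergeometric tail (any parent-child propagation must already be in
the annotation table). The population defaults to whatever gene list
the caller supplies — in the pipeline, all genes of the simulated
universe. BH adjustment via statsmodels; adjusted p < 0.1 flags
significance. ΔΔCT assumes amplification efficiency 2 and averages
technical replicates on the Ct scale before differencing; ΔΔCt is paired
within biological replicates against the reference condition, fold
changes are summarized as mean ± SEM and the reference fold is exactly
1. Fewer than two biological replicates leaves the SEM undefined and
flagged.

## Problem sizes and tolerances

The test suite and the acceptance script run everything at desk scale:
time courses of 200–500 probes, cohorts of 220 patients, 100 kb
calibration backgrounds, 100-cohort recovery and 500-cohort null
batches (n_iter = 1000–2000 where full 10,000-iteration precision is
not needed; the Monte-Carlo error of M scales as SD/√n_iter, about 1%
of SD at 10⁴). Exhaustive Fisher validation runs over every valid
(k, n, K, N) with N ≤ 60. Hand-checkable anchors (the 3-column PWM
scores 1, 200/225, 125/225; ΔΔCt = −2 ⇒ fold 4; BH on (0.01, 0.02,
0.04)) are asserted at 1e-12.

## Known limitations

- The generators produce clean Gaussian structure; none of the
  robustness questions raised by real microarray or qPCR data (outliers,
  saturation, efficiency drift) are addressed.
- The cutoff finder assumes the low-expression mode dominates; cohorts
  where most patients are splitter-high would need the rule mirrored.
- The resampling test's anticonservatism (above) is inherent to the
  published procedure, not corrected here.
- PWM scanning is exhaustive per window; fine for promoters and 100 kb
  backgrounds, not tuned for genome-scale scans.
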