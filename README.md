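# evi1kit

Tools for calling the target genes of an inducible transcription factor
and testing whether a candidate target is anti-correlated with the
factor across patient cohorts. The package grew out of the analysis
pattern used to establish that the transcription factor EVI1 represses
*MS4A3* in myeloid leukemia: a tet-off induction time course screened
with intensity/fold-change/background filters, patient cohorts split at
kernel-density minima of the factor's expression and tested with a
resampling Z statistic, promoter scanning with information-weighted
position weight matrices, term-for-term GO enrichment, and ΔΔCT qPCR
quantification. Every stage runs on synthetic data produced by the
package's own generators, which plant known structure so recovery can
be verified — no external downloads are needed.

## Who this is for

Computational biologists who want the individual procedures (each is a
plain function over pandas/numpy objects) or the whole pipeline
(`evi1kit run`) with reproducible seeds, plain-text inputs and outputs,
and a manifest.

## The statistics at the core

**Regulated-gene filter.** For clones E10/E14 (± tetracycline at 6, 12,
24, 48 h) and control lines P2/U937T (± tet at 48 h), with log2
intensities x, the per-condition effect is log2 FC = x(−tet) − x(+tet).
A probe set is called regulated iff

1. mean(x(+tet), x(−tet)) ≥ 3 in E10/E14 at 24 h and 48 h and in
   P2/U937T at 48 h,
2. |log2 FC| ≥ 1 at 24 h and 48 h in both clones, all four with one
   sign, and
3. per clone, |log2 FC(48 h)| ≥ 10^(|log2 FC(48 h)|/3) ·
   max(|log2 FC(control, 48 h)|) — induction must exceed the
   tet-withdrawal background seen in control cells.

Genes keep the probe set with the largest mean |log2 FC(48 h)|.

**Cohort association.** The splitter gene's log2 values are smoothed
with a Gaussian KDE (Silverman bandwidth); the cutoff is the interior
density minimum (when several exist, the minimum above the dominant
low mode with density < 5% of the maximum). The high group (n_h) is
compared against 10,000 random subsamples of n_h low-group patients:
d_i = mean(response|high) − mean(response|sampled low), M = mean(d),
SD = sd(d), **Z = −M/SD**, p = 2·(1 − Φ(|Z|)). Repression of the
response gene in splitter-high patients gives M < 0, Z > 0.

**Motif scanning.** Matrix similarity of window b against PWM f with
per-position information weights ci = (100/ln 4)·Σ_b f·ln f + 100:

    score = Σ_l ci(l)·f(b_l, l) / Σ_l ci(l)·max_b f(b, l)  ∈ [0, 1]

scored on both strands; the detection threshold is calibrated so a
background sequence yields at most one hit per 10 kb.

**GO enrichment** is a one-sided Fisher exact test per term
(p = P(X ≥ k), X hypergeometric), Benjamini–Hochberg adjusted,
significant at adjusted p < 0.1. **qPCR** fold changes are
2^(−ΔΔCt) with technical replicates averaged on the Ct scale and SEM
over ≥ 3 biological replicates.

## Worked example

Simulate a cohort of 20 splitter-high and 200 splitter-low patients
(modes at log2 = 9 and 4, planted repression of 1 log2 unit) and run the
association test:

```
$ evi1kit simulate cohort --seed 11 --out cohort.tsv
$ evi1kit cohort --table cohort.tsv --iters 10000 --seed 1 --out assoc.tsv
{"cutoff": 6.84, "n_high": 20, "n_low": 200, "pct_high": 9.1,
 "M": -1.13, "SD": 0.11, "Z": 10.61, "p_value": 2.8e-26}
```

The KDE found a single density minimum at log2 = 6.84, between the two
planted modes, assigning 9.1% of patients to the high group. The mean
resampled difference M = −1.13 recovers the planted repression (its
magnitude overshoots 1.0 slightly because the high-mode patients also
carry the baseline noise), and Z = −M/SD = 10.61 rejects the null
decisively. In Python the same run is:

```python
from evi1kit import CohortDesign, simulate_cohort
from evi1kit.cohort import associate

table, _ = simulate_cohort(CohortDesign(seed=11))
cutoff, boot = associate(table, n_iter=10_000, seed=1)
print(boot.M, boot.SD, boot.Z, boot.p_two_sided)
```

The full pipeline — time course, cohort, promoter scan, GO enrichment,
qPCR — runs from one YAML config and writes a manifest of every output
with parameters, seeds, and SHA-256 hashes:

```
$ evi1kit run --config demo.yaml --out results/
```

where `demo.yaml` can be as small as `{seed: 5}` (all stages, default
designs).

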