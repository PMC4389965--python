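"""Synthetic-data generators for every pipeline input.

Each generator emulates one class of input consumed by the analysis stages:
a tet-off induction time course with planted regulated genes, patient
cohorts with bimodal splitter-gene expression, promoter sequences with
planted motif instances, gene->GO annotation tables, and triplicate qPCR
Ct tables.  All values live on the log2 scale where the downstream
statistics operate, noise is Gaussian on that scale, and every generator
returns the planted truth alongside the data so each stage can be tested
for parameter recovery.  A fixed seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timecourse import TimeCourseMatrix

CLONES = ("E10", "E14")
CONTROLS = ("P2", "U937T")
TIMEPOINTS_H = (6, 12, 24, 48)

# fraction of the full planted effect present at each time point; the
# full effect is reached by 24 h, matching the rapid induction the
# tet-off system shows
_RAMP = {6: 0.3, 12: 0.7, 24: 1.0, 48: 1.0}


@dataclass(frozen=True)
class TimeCourseDesign:
    """Design of a two-clone + two-control tet-withdrawal time course.

    Expression is simulated directly on the log2-intensity scale.
    ``n_regulated_up``/``n_regulated_down`` probes receive a planted
    -tet minus +tet effect in both clones, with |log2 FC| drawn
    uniformly from ``induced_log2fc_range`` (full size at 24 h and
    48 h).  Every cell line, controls included, additionally receives a
    background tet-withdrawal effect of SD ``background_log2fc_sd``, so
    the background-exceedance rule of the downstream filter is
    genuinely exercised.
    """

    n_probes: int = 500
    n_regulated_up: int = 20
    n_regulated_down: int = 20
    induced_log2fc_range: tuple[float, float] = (1.0, 4.0)
    background_log2fc_sd: float = 0.1
    noise_sd: float = 0.05
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    clones: tuple[str, ...] = CLONES
    controls: tuple[str, ...] = CONTROLS
    timepoints_h: tuple[int, ...] = TIMEPOINTS_H
    shared_gene_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_regulated_up < 0 or self.n_regulated_down < 0:
            raise ValueError("regulated counts must be non-negative")
        if self.n_regulated_up + self.n_regulated_down > self.n_probes:
            raise ValueError(
                "n_regulated_up + n_regulated_down exceeds n_probes"
            )
        if self.background_log2fc_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.induced_log2fc_range[0] > self.induced_log2fc_range[1]:
            raise ValueError("induced_log2fc_range must be ordered")
        if self.induced_log2fc_range[0] < 0:
            raise ValueError("induced_log2fc_range is on |log2 FC|, must be >= 0")
        if not 0.0 <= self.shared_gene_fraction < 1.0:
            raise ValueError("shared_gene_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a patient cohort with bimodal splitter-gene expression.

    Splitter (EVI1-like) log2 values are a two-component Gaussian
    mixture; the response gene (MS4A3-like) is shifted down by
    ``effect_delta`` log2 units in splitter-high patients
    (positive delta = repression).
    """

    n_high: int = 20
    n_low: int = 200
    mu_low: float = 4.0
    mu_high: float = 9.0
    sigma_low: float = 0.5
    sigma_high: float = 0.5
    ms4a3_baseline: float = 7.0
    effect_delta: float = 1.0
    ms4a3_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("group sizes must be non-negative")
        if self.sigma_low <= 0 or self.sigma_high <= 0 or self.ms4a3_sd <= 0:
            raise ValueError("sigmas must be positive")
        if self.mu_high <= self.mu_low:
            raise ValueError("mu_high must exceed mu_low")


@dataclass(frozen=True)
class PromoterSpec:
    """Specification of synthetic promoter sequences with planted motifs.

    ``planted_motifs`` holds (pwm_id, position, strand) triples; the
    consensus of the named PWM is written at that 0-based position, on
    the reverse complement for strand '-'.
    """

    length: int = 268
    gc_fraction: float = 0.5
    planted_motifs: tuple[tuple[str, int, str], ...] = ()
    n_sequences: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        for pwm_id, pos, strand in self.planted_motifs:
            if pos < 0:
                raise ValueError(f"negative motif position for {pwm_id}")
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be + or -, got {strand!r}")


def _sample_columns(design: TimeCourseDesign) -> pd.DataFrame:
    rows = []
    for line in design.clones:
        for tet in ("plus", "minus"):
            for h in design.timepoints_h:
                rows.append((f"{line}_{tet}_{h}h", line, tet, h))
    for line in design.controls:
        for tet in ("plus", "minus"):
            rows.append((f"{line}_{tet}_48h", line, tet, 48))
    return pd.DataFrame(rows, columns=["sample_id", "cell_line", "tet", "hours"])


def simulate_timecourse(
    design: TimeCourseDesign,
) -> tuple[TimeCourseMatrix, pd.DataFrame]:
    """Simulate a tet-withdrawal time course.

    Returns the expression matrix plus a truth table with one row per
    probe: probe_id, gene, status (up/down/none) and the planted
    |log2 FC| (0 for unregulated probes).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    meta = _sample_columns(design)
    n = design.n_probes

    probe_ids = np.array([f"probe_{i:05d}_at" for i in range(n)])
    genes = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    n_shared = int(round(design.shared_gene_fraction * n))
    if n_shared:
        # map a leading block of probes onto half as many genes so some
        # genes carry two probe sets
        donors = np.arange(n_shared)
        genes[donors] = [f"GENE{i // 2:05d}" for i in donors]

    status = np.array(["none"] * n, dtype=object)
    planted = np.zeros(n)
    n_up, n_down = design.n_regulated_up, design.n_regulated_down
    reg_idx = rng.choice(n, size=n_up + n_down, replace=False)
    up_idx, down_idx = reg_idx[:n_up], reg_idx[n_up:]
    status[up_idx], status[down_idx] = "up", "down"
    lo, hi = design.induced_log2fc_range
    planted[reg_idx] = rng.uniform(lo, hi, size=n_up + n_down)
    signed = planted.copy()
    signed[down_idx] *= -1.0

    baseline = rng.uniform(*design.baseline_log2_range, size=n)

    # per-(probe, cell line) background effect of tet withdrawal,
    # applied to every -tet column of that line, clones and controls alike
    lines = list(design.clones) + list(design.controls)
    background = {
        line: rng.normal(0.0, design.background_log2fc_sd, size=n)
        for line in lines
    }

    values = np.empty((n, len(meta)))
    for j, row in meta.iterrows():
        col = baseline.copy()
        if row.tet == "minus":
            col += background[row.cell_line]
            if row.cell_line in design.clones:
                col += signed * _RAMP[int(row.hours)]
        if design.noise_sd > 0:
            col += rng.normal(0.0, design.noise_sd, size=n)
        values[:, j] = col

    matrix = TimeCourseMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=meta.sample_id),
        metadata=meta,
        probe_to_gene=pd.Series(genes, index=probe_ids, name="gene"),
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene": genes,
            "status": status,
            "planted_abs_log2fc": planted,
        }
    )
    return matrix, truth


def simulate_cohort(design: CohortDesign) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a patient cohort.

    Returns a table (sample_id, evi1_log2, ms4a3_log2) and the true
    high/low labels as a boolean Series (True = splitter-high).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_low + design.n_high
    is_high = np.zeros(n, dtype=bool)
    is_high[design.n_low:] = True

    evi1 = np.empty(n)
    evi1[~is_high] = rng.normal(design.mu_low, design.sigma_low, design.n_low)
    evi1[is_high] = rng.normal(design.mu_high, design.sigma_high, design.n_high)

    ms4a3 = (
        design.ms4a3_baseline
        - design.effect_delta * is_high
        + rng.normal(0.0, design.ms4a3_sd, n)
    )

    order = rng.permutation(n)
    table = pd.DataFrame(
        {
            "sample_id": [f"pt_{i:04d}" for i in range(n)],
            "evi1_log2": evi1[order],
            "ms4a3_log2": ms4a3[order],
        }
    )
    labels = pd.Series(is_high[order], index=table.sample_id, name="evi1_high")
    return table, labels


def simulate_promoters(
    spec: PromoterSpec, pwms: dict
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate promoter sequences with planted PWM consensus sites.

    ``pwms`` maps pwm_id -> PWM (see :mod:`evi1kit.motifs`).  Returns a
    list of (sequence_id, sequence) records and a truth table of planted
    hits (sequence_id, pwm_id, start, strand).
    """
    from .motifs import reverse_complement

    spec.validate()
    for pwm_id, pos, _strand in spec.planted_motifs:
        if pwm_id not in pwms:
            raise ValueError(f"unknown PWM id {pwm_id!r}")
        if pos + pwms[pwm_id].length > spec.length:
            raise ValueError(f"motif {pwm_id!r} at {pos} exceeds sequence length")

    rng = np.random.default_rng(spec.seed)
    gc, at = spec.gc_fraction / 2.0, (1.0 - spec.gc_fraction) / 2.0
    probs = np.array([at, gc, gc, at])  # A C G T
    bases = np.array(list("ACGT"))

    records = []
    truth_rows = []
    for i in range(spec.n_sequences):
        seq_id = f"promoter_{i}"
        seq = rng.choice(bases, size=spec.length, p=probs)
        if i == 0:  # motifs are planted in the first sequence
            for pwm_id, pos, strand in spec.planted_motifs:
                cons = pwms[pwm_id].consensus()
                if strand == "-":
                    cons = reverse_complement(cons)
                seq[pos : pos + len(cons)] = list(cons)
                truth_rows.append((seq_id, pwm_id, pos, strand))
        records.append((seq_id, "".join(seq)))
    truth = pd.DataFrame(
        truth_rows, columns=["sequence_id", "pwm_id", "start", "strand"]
    )
    return records, truth


def simulate_pwm(
    length: int = 8,
    dominance: float = 0.85,
    seed: int = 0,
    pwm_id: str = "synthetic_pwm",
):
    """A synthetic position frequency matrix with one dominant base per
    position (frequency ``dominance``), the remaining mass split
    randomly (Dirichlet) over the other three bases.

    Stands in for binding-site matrices when none are supplied; the
    uneven non-dominant frequencies keep the window-score distribution
    continuous, which threshold calibration relies on.
    """
    from .motifs import PWM

    if not 0.25 <= dominance <= 1.0:
        raise ValueError("dominance must lie in [0.25, 1]")
    rng = np.random.default_rng(seed)
    freqs = np.empty((length, 4))
    dominant = rng.integers(0, 4, size=length)
    for l in range(length):
        rest = (1.0 - dominance) * rng.dirichlet(np.ones(3))
        row = np.insert(rest, dominant[l], 0.0)
        row[dominant[l]] = dominance
        freqs[l] = row
    return PWM(pwm_id, freqs)


def simulate_go_annotations(
    n_genes: int,
    n_terms: int,
    density: float,
    seed: int,
    study_size: int = 0,
    enrichment_factor: float = 1.0,
) -> tuple[pd.DataFrame, list[str], list[str], str | None]:
    """Simulate a gene->term annotation table.

    Each (gene, term) pair is annotated independently with probability
    ``density``.  If ``study_size`` > 0 a study set is drawn and the
    first term is planted at ``enrichment_factor`` times the background
    density within it (capped at 1).  Returns the annotation table, the
    population gene list, the study list, and the enriched term id
    (None when no enrichment was planted).
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    if study_size > n_genes:
        raise ValueError("study_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    terms = [f"GO:{i:07d}" for i in range(n_terms)]

    annotated = rng.random((n_genes, n_terms)) < density

    study: list[str] = []
    enriched_term: str | None = None
    if study_size > 0:
        study_idx = rng.choice(n_genes, size=study_size, replace=False)
        study = [genes[i] for i in sorted(study_idx)]
        if enrichment_factor != 1.0 and n_terms > 0:
            enriched_term = terms[0]
            p = min(1.0, density * enrichment_factor)
            annotated[study_idx, 0] = rng.random(study_size) < p

    gi, ti = np.nonzero(annotated)
    table = pd.DataFrame(
        {"gene": [genes[i] for i in gi], "term": [terms[j] for j in ti]}
    )
    return table, genes, study, enriched_term


def simulate_qpcr(
    true_fold_change: float,
    ct_sd: float,
    n_replicates: int,
    seed: int,
    n_technical: int = 3,
    reference_condition: str = "reference",
    condition: str = "treated",
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for one target against a housekeeping gene.

    The treated condition carries a target shift of -log2(fold) cycles
    relative to the reference, i.e. ddCt quantification should recover
    ``true_fold_change``.  Gaussian noise of SD ``ct_sd`` is added per
    technical replicate.
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")
    if n_replicates < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(seed)
    hk_ct, ref_target_ct = 20.0, 25.0
    shift = -np.log2(true_fold_change)
    rows = []
    for bio in range(1, n_replicates + 1):
        for cond, target_ct in (
            (reference_condition, ref_target_ct),
            (condition, ref_target_ct + shift),
        ):
            for gene, base in (("target", target_ct), ("housekeeping", hk_ct)):
                for tech in range(1, n_technical + 1):
                    ct = base + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0)
                    rows.append((bio, cond, gene, tech, ct))
    return pd.DataFrame(
        rows,
        columns=[
            "biological_replicate",
            "condition",
            "gene",
            "technical_replicate",
            "ct",
        ],
    )
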