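"""End-to-end orchestration: simulate -> filter -> associate -> scan ->
enrich -> qpcr, with a manifest of parameters, seeds and output hashes.

Stages communicate through plain files in the output directory; the
manifest suffices to reproduce any output.  Deterministic stages are
byte-identical on rerun with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as ekio
from .cohort import associate
from .enrichment import enrich
from .motifs import calibrate_threshold, hits_to_bed, random_background, scan
from .qpcr import delta_delta_ct
from .simulate import (
    CohortDesign,
    PromoterSpec,
    TimeCourseDesign,
    simulate_cohort,
    simulate_go_annotations,
    simulate_promoters,
    simulate_pwm,
    simulate_qpcr,
    simulate_timecourse,
)
from .timecourse import run_filter

log = logging.getLogger("evi1kit")

STAGES = ("timecourse", "cohort", "motifs", "go", "qpcr")

_DEFAULTS: dict[str, dict] = {
    "timecourse": {"min_intensity": 3.0, "min_fold": 2.0},
    "cohort": {"n_iter": 10_000, "bandwidth": "silverman", "five_pct": 0.05},
    "motifs": {
        "pwm_length": 8,
        "pwm_dominance": 0.85,
        "background_bp": 100_000,
        "target_rate": 1.0 / 10_000.0,
        "gc_fraction": 0.5,
        "promoter_length": 268,
        "planted_position": 50,
        "planted_strand": "+",
    },
    "go": {
        "n_genes": 2000,
        "n_terms": 50,
        "density": 0.05,
        "study_size": 40,
        "enrichment_factor": 5.0,
    },
    "qpcr": {"true_fold_change": 16.0, "ct_sd": 0.1, "n_replicates": 4},
}


class RunConfig:
    """Validated pipeline configuration.

    Top-level keys: ``seed`` (int), ``stages`` (list of stage names to
    run), and one optional parameter block per stage.  Unknown keys are
    rejected.  ``timecourse`` and ``cohort`` blocks may additionally
    carry ``design`` sub-blocks with fields of the corresponding
    simulation design.
    """

    def __init__(self, raw: dict):
        allowed_top = {"seed", "stages", *STAGES}
        unknown = set(raw) - allowed_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.stages = list(raw.get("stages", STAGES))
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.params: dict[str, dict] = {}
        self.designs: dict[str, dict] = {}
        for stage in STAGES:
            block = dict(raw.get(stage, {}))
            self.designs[stage] = dict(block.pop("design", {}))
            allowed = set(_DEFAULTS[stage])
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in {stage!r} block: {sorted(unknown)}"
                )
            self.params[stage] = {**_DEFAULTS[stage], **block}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "stages": self.stages}
        for stage in STAGES:
            block = dict(self.params[stage])
            if self.designs[stage]:
                block["design"] = dict(self.designs[stage])
            out[stage] = block
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _design(cls, overrides: dict, seed: int):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - fields
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    return cls(**{"seed": seed, **overrides})


def run(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    if "timecourse" in config.stages:
        log.info("stage timecourse")
        p = config.params["timecourse"]
        design = _design(
            TimeCourseDesign, config.designs["timecourse"], config.seed
        )
        matrix, truth = simulate_timecourse(design)
        ekio.write_timecourse(
            matrix,
            out / "expression.tsv",
            out / "sample_metadata.tsv",
            out / "probe_gene_map.tsv",
        )
        truth.to_csv(out / "timecourse_truth.tsv", sep="\t", index=False)
        genes, calls = run_filter(
            matrix, min_intensity=p["min_intensity"], min_fold=p["min_fold"]
        )
        calls.to_csv(out / "regulated_calls.tsv", sep="\t", index=False)
        (out / "heatmap_order.txt").write_text("\n".join(genes) + "\n")
        for n in (
            "expression.tsv",
            "sample_metadata.tsv",
            "probe_gene_map.tsv",
            "timecourse_truth.tsv",
            "regulated_calls.tsv",
            "heatmap_order.txt",
        ):
            emit(n, out / n)

    if "cohort" in config.stages:
        log.info("stage cohort")
        p = config.params["cohort"]
        design = _design(CohortDesign, config.designs["cohort"], config.seed + 1)
        cohort, _labels = simulate_cohort(design)
        cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
        cut, boot = associate(
            cohort,
            n_iter=p["n_iter"],
            seed=config.seed + 2,
            bandwidth=p["bandwidth"],
            five_pct=p["five_pct"],
        )
        row = {
            "dataset": "synthetic",
            "cutoff": None if cut.cutoff is None else round(cut.cutoff, 2),
            "rule": cut.rule_applied,
        }
        if boot is not None:
            row.update(
                n_high=boot.n_high,
                n_low=boot.n_low,
                pct_high=boot.pct_high,
                M=round(boot.M, 2),
                SD=round(boot.SD, 2),
                Z=round(boot.Z, 2),
                p_value=float(f"{boot.p_two_sided:.1e}"),
            )
        pd.DataFrame([row]).to_csv(
            out / "cohort_association.tsv", sep="\t", index=False
        )
        emit("cohort.tsv", out / "cohort.tsv")
        emit("cohort_association.tsv", out / "cohort_association.tsv")

    if "motifs" in config.stages:
        log.info("stage motifs")
        p = config.params["motifs"]
        pwm = simulate_pwm(
            length=p["pwm_length"],
            dominance=p["pwm_dominance"],
            seed=config.seed + 3,
            pwm_id="synthetic_pwm",
        )
        spec = PromoterSpec(
            length=p["promoter_length"],
            gc_fraction=p["gc_fraction"],
            planted_motifs=(
                ("synthetic_pwm", p["planted_position"], p["planted_strand"]),
            ),
            seed=config.seed + 4,
        )
        records, motif_truth = simulate_promoters(spec, {"synthetic_pwm": pwm})
        ekio.write_fasta(records, out / "promoters.fasta")
        motif_truth.to_csv(out / "motif_truth.tsv", sep="\t", index=False)
        background = random_background(
            p["background_bp"], p["gc_fraction"], seed=config.seed + 5
        )
        threshold, achieved = calibrate_threshold(
            pwm, background, target_rate=p["target_rate"]
        )
        hits = []
        for seq_id, seq in records:
            hits.extend(scan(seq, pwm, threshold, sequence_id=seq_id))
        bed = hits_to_bed(hits, {pwm.id: pwm.length})
        bed.to_csv(out / "motif_hits.bed", sep="\t", index=False, header=False)
        pd.DataFrame(
            [
                {
                    "sequence_id": h.sequence_id,
                    "start": h.start,
                    "strand": h.strand,
                    "score": h.score,
                    "pwm_id": h.pwm_id,
                    "threshold": threshold,
                    "rate_achieved": achieved,
                }
                for h in hits
            ]
        ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        for n in ("promoters.fasta", "motif_truth.tsv", "motif_hits.bed", "motif_hits.tsv"):
            emit(n, out / n)

    if "go" in config.stages:
        log.info("stage go")
        p = config.params["go"]
        annotations, population, study, _term = simulate_go_annotations(
            p["n_genes"],
            p["n_terms"],
            p["density"],
            seed=config.seed + 6,
            study_size=p["study_size"],
            enrichment_factor=p["enrichment_factor"],
        )
        annotations.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
        table = enrich(study, annotations, population)
        table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        emit("go_annotations.tsv", out / "go_annotations.tsv")
        emit("go_enrichment.tsv", out / "go_enrichment.tsv")

    if "qpcr" in config.stages:
        log.info("stage qpcr")
        p = config.params["qpcr"]
        ct = simulate_qpcr(
            p["true_fold_change"],
            p["ct_sd"],
            p["n_replicates"],
            seed=config.seed + 7,
        )
        ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        folds = delta_delta_ct(ct, reference_condition="reference")
        folds.to_csv(out / "qpcr_fold_changes.tsv", sep="\t", index=False)
        emit("ct_table.tsv", out / "ct_table.tsv")
        emit("qpcr_fold_changes.tsv", out / "qpcr_fold_changes.tsv")

    manifest = {
        "config": config.to_dict(),
        "outputs": {
            name: {"path": rel, "sha256": _sha256(out / rel)}
            for name, rel in outputs.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
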