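"""Plain-text readers and writers for the pipeline's file formats.

Expression matrices and metadata travel as TSV, promoters as FASTA
(via Biopython), PWMs as JASPAR-style plain-text matrices, annotations
as two-column TSV, motif hits as BED6 + a TSV with exact scores.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM
from .timecourse import TimeCourseMatrix


def write_timecourse(
    matrix: TimeCourseMatrix, matrix_path, meta_path, gene_map_path
) -> None:
    matrix.values.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    matrix.metadata.to_csv(meta_path, sep="\t", index=False)
    matrix.probe_to_gene.rename_axis("probe_id").to_csv(gene_map_path, sep="\t")


def read_timecourse(matrix_path, meta_path, gene_map_path) -> TimeCourseMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    meta = pd.read_csv(meta_path, sep="\t")
    gene_map = pd.read_csv(gene_map_path, sep="\t", index_col="probe_id")["gene"]
    return TimeCourseMatrix(values=values, metadata=meta, probe_to_gene=gene_map)


def read_cohort(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "evi1_log2", "ms4a3_log2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return table


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def parse_jaspar(text: str, pwm_id: str | None = None) -> PWM:
    """Parse one JASPAR-style matrix.

    Accepts the bracketed 4-line form::

        >MA0001.1 NAME
        A  [ 4 19  0 ]
        C  [16  0 20 ]
        G  [ 0  1  0 ]
        T  [ 0  0  0 ]

    or plain 4 whitespace-separated rows in A/C/G/T order.  Counts are
    normalized per column; frequency matrices pass through unchanged.
    """
    rows: dict[str, list[float]] = {}
    header = None
    for line in text.strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:].split()[0]
            continue
        cleaned = line.replace("[", " ").replace("]", " ")
        parts = cleaned.split()
        if parts[0].upper() in "ACGT" and len(parts[0]) == 1:
            base, nums = parts[0].upper(), parts[1:]
        else:
            base = "ACGT"[len(rows)]
            nums = parts
        rows[base] = [float(x) for x in nums]
    if set(rows) != set("ACGT"):
        raise ValueError(f"matrix rows found for {sorted(rows)}, need A,C,G,T")
    counts = np.array([rows[b] for b in "ACGT"]).T  # (L, 4)
    return PWM.from_counts(pwm_id or header or "pwm", counts)


def read_pwm_file(path) -> list[PWM]:
    """Read one file holding one or more JASPAR-style matrices."""
    text = Path(path).read_text()
    blocks: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">") and current:
            blocks.append("\n".join(current))
            current = []
        current.append(line)
    if current:
        blocks.append("\n".join(current))
    return [parse_jaspar(b) for b in blocks if b.strip()]


def read_pwm_dir(path) -> dict[str, PWM]:
    pwms: dict[str, PWM] = {}
    for f in sorted(Path(path).glob("*")):
        if f.is_file():
            for pwm in read_pwm_file(f):
                pwms[pwm.id] = pwm
    if not pwms:
        raise ValueError(f"no PWM files found under {path}")
    return pwms


def read_annotations(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(table.columns):
        # headerless two-column form
        table = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    return table[["gene", "term"]]


def read_gene_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
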