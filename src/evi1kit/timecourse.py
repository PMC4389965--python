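"""Calling regulated genes from a tet-off induction time course.

The experimental layout: two inducible clones (E10, E14) sampled at 6,
12, 24 and 48 h with and without tetracycline, plus two control lines
(P2, U937T) sampled at 48 h.  Because tet withdrawal itself perturbs
expression in control cells, a probe set is called regulated only when

* its mean log2 intensity is >= ``min_intensity`` in each of the six
  conditions E10/E14 @ 24 h & 48 h and P2/U937T @ 48 h (averaged over
  the +/- tet pair),
* |log2 FC| >= log2(min_fold) at 24 h AND 48 h in BOTH clones with a
  single consistent sign, and
* per clone, the 48 h effect exceeds the background:
  |log2 FC(clone, 48 h)| >= base^(|log2 FC(clone, 48 h)|/divisor) *
  max over control lines of |log2 FC(control, 48 h)|,
  with base=10 and divisor=3 by default.

When several probe sets map to one gene, the one with the most
pronounced regulation (largest mean |48 h log2 FC| over clones) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLONES = ("E10", "E14")
CONTROLS = ("P2", "U937T")
FILTER_CONDITIONS = (
    ("E10", 24),
    ("E10", 48),
    ("E14", 24),
    ("E14", 48),
    ("P2", 48),
    ("U937T", 48),
)


class ConfigurationError(ValueError):
    """Raised when the matrix lacks a column the filter requires."""


@dataclass(frozen=True)
class TimeCourseMatrix:
    """Probe x sample log2 intensities with sample metadata.

    ``values``: DataFrame, probe ids as index, sample ids as columns.
    ``metadata``: DataFrame with columns sample_id, cell_line,
    tet ('plus'/'minus'), hours.
    ``probe_to_gene``: Series mapping probe id -> gene symbol; probes
    absent from the map count as unannotated and are dropped by the
    intensity filter.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    probe_to_gene: pd.Series

    def __post_init__(self):
        missing = set(self.metadata.sample_id) - set(self.values.columns)
        if missing:
            raise ConfigurationError(
                f"metadata names samples absent from the matrix: {sorted(missing)}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    def sample_for(self, cell_line: str, tet: str, hours: int) -> str:
        m = self.metadata
        hit = m[
            (m.cell_line == cell_line) & (m.tet == tet) & (m.hours == hours)
        ]
        if len(hit) != 1:
            raise ConfigurationError(
                f"need exactly one sample for ({cell_line}, {tet}, {hours} h), "
                f"found {len(hit)}"
            )
        return hit.sample_id.iloc[0]


@dataclass(frozen=True)
class RegulationCall:
    """One regulated probe set: per-condition fold changes and flags."""

    gene: str
    probe_id: str
    log2fc: dict  # (clone, hours) -> float
    control_log2fc: dict  # control line -> float at 48 h
    direction: str  # 'up' or 'down'
    passes_intensity: bool = True
    passes_fc: bool = True
    passes_background: bool = True

    def mean_fc48(self) -> float:
        return float(np.mean([self.log2fc[(c, 48)] for c in CLONES]))


def filter_probesets(matrix: TimeCourseMatrix, min_intensity: float = 3.0) -> list[str]:
    """Retain probes whose mean +/- tet log2 intensity is >= threshold
    in every required (line, time) condition, and which carry a gene
    annotation."""
    keep = pd.Series(True, index=matrix.values.index)
    for line, hours in FILTER_CONDITIONS:
        plus = matrix.sample_for(line, "plus", hours)
        minus = matrix.sample_for(line, "minus", hours)
        mean = (matrix.values[plus] + matrix.values[minus]) / 2.0
        keep &= mean >= min_intensity
    annotated = matrix.values.index.isin(matrix.probe_to_gene.dropna().index)
    keep &= pd.Series(annotated, index=matrix.values.index)
    return list(matrix.values.index[keep])


def compute_fold_changes(
    matrix: TimeCourseMatrix, probes: list[str] | None = None
) -> pd.DataFrame:
    """Per-probe log2 fold change (-tet minus +tet) for each
    (cell line, hours) pair present in the metadata.

    Returns a DataFrame indexed by probe with MultiIndex columns
    (cell_line, hours).
    """
    meta = matrix.metadata
    pairs = sorted(
        {(r.cell_line, int(r.hours)) for r in meta.itertuples()},
        key=lambda p: (p[0], p[1]),
    )
    values = matrix.values if probes is None else matrix.values.loc[probes]
    cols = {}
    for line, hours in pairs:
        plus = matrix.sample_for(line, "plus", hours)
        minus = matrix.sample_for(line, "minus", hours)
        cols[(line, hours)] = values[minus] - values[plus]
    fc = pd.DataFrame(cols)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["cell_line", "hours"])
    return fc


def call_regulated(
    fcs: pd.DataFrame,
    probe_to_gene: pd.Series,
    min_fold: float = 2.0,
    exceedance_base: float = 10.0,
    exceedance_divisor: float = 3.0,
) -> list[RegulationCall]:
    """Apply the two-fold + background-exceedance criterion.

    ``fcs`` is the output of :func:`compute_fold_changes` and must cover
    E10/E14 at 24 h and 48 h and P2/U937T at 48 h.
    """
    for col in [(c, h) for c in CLONES for h in (24, 48)] + [
        (c, 48) for c in CONTROLS
    ]:
        if col not in fcs.columns:
            raise ConfigurationError(f"fold changes missing condition {col}")

    min_log2 = np.log2(min_fold)
    calls = []
    for probe in fcs.index:
        clone_fc = {
            (c, h): float(fcs.loc[probe, (c, h)]) for c in CLONES for h in (24, 48)
        }
        vals = np.array(list(clone_fc.values()))
        if not (np.abs(vals) >= min_log2).all():
            continue
        signs = np.sign(vals)
        if not (signs == signs[0]).all():
            continue
        ctrl_fc = {c: float(fcs.loc[probe, (c, 48)]) for c in CONTROLS}
        max_ctrl = max(abs(v) for v in ctrl_fc.values())
        ok = True
        for c in CLONES:
            eff = abs(clone_fc[(c, 48)])
            if eff < exceedance_base ** (eff / exceedance_divisor) * max_ctrl:
                ok = False
                break
        if not ok:
            continue
        calls.append(
            RegulationCall(
                gene=str(probe_to_gene.get(probe, probe)),
                probe_id=str(probe),
                log2fc=clone_fc,
                control_log2fc=ctrl_fc,
                direction="up" if signs[0] > 0 else "down",
            )
        )
    return calls


def collapse_probesets(calls: list[RegulationCall]) -> list[RegulationCall]:
    """Keep, per gene, the probe set with the most pronounced regulation
    (largest mean |log2 FC| at 48 h over clones); ties break on the
    lexicographically smallest probe id."""
    best: dict[str, RegulationCall] = {}
    for call in sorted(calls, key=lambda c: c.probe_id):
        strength = abs(call.mean_fc48())
        cur = best.get(call.gene)
        if cur is None or strength > abs(cur.mean_fc48()):
            best[call.gene] = call
    return [best[g] for g in sorted(best)]


def order_for_heatmap(
    calls: list[RegulationCall],
) -> tuple[list[str], pd.DataFrame]:
    """Genes in descending mean 48 h log2 FC plus the per-time-point FC
    table ready for export/plotting."""
    ordered = sorted(calls, key=lambda c: (-c.mean_fc48(), c.gene))
    genes = [c.gene for c in ordered]
    rows = []
    for c in ordered:
        row = {"gene": c.gene, "probe_id": c.probe_id, "direction": c.direction}
        for (line, h), v in sorted(c.log2fc.items()):
            row[f"log2fc_{line}_{h}h"] = v
        for line, v in sorted(c.control_log2fc.items()):
            row[f"log2fc_{line}_48h"] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    return genes, table


def run_filter(
    matrix: TimeCourseMatrix,
    min_intensity: float = 3.0,
    min_fold: float = 2.0,
    exceedance_base: float = 10.0,
    exceedance_divisor: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Full chain: intensity filter -> fold changes -> regulation calls
    -> per-gene collapse -> heatmap ordering."""
    probes = filter_probesets(matrix, min_intensity)
    fcs = compute_fold_changes(matrix, probes)
    calls = call_regulated(
        fcs,
        matrix.probe_to_gene,
        min_fold=min_fold,
        exceedance_base=exceedance_base,
        exceedance_divisor=exceedance_divisor,
    )
    collapsed = collapse_probesets(calls)
    return order_for_heatmap(collapsed)
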