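import numpy as np
import pandas as pd
import pytest

from evi1kit import PWM, TimeCourseMatrix


def build_matrix(per_condition: dict, probe_to_gene: dict | None = None):
    """Assemble a TimeCourseMatrix from {probe: {(line, tet, hours): value}}.

    Missing (line, tet, hours) combinations default to 10.0 so the
    intensity filter passes unless a test says otherwise.
    """
    layout = [
        (line, tet, h)
        for line in ("E10", "E14")
        for tet in ("plus", "minus")
        for h in (6, 12, 24, 48)
    ] + [(line, tet, 48) for line in ("P2", "U937T") for tet in ("plus", "minus")]
    meta = pd.DataFrame(
        [(f"{l}_{t}_{h}h", l, t, h) for l, t, h in layout],
        columns=["sample_id", "cell_line", "tet", "hours"],
    )
    probes = list(per_condition)
    values = pd.DataFrame(10.0, index=probes, columns=meta.sample_id)
    for probe, conds in per_condition.items():
        for (line, tet, hours), v in conds.items():
            values.loc[probe, f"{line}_{tet}_{hours}h"] = v
    if probe_to_gene is None:
        probe_to_gene = {p: f"gene_of_{p}" for p in probes}
    return TimeCourseMatrix(
        values=values,
        metadata=meta,
        probe_to_gene=pd.Series(probe_to_gene, name="gene"),
    )


def clone_effect(fc24: float, fc48: float, ctrl: tuple[float, float] = (0.0, 0.0)):
    """Condition dict for one probe: a clean planted effect on a flat
    baseline of 10, expressed as -tet minus +tet log2 fold changes."""
    conds = {}
    for line in ("E10", "E14"):
        conds[(line, "minus", 24)] = 10.0 + fc24
        conds[(line, "minus", 48)] = 10.0 + fc48
    conds[("P2", "minus", 48)] = 10.0 + ctrl[0]
    conds[("U937T", "minus", 48)] = 10.0 + ctrl[1]
    return conds


@pytest.fixture
def three_column_pwm():
    """The hand-checkable PWM [A:1 | A:0.5,C:0.5 | G:1]."""
    return PWM(
        "toy",
        np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
            ]
        ),
    )
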