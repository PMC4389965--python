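"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain nested loops over labelled values,
deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

CLONES = ("E10", "E14")
CONTROLS = ("P2", "U937T")


def _value(matrix, probe, line, tet, hours):
    meta = matrix.metadata
    row = meta[(meta.cell_line == line) & (meta.tet == tet) & (meta.hours == hours)]
    assert len(row) == 1
    return float(matrix.values.loc[probe, row.sample_id.iloc[0]])


def brute_force_regulated(
    matrix,
    min_intensity=3.0,
    min_fold=2.0,
    base=10.0,
    divisor=3.0,
):
    """Quadruple-loop reference for the full regulated-gene filter.

    Returns {gene: (probe_id, mean_fc48)} after per-gene collapse.
    """
    passing = {}
    for probe in matrix.values.index:
        if probe not in matrix.probe_to_gene.index:
            continue
        gene = matrix.probe_to_gene.loc[probe]
        if gene is None or (isinstance(gene, float) and math.isnan(gene)):
            continue

        ok = True
        for line, hours in [
            ("E10", 24), ("E10", 48), ("E14", 24), ("E14", 48),
            ("P2", 48), ("U937T", 48),
        ]:
            mean = (
                _value(matrix, probe, line, "plus", hours)
                + _value(matrix, probe, line, "minus", hours)
            ) / 2.0
            if mean < min_intensity:
                ok = False
        if not ok:
            continue

        fcs = {}
        for line in CLONES:
            for hours in (24, 48):
                fcs[(line, hours)] = _value(
                    matrix, probe, line, "minus", hours
                ) - _value(matrix, probe, line, "plus", hours)
        ctrl = {
            line: _value(matrix, probe, line, "minus", 48)
            - _value(matrix, probe, line, "plus", 48)
            for line in CONTROLS
        }

        if any(abs(v) < math.log2(min_fold) for v in fcs.values()):
            continue
        signs = {math.copysign(1, v) for v in fcs.values()}
        if len(signs) != 1:
            continue
        max_ctrl = max(abs(v) for v in ctrl.values())
        exceeds = True
        for line in CLONES:
            eff = abs(fcs[(line, 48)])
            if eff < base ** (eff / divisor) * max_ctrl:
                exceeds = False
        if not exceeds:
            continue

        mean48 = (fcs[("E10", 48)] + fcs[("E14", 48)]) / 2.0
        strength = abs(mean48)
        prev = passing.get(gene)
        if prev is None or strength > prev[2] or (
            strength == prev[2] and probe < prev[0]
        ):
            passing[gene] = (probe, mean48, strength)
    return {g: (p, m) for g, (p, m, _s) in passing.items()}


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(n, K) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def brute_force_window_scores(pwm, seq: str):
    """Per-window similarity on both strands, plain Python loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    weights = []
    for col in pwm.frequencies:
        s = sum(f * math.log(f) for f in col if f > 0)
        weights.append(100.0 / math.log(4.0) * s + 100.0)
    denom = sum(w * max(col) for w, col in zip(weights, pwm.frequencies))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score(window):
        num = 0.0
        for l, b in enumerate(window):
            if b in idx:
                num += weights[l] * pwm.frequencies[l][idx[b]]
        return min(num / denom, 1.0)

    L = pwm.length
    fwd, rev = [], []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        fwd.append(score(w))
        rc = "".join(comp[b] for b in reversed(w))
        rev.append(score(rc))
    return np.array(fwd), np.array(rev)
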