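"""Relative qPCR quantification with the ddCt method.

Technical replicates are averaged on the Ct scale, dCt = mean Ct(target)
- mean Ct(housekeeping) per biological replicate and condition, ddCt is
taken against the reference condition, and fold change = 2^(-ddCt)
(amplification efficiency fixed at 2).  Fold changes are summarized as
mean and SEM across biological replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "biological_replicate",
    "condition",
    "gene",
    "technical_replicate",
    "ct",
)


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """dCt per (biological replicate, condition).

    Expects genes labelled 'target' and 'housekeeping'; technical
    replicates are averaged on the Ct scale first.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    mean_ct = (
        table.groupby(["biological_replicate", "condition", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in ("target", "housekeeping"):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            raise ValueError(f"missing {gene} Ct values for some condition")
    out = (mean_ct["target"] - mean_ct["housekeeping"]).rename("dct")
    return out.reset_index()


def delta_delta_ct(
    table: pd.DataFrame, reference_condition: str
) -> pd.DataFrame:
    """Per-condition mean fold change and SEM over biological replicates.

    ddCt is computed within each biological replicate against that
    replicate's own reference-condition dCt (paired design).  Returns a
    frame (condition, n_replicates, mean_fold, sem_fold, sem_defined);
    the reference condition itself has fold 1 by construction.
    """
    dct = delta_ct(table)
    conditions = dct["condition"].unique()
    if reference_condition not in conditions:
        raise ValueError(
            f"reference condition {reference_condition!r} absent from table"
        )
    ref = dct[dct["condition"] == reference_condition].set_index(
        "biological_replicate"
    )["dct"]

    rows = []
    for cond, sub in dct.groupby("condition"):
        sub = sub.set_index("biological_replicate")
        common = sub.index.intersection(ref.index)
        if len(common) == 0:
            raise ValueError(
                f"no biological replicate shared between {cond!r} and the "
                "reference condition"
            )
        ddct = sub.loc[common, "dct"] - ref.loc[common]
        fold = np.power(2.0, -ddct.to_numpy())
        n = len(fold)
        sem_defined = n >= 2
        sem = float(fold.std(ddof=1) / np.sqrt(n)) if sem_defined else float("nan")
        rows.append((cond, n, float(fold.mean()), sem, sem_defined))
    return pd.DataFrame(
        rows,
        columns=["condition", "n_replicates", "mean_fold", "sem_fold", "sem_defined"],
    )
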