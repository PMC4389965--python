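"""Term-for-term GO enrichment.

Each term is tested independently: the overlap k between the study set
(n genes) and the term's annotated genes (K of N population genes) is
compared against the hypergeometric null with a one-sided Fisher exact
test, p = P(X >= k).  P-values are Benjamini–Hochberg adjusted and terms
with adjusted p < 0.1 are flagged significant.  No GO-graph propagation
is performed — inherited annotations are the input table's
responsibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_LEVEL = 0.1


def fisher_one_sided(k: int, n: int, K: int, N: int) -> float:
    """One-sided (enrichment) Fisher exact p-value.

    p = P(X >= k) for X ~ Hypergeometric(N population, K annotated,
    n drawn).
    """
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if n > N or K > N:
        raise ValueError("study or annotation count exceeds population")
    if k > min(n, K):
        raise ValueError("overlap k exceeds min(n, K)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study: list[str],
    annotations: pd.DataFrame,
    population: list[str],
    alpha: float = SIGNIFICANCE_LEVEL,
) -> pd.DataFrame:
    """Term-for-term enrichment of ``study`` within ``population``.

    ``annotations`` is a two-column frame (gene, term).  Returns one row
    per term annotated in the population, sorted by raw p-value, with
    columns term, k, n, K, N, p_raw, p_adj, significant.  An empty study
    set yields an empty table.
    """
    pop = set(population)
    study_set = set(study)
    if not study_set <= pop:
        raise ValueError("study set must be a subset of the population")
    if len(study_set) == 0:
        return pd.DataFrame(
            columns=["term", "k", "n", "K", "N", "p_raw", "p_adj", "significant"]
        )

    ann = annotations[annotations["gene"].isin(pop)]
    N, n = len(pop), len(study_set)
    rows = []
    for term, genes in ann.groupby("term")["gene"]:
        term_genes = set(genes)
        K = len(term_genes)
        k = len(term_genes & study_set)
        rows.append((term, k, n, K, N, fisher_one_sided(k, n, K, N)))
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_raw"])
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return (
        table.sort_values(["p_raw", "term"], kind="mergesort")
        .reset_index(drop=True)
    )
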