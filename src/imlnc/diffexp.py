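"""Differential expression of lncRNAs against the normal group.

Each immunophenotype (IH, IL) is compared to the normal samples separately.
The fold change is computed on log2(FPKM + 1); the Student's t-test is run on
per-lncRNA Z-scores of the log2 values (standardized over the union of the
two compared groups), and p-values are Benjamini-Hochberg adjusted within
each comparison.  A lncRNA is called significant when FDR < 0.01 and
|log2FC| > 2 (both thresholds configurable).  The two result sets are then
combined into the Constitutive / IH-specific / IL-specific categories.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

CATEGORIES = ("Constitutive", "IH-specific", "IL-specific", "none")


def diff_expr(
    matrix: ExpressionMatrix,
    group_ids: Sequence[str],
    normal_ids: Sequence[str],
    fdr_thresh: float = 0.01,
    lfc_thresh: float = 2.0,
    on_zscores: bool = True,
    equal_var: bool = True,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-lncRNA differential expression of ``group`` vs ``normal``.

    Returns a DataFrame indexed by lncRNA id with columns ``log2fc``, ``t``,
    ``p``, ``fdr``, ``significant`` and ``direction`` (up/down/ns).  With
    ``on_zscores`` (default) the t-test runs on row Z-scores of the log2
    values computed over the union of the compared samples; set it False to
    test the raw log2 scale.  ``equal_var=False`` switches to Welch's t.
    """
    group_ids = list(group_ids)
    normal_ids = list(normal_ids)
    if len(group_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("each compared group needs at least 2 samples")
    overlap = set(group_ids) & set(normal_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")

    lnc = matrix.subset_features(matrix.lncrna_ids)
    union = group_ids + normal_ids
    log2 = np.log2(lnc.values[union].to_numpy(dtype=float) + pseudocount)
    n_g = len(group_ids)
    log2fc = log2[:, :n_g].mean(axis=1) - log2[:, n_g:].mean(axis=1)

    if on_zscores:
        mean = log2.mean(axis=1, keepdims=True)
        sd = log2.std(axis=1, ddof=1, keepdims=True)
        constant = (sd == 0).ravel()
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant lncRNA row(s) over the compared "
                "samples; their t is set to 0",
                stacklevel=2,
            )
        sd[sd == 0] = 1.0
        test_mat = (log2 - mean) / sd
    else:
        test_mat = log2

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(
            test_mat[:, :n_g], test_mat[:, n_g:], axis=1, equal_var=equal_var
        )
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    significant = (fdr < fdr_thresh) & (np.abs(log2fc) > lfc_thresh)
    direction = np.where(~significant, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "significant": significant,
            "direction": direction,
        },
        index=lnc.feature_ids,
    )


def categorize(ih_results: pd.DataFrame, il_results: pd.DataFrame) -> pd.DataFrame:
    """Combine the two phenotype-vs-normal screens into category calls.

    Constitutive = significant in both comparisons, IH-/IL-specific =
    significant in exactly one, ``none`` otherwise.  Both inputs must cover
    the same lncRNA universe.
    """
    if set(ih_results.index) != set(il_results.index):
        raise ValueError("IH and IL results cover different lncRNA universes")
    il = il_results.reindex(ih_results.index)
    sig_ih = ih_results["significant"].to_numpy(dtype=bool)
    sig_il = il["significant"].to_numpy(dtype=bool)
    category = np.select(
        [sig_ih & sig_il, sig_ih & ~sig_il, ~sig_ih & sig_il],
        ["Constitutive", "IH-specific", "IL-specific"],
        default="none",
    )
    return pd.DataFrame(
        {
            "log2fc_ih": ih_results["log2fc"],
            "log2fc_il": il["log2fc"],
            "fdr_ih": ih_results["fdr"],
            "fdr_il": il["fdr"],
            "direction_ih": ih_results["direction"],
            "direction_il": il["direction"],
            "category": category,
        },
        index=ih_results.index,
    )
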