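"""Expression filtering and scale transforms.

Three small operations applied before any modeling: drop features that are
not expressed (FPKM > 0) in at least a fraction of samples, move FPKM to
log2(FPKM + pseudocount), and standardize each feature row to a Z-score.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ZScoreMatrix


def filter_expressed(
    matrix: ExpressionMatrix, min_expr_frac: float = 0.7
) -> ExpressionMatrix:
    """Keep features with FPKM > 0 in at least ``min_expr_frac`` of all samples.

    The boundary is inclusive: a feature expressed in exactly the threshold
    fraction of samples is retained.  Feature order is preserved.  Idempotent.
    """
    if not (0.0 <= min_expr_frac <= 1.0):
        raise ValueError(f"min_expr_frac must lie in [0, 1], got {min_expr_frac!r}")
    expressed_frac = (matrix.values.to_numpy() > 0).mean(axis=1)
    keep = expressed_frac >= min_expr_frac
    if not keep.any():
        raise ValueError(
            f"no feature is expressed in >= {min_expr_frac:.0%} of samples; "
            "relax min_expr_frac"
        )
    kept_ids = matrix.feature_ids[keep]
    return matrix.subset_features(kept_ids)


def log2_transform(
    matrix: Union[ExpressionMatrix, pd.DataFrame], pseudocount: float = 1.0
) -> pd.DataFrame:
    """Elementwise log2(x + pseudocount); monotone in x."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount!r}")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_transform requires nonnegative input")
    if pseudocount == 0 and (arr == 0).any():
        raise ValueError("pseudocount 0 with zero entries would produce -inf")
    return pd.DataFrame(np.log2(arr + pseudocount), index=values.index, columns=values.columns)


def zscore_rows(values: pd.DataFrame, ddof: int = 1) -> ZScoreMatrix:
    """Standardize each row to mean 0, sd 1 (sample sd with ``ddof=1`` by default).

    Constant rows have no scale and are rejected with the offending feature
    ids in the error message; exclude them (or relax the expression filter)
    before standardizing.
    """
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        bad = values.index[constant][:10].tolist()
        raise ValueError(f"constant rows cannot be z-scored: {bad}")
    z = (arr - mean) / sd
    return ZScoreMatrix(
        values=pd.DataFrame(z, index=values.index, columns=values.columns),
        provenance={"transform": "zscore_rows", "ddof": ddof, "n_samples": values.shape[1]},
    )
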