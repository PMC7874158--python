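"""Associations between signature lncRNAs and immune-cell infiltration.

Infiltration estimates (e.g. TIMER output, consumed as a samples x cell-types
table) are dichotomized at the per-cell-type median; each predictor (a
signature lncRNA's Z-scored expression, or the im-lncScore) is then tested
against each binary infiltration outcome with univariate logistic
regression.  Odds ratios are per standard deviation of the predictor by
default, with Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm


@dataclass
class AssociationResult:
    predictor_id: str
    cell_type: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False

    def __post_init__(self) -> None:
        if not self.separation and not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio must lie inside its confidence interval")


def dichotomize_infiltration(infiltration: pd.DataFrame) -> pd.DataFrame:
    """Per cell type: high (1) iff the value exceeds the column median.

    Values equal to the median are assigned low — the median sample itself is
    a low-infiltration sample.  Shift-invariant by construction.
    """
    if infiltration.shape[0] < 3:
        raise ValueError("need at least 3 samples per cell type")
    arr = infiltration.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        bad = infiltration.columns[constant].tolist()
        raise ValueError(f"constant infiltration column(s): {bad}")
    med = np.median(arr, axis=0)
    return pd.DataFrame(
        (arr > med).astype(int), index=infiltration.index, columns=infiltration.columns
    )


def univariate_logit(
    predictor: pd.Series | np.ndarray,
    outcome: pd.Series | np.ndarray,
    standardize: bool = True,
    predictor_id: str = "predictor",
    cell_type: str = "outcome",
) -> AssociationResult:
    """Maximum-likelihood fit of logit P(high) = b0 + b1 * x.

    With ``standardize`` (default) x is scaled to unit SD so the odds ratio
    exp(b1) is per one SD of the predictor.  Perfect separation yields a
    flagged sentinel result (infinite or zero OR, NaN CI/p) with a warning
    rather than an exception.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    if x.std(ddof=0) == 0:
        raise ValueError("predictor is constant")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=0)

    X = sm.add_constant(x)
    sentinel = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-10, maxiter=100)
        beta = fit.params[1]
        se = fit.bse[1]
        if not np.isfinite(se) or abs(beta) > 30:
            sentinel = np.sign(beta)
    except Exception:  # PerfectSeparationError or singular Hessian
        direction = np.sign(np.corrcoef(x, y)[0, 1])
        sentinel = direction if direction != 0 else 1.0

    if sentinel is not None:
        warnings.warn(
            f"perfect separation for {predictor_id!r} vs {cell_type!r}; "
            "odds ratio reported as a sentinel",
            stacklevel=2,
        )
        return AssociationResult(
            predictor_id=predictor_id,
            cell_type=cell_type,
            odds_ratio=float("inf") if sentinel > 0 else 0.0,
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            separation=True,
        )

    z = norm.ppf(0.975)
    wald_p = 2 * norm.sf(abs(beta / se))
    return AssociationResult(
        predictor_id=predictor_id,
        cell_type=cell_type,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(wald_p),
    )


def associate_all(
    predictors: pd.DataFrame,
    infiltration: pd.DataFrame,
    standardize: bool = True,
) -> pd.DataFrame:
    """Every predictor row against every dichotomized infiltration column.

    ``predictors``: predictors in rows, samples in columns.  ``infiltration``:
    raw levels, samples in rows.  Returns a tidy forest-plot-ready table.
    """
    common = predictors.columns.intersection(infiltration.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between predictors and infiltration")
    binary = dichotomize_infiltration(infiltration.loc[common])
    rows = []
    for pid in predictors.index:
        x = predictors.loc[pid, common]
        for ct in binary.columns:
            res = univariate_logit(
                x, binary[ct], standardize=standardize, predictor_id=pid, cell_type=ct
            )
            rows.append(
                {
                    "predictor": res.predictor_id,
                    "cell_type": res.cell_type,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "separation": res.separation,
                }
            )
    return pd.DataFrame(rows)
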