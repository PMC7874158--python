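"""The im-lncScore and its discrimination performance.

The signature's per-sample score is the first principal component of the
Z-scored signature expression (samples as observations, no re-centering
beyond the Z-scores).  Because a principal axis has an arbitrary sign, the
score is oriented to correlate positively with the mean Z-score across the
signature features, or with the Immune-High class when labels are supplied.
Discrimination is summarized by the Mann-Whitney (rank) AUC with a bootstrap
confidence interval and the Youden-optimal cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .matrix import ZScoreMatrix


@dataclass
class ImLncScore:
    score: pd.Series  # per-sample PC1 score
    loadings: pd.Series  # per-signature-feature PC1 loading
    variance_explained: float
    orientation: str  # "labels" or "mean-z"


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    score_median: float


def compute_imlncscore(
    z: ZScoreMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
    positive_label: str = "IH",
) -> ImLncScore:
    """PC1 of the z-scored signature submatrix, sign-oriented.

    ``z`` holds signature features in rows and samples in columns.  The PCA
    runs on the matrix as-is (samples as observations); orientation flips the
    component so that the score correlates positively with the per-sample
    mean Z across signature features, or — when ``labels`` are given — so
    that the mean score of ``positive_label`` samples is the larger one.
    """
    values = z.values if isinstance(z, ZScoreMatrix) else z
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a principal component")
    X = values.to_numpy(dtype=float).T  # samples x features
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] == 0:
        raise ValueError("degenerate input: all samples identical")
    pc1 = Vt[0]
    score = X @ pc1
    var_explained = float(S[0] ** 2 / (S**2).sum())

    flip = False
    orientation = "mean-z"
    if labels is not None:
        labels = labels.reindex(values.columns)
        pos = labels == positive_label
        neg = labels.notna() & ~pos
        if pos.any() and neg.any():
            orientation = "labels"
            flip = score[pos.to_numpy()].mean() < score[neg.to_numpy()].mean()
    if orientation == "mean-z":
        mean_z = X.mean(axis=1)
        flip = float(np.dot(score - score.mean(), mean_z - mean_z.mean())) < 0
    if flip:
        score = -score
        pc1 = -pc1
    return ImLncScore(
        score=pd.Series(score, index=values.columns, name="im_lncScore"),
        loadings=pd.Series(pc1, index=values.index, name="loading"),
        variance_explained=var_explained,
        orientation=orientation,
    )


def roc_auc(
    scores: pd.Series | np.ndarray,
    binary_labels,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Rank-formulation AUC with tie correction, ROC points and bootstrap CI.

    Labels are truthy for the positive class.  The CI is a stratified
    percentile bootstrap (resampling within each class), seeded.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = _rank_auc(s, y)
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), s)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        sb = np.concatenate([s[pi], s[ni]])
        yb = np.concatenate([np.ones(len(pi), bool), np.zeros(len(ni), bool)])
        boots[b] = _rank_auc(sb, yb)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        score_median=float(np.median(s)),
    )


def _rank_auc(s: np.ndarray, y: np.ndarray) -> float:
    r = rankdata(s)  # average ranks handle ties
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def optimal_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J break toward the threshold closest to the score median.  The
    returned value is a score threshold: predict positive when
    score >= cutoff.  If even the best J is <= 0 the score is
    anti-informative at every cutoff and a warning is raised.
    """
    j = roc.tpr - roc.fpr
    finite = np.isfinite(roc.thresholds)
    j_f = j[finite]
    th_f = roc.thresholds[finite]
    if len(th_f) == 0:
        raise ValueError("degenerate ROC: no finite thresholds")
    best = j_f.max()
    tied = np.flatnonzero(j_f >= best - 1e-12)
    pick = tied[np.argmin(np.abs(th_f[tied] - roc.score_median))]
    if best <= 0:
        warnings.warn(
            f"maximal Youden J is {best:.3f} <= 0; the score is anti-informative",
            stacklevel=2,
        )
    return float(th_f[pick])
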