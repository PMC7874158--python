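"""Signature discovery: repeated-CV mRMR + random forest with distance consensus.

The framework that produces the minimal immunophenotype-related lncRNA
signature:

1. Repeated stratified k-fold cross-validation (default 3 folds, 1000
   repeats) over the tumor samples.
2. On each training split, greedy mRMR feature selection (mutual information
   on 3-bin discretized Z-scores, MID criterion) screens the candidate
   lncRNAs down to the top 5%; a random forest (500 trees, sqrt(p) features
   per split) fit on the screened set ranks them by mean decrease in Gini
   impurity.
3. For every size on a grid, a forest trained on the top-ranked features is
   scored on the held-out fold with the balanced error rate (BER).  Each run
   is mirrored by a negative control in which the class labels are permuted.
4. The final signature size is the smallest one beyond which the mean BER no
   longer improves; every (repeat, fold) then contributes one candidate
   signature of that size, its features ordered by descending Gini
   importance.
5. Candidates are compared with a Spearman signature distance
   ``D = 1 - mean_i Rho(F1_i, F2_i)`` over importance-sorted feature pairs;
   the candidate with the smallest summed distance to all others is the
   representative signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .matrix import ZScoreMatrix


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SignatureCandidate:
    """One CV output signature: features ordered by descending Gini importance."""

    feature_ids: tuple[str, ...]
    importances: tuple[float, ...]
    test_ber: float
    repeat_idx: int
    fold_idx: int

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.importances):
            raise ValueError("feature_ids and importances lengths differ")
        imps = np.asarray(self.importances)
        if len(imps) > 1 and (np.diff(imps) > 1e-12).any():
            raise ValueError("importances must be sorted descending")

    @property
    def size(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the CV framework; defaults: 1000 repeats of 3-fold CV."""

    n_folds: int = 3
    n_repeats: int = 1000
    top_frac: float = 0.05
    size_grid: tuple[int, ...] = tuple(range(1, 16))
    ber_tolerance: float = 0.01
    n_negative_controls: int = 1
    rf_trees: int = 500
    mi_bins: int = 3
    mrmr_criterion: str = "MID"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 < self.top_frac <= 1.0):
            raise ValueError("top_frac must lie in (0, 1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.size_grid:
            raise ValueError("size_grid must be non-empty")
        if list(self.size_grid) != sorted(set(self.size_grid)):
            raise ValueError("size_grid must be strictly ascending")
        if self.ber_tolerance < 0:
            raise ValueError("ber_tolerance must be nonnegative")
        if self.mrmr_criterion not in ("MID", "MIQ"):
            raise ValueError("mrmr_criterion must be 'MID' or 'MIQ'")


@dataclass
class DistanceResult:
    """Pairwise signature distances and the representative pick."""

    distances: np.ndarray  # candidates x candidates, symmetric, zero diagonal
    summed: np.ndarray  # per-candidate row sums
    representative_idx: int


@dataclass
class CVResult:
    """Everything the repeated-CV framework emits."""

    candidates: list[SignatureCandidate]
    selected_size: int
    ber_by_size: pd.DataFrame  # columns: size, mean_ber, sd_ber, n
    control_ber_by_size: pd.DataFrame
    control_bers: np.ndarray = field(default_factory=lambda: np.empty(0))  # at selected size


# ---------------------------------------------------------------------------
# mutual information / mRMR
# ---------------------------------------------------------------------------


def discretize_features(X: np.ndarray, bins: int = 3) -> np.ndarray:
    """Discretize each column; 3 bins split at mean +/- sd, otherwise quantiles.

    ``X`` is samples x features; returns integer codes of the same shape.
    """
    X = np.asarray(X, dtype=float)
    codes = np.zeros(X.shape, dtype=np.int64)
    if bins == 3:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        codes += (X > (mu - sd)).astype(np.int64)
        codes += (X > (mu + sd)).astype(np.int64)
    else:
        qs = np.quantile(X, np.linspace(0, 1, bins + 1)[1:-1], axis=0)
        for q in qs:
            codes += (X > q).astype(np.int64)
    return codes


def mutual_information(a: np.ndarray, b: np.ndarray, n_levels_a: int, n_levels_b: int) -> float:
    """MI (nats) of two integer-coded vectors via their contingency table."""
    n = len(a)
    joint = np.bincount(a * n_levels_b + b, minlength=n_levels_a * n_levels_b).astype(float)
    joint = joint.reshape(n_levels_a, n_levels_b) / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _mi_vector(codes: np.ndarray, target: np.ndarray, n_levels_f: int, n_levels_t: int) -> np.ndarray:
    """MI of every feature column of ``codes`` against ``target`` (vectorized).

    One flat bincount builds all contingency tables at once.
    """
    n, nf = codes.shape
    width = n_levels_f * n_levels_t
    flat = (codes * n_levels_t + target[:, None] + np.arange(nf)[None, :] * width).ravel()
    joint = np.bincount(flat, minlength=nf * width).reshape(nf, n_levels_f, n_levels_t) / n
    pa = joint.sum(axis=2, keepdims=True)
    pb = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = joint * np.log(joint / (pa * pb))
    return np.nansum(terms, axis=(1, 2))


def mrmr_select(
    z: ZScoreMatrix | pd.DataFrame,
    labels: Sequence,
    n_select: int,
    bins: int = 3,
    criterion: str = "MID",
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    ``z`` holds candidate features in rows and samples in columns; ``labels``
    are the per-sample class labels aligned to the columns.  The first pick
    maximizes I(f; class); each next pick maximizes
    I(f; class) - mean_{s in selected} I(f; s) (MID) or the quotient form
    (MIQ).  Mutual information is estimated on discretized features (3 bins
    at mean +/- sd by default).  Constant features are excluded with a
    warning.  Deterministic: ties break on feature order.
    """
    values = z.values if isinstance(z, ZScoreMatrix) else z
    if isinstance(labels, pd.Series):
        labels = labels.reindex(values.columns).to_numpy()
    y = np.asarray(labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for mRMR")
    X = values.to_numpy(dtype=float).T  # samples x features
    feature_ids = list(values.index)

    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant feature(s) excluded from mRMR", stacklevel=2
        )
        X = X[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    if n_select > len(feature_ids):
        raise ValueError(
            f"n_select={n_select} exceeds the {len(feature_ids)} usable features"
        )

    codes = discretize_features(X, bins=bins)
    relevance = _mi_vector(codes, y_codes, bins, len(classes))

    n_feat = len(feature_ids)
    selected: list[int] = []
    selected_mask = np.zeros(n_feat, dtype=bool)
    redundancy_sum = np.zeros(n_feat)
    eps = 1e-12
    for step in range(n_select):
        if step == 0:
            score = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            if criterion == "MID":
                score = relevance - mean_red
            else:  # MIQ
                score = relevance / (mean_red + eps)
        score[selected_mask] = -np.inf
        pick = int(np.argmax(score))
        selected.append(pick)
        selected_mask[pick] = True
        # update running redundancy against the newest selected feature
        redundancy_sum += _mi_vector(codes, codes[:, pick], bins, bins)
    return [feature_ids[i] for i in selected]


# ---------------------------------------------------------------------------
# BER and CV framework
# ---------------------------------------------------------------------------


def balanced_error_rate(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Mean of the per-class misclassification fractions of a binary call."""
    y = np.asarray(true_labels)
    yhat = np.asarray(predicted_labels)
    if len(y) != len(yhat):
        raise ValueError("label vectors differ in length")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"true labels must contain exactly 2 classes, got {len(classes)}")
    errs = [(yhat[y == c] != c).mean() for c in classes]
    return float(np.mean(errs))


def stratified_folds(
    labels: Sequence, n_folds: int, seed: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs (train, test) over the samples."""
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _fold_signatures(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    train: np.ndarray,
    test: np.ndarray,
    sizes: Sequence[int],
    config: DiscoveryConfig,
    rf_seed: int,
) -> dict[int, tuple[tuple[str, ...], tuple[float, ...], float]]:
    """Screen the training split with mRMR, Gini-rank, then score each size.

    The top 5% mRMR features feed one forest whose mean-decrease-in-Gini
    importances rank them; the size-``s`` signature is the ``s`` top-ranked
    features, refit and scored on the held-out fold.
    """
    z_train = pd.DataFrame(X[train].T, index=feature_ids)
    n_top = max(1, int(np.ceil(config.top_frac * len(feature_ids))))
    screened = mrmr_select(
        z_train, y[train], n_top, bins=config.mi_bins, criterion=config.mrmr_criterion
    )
    col_of = {f: i for i, f in enumerate(feature_ids)}
    top_cols = [col_of[f] for f in screened]
    ranker = RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features="sqrt",
        random_state=rf_seed,
        n_jobs=1,
    )
    ranker.fit(X[np.ix_(train, top_cols)], y[train])
    gini_order = np.argsort(-ranker.feature_importances_, kind="stable")
    order = [screened[i] for i in gini_order]
    out: dict[int, tuple[tuple[str, ...], tuple[float, ...], float]] = {}
    for size in sizes:
        if size > len(order):
            continue
        feats = order[:size]
        cols = [col_of[f] for f in feats]
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features="sqrt",
            random_state=rf_seed + size,
            n_jobs=1,
        )
        rf.fit(X[np.ix_(train, cols)], y[train])
        pred = rf.predict(X[np.ix_(test, cols)])
        ber = balanced_error_rate(y[test], pred)
        imp_order = np.argsort(-rf.feature_importances_, kind="stable")
        feats_sorted = tuple(feats[i] for i in imp_order)
        imps_sorted = tuple(float(rf.feature_importances_[i]) for i in imp_order)
        out[size] = (feats_sorted, imps_sorted, ber)
    return out


def run_cv_framework(
    z: ZScoreMatrix | pd.DataFrame,
    labels: Sequence,
    config: DiscoveryConfig,
) -> CVResult:
    """Repeated stratified CV producing candidate signatures and BER curves.

    Emits exactly ``n_folds * n_repeats`` candidates at the selected size.
    Each repeat is mirrored by ``n_negative_controls`` label-permutation runs
    of the identical procedure, whose BERs form the chance-level reference.
    Fully seeded and deterministic.
    """
    values = z.values if isinstance(z, ZScoreMatrix) else z
    if isinstance(labels, pd.Series):
        labels = labels.reindex(values.columns).to_numpy()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly 2 classes")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= n_folds={config.n_folds}"
        )
    X = values.to_numpy(dtype=float).T  # samples x features
    feature_ids = list(values.index)

    rng = np.random.default_rng(config.seed)
    real_store: list[tuple[int, int, dict]] = []  # (repeat, fold, size->result)
    control_records: list[tuple[int, float]] = []  # (size, ber)

    for rep in range(config.n_repeats):
        fold_seed = int(rng.integers(2**31))
        rf_base = int(rng.integers(2**31 - 10_000))
        folds = stratified_folds(y, config.n_folds, seed=fold_seed)
        for fi, (train, test) in enumerate(folds):
            res = _fold_signatures(
                X, y, feature_ids, train, test, config.size_grid, config,
                rf_seed=(rf_base + fi * 100) % (2**31 - 20),
            )
            real_store.append((rep, fi, res))
        for _ in range(config.n_negative_controls):
            y_perm = rng.permutation(y)
            ctrl_seed = int(rng.integers(2**31))
            ctrl_rf = int(rng.integers(2**31 - 10_000))
            ctrl_folds = stratified_folds(y_perm, config.n_folds, seed=ctrl_seed)
            for fi, (train, test) in enumerate(ctrl_folds):
                res = _fold_signatures(
                    X, y_perm, feature_ids, train, test, config.size_grid, config,
                    rf_seed=(ctrl_rf + fi * 100) % (2**31 - 20),
                )
                for size, (_, _, ber) in res.items():
                    control_records.append((size, ber))

    # per-size summaries
    per_size: dict[int, list[float]] = {}
    for _, _, res in real_store:
        for size, (_, _, ber) in res.items():
            per_size.setdefault(size, []).append(ber)
    ber_by_size = pd.DataFrame(
        {
            "size": sorted(per_size),
            "mean_ber": [float(np.mean(per_size[s])) for s in sorted(per_size)],
            "sd_ber": [float(np.std(per_size[s], ddof=1)) if len(per_size[s]) > 1 else 0.0 for s in sorted(per_size)],
            "n": [len(per_size[s]) for s in sorted(per_size)],
        }
    )

    ctrl_per_size: dict[int, list[float]] = {}
    for size, ber in control_records:
        ctrl_per_size.setdefault(size, []).append(ber)
    control_ber_by_size = pd.DataFrame(
        {
            "size": sorted(ctrl_per_size),
            "mean_ber": [float(np.mean(ctrl_per_size[s])) for s in sorted(ctrl_per_size)],
            "n": [len(ctrl_per_size[s]) for s in sorted(ctrl_per_size)],
        }
    )

    mean_by_size = dict(zip(ber_by_size["size"], ber_by_size["mean_ber"]))
    selected_size = select_signature_size(mean_by_size, config.ber_tolerance)

    candidates = [
        SignatureCandidate(
            feature_ids=res[selected_size][0],
            importances=res[selected_size][1],
            test_ber=res[selected_size][2],
            repeat_idx=rep,
            fold_idx=fi,
        )
        for rep, fi, res in real_store
    ]
    control_at_size = np.array(ctrl_per_size.get(selected_size, []), dtype=float)
    return CVResult(
        candidates=candidates,
        selected_size=selected_size,
        ber_by_size=ber_by_size,
        control_ber_by_size=control_ber_by_size,
        control_bers=control_at_size,
    )


def select_signature_size(per_size_ber: Mapping[int, float], tolerance: float = 0.0) -> int:
    """Smallest size beyond which the mean BER no longer improves.

    Returns the smallest size ``s`` such that no larger size on the grid has
    a mean BER below ``BER(s) - tolerance``; a strictly improving profile
    selects the largest size.
    """
    if not per_size_ber:
        raise ValueError("empty BER profile")
    sizes = sorted(per_size_ber)
    for i, s in enumerate(sizes[:-1]):
        later_min = min(per_size_ber[t] for t in sizes[i + 1 :])
        if later_min >= per_size_ber[s] - tolerance:
            return s
    return sizes[-1]


# ---------------------------------------------------------------------------
# signature distance and representative selection
# ---------------------------------------------------------------------------


def _importance_sorted(sig: SignatureCandidate) -> list[str]:
    order = np.argsort(-np.asarray(sig.importances), kind="stable")
    return [sig.feature_ids[i] for i in order]


def signature_distance(
    sig1: SignatureCandidate,
    sig2: SignatureCandidate,
    z: ZScoreMatrix | pd.DataFrame,
    pairing: str = "gini",
) -> float:
    """Spearman signature distance ``D = 1 - mean_i Rho(F1_i, F2_i)``.

    Both signatures are sorted by descending Gini importance and paired
    positionally (``pairing="gini"``, the default) or by the maximum-weight
    assignment of the pairwise Rho matrix (``pairing="matching"``).  Rho is
    the Spearman correlation of the paired features' expression over the
    samples of ``z`` (pass tumor samples only).  D lies in [0, 2].
    """
    if sig1.size != sig2.size:
        raise ValueError(f"signature sizes differ: {sig1.size} vs {sig2.size}")
    values = z.values if isinstance(z, ZScoreMatrix) else z
    f1 = _importance_sorted(sig1)
    f2 = _importance_sorted(sig2)
    ranks = {
        f: rankdata(values.loc[f].to_numpy(dtype=float))
        for f in set(f1) | set(f2)
    }

    def rho(a: str, b: str) -> float:
        ra, rb = ranks[a], ranks[b]
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt((ra**2).sum() * (rb**2).sum())
        if denom == 0:
            return 0.0
        return float((ra * rb).sum() / denom)

    k = sig1.size
    if pairing == "gini":
        total = sum(rho(a, b) for a, b in zip(f1, f2))
    elif pairing == "matching":
        R = np.array([[rho(a, b) for b in f2] for a in f1])
        rows, cols = linear_sum_assignment(-R)
        total = float(R[rows, cols].sum())
    else:
        raise ValueError("pairing must be 'gini' or 'matching'")
    return 1.0 - total / k


def pick_representative(
    candidates: Sequence[SignatureCandidate],
    z: ZScoreMatrix | pd.DataFrame,
    pairing: str = "gini",
) -> DistanceResult:
    """Representative = candidate with the smallest summed pairwise distance.

    Ties (within 1e-12) break on lowest test BER, then lowest candidate
    index.  The Gini-positional pairing is vectorized through a Spearman
    correlation lookup over all features appearing in any candidate.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")
    k = candidates[0].size
    if any(c.size != k for c in candidates):
        raise ValueError("all candidates must share the same size")
    values = z.values if isinstance(z, ZScoreMatrix) else z

    feats = sorted({f for c in candidates for f in c.feature_ids})
    fidx = {f: i for i, f in enumerate(feats)}
    R = np.apply_along_axis(rankdata, 1, values.loc[feats].to_numpy(dtype=float))
    Rc = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt((Rc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    C = (Rc / norm[:, None]) @ (Rc / norm[:, None]).T  # Spearman rho lookup

    idx = np.array(
        [[fidx[f] for f in _importance_sorted(c)] for c in candidates], dtype=np.int64
    )
    n = len(candidates)
    if pairing == "gini":
        S = np.zeros((n, n))
        for i in range(k):
            S += C[np.ix_(idx[:, i], idx[:, i])]
        D = 1.0 - S / k
    elif pairing == "matching":
        D = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                sub = C[np.ix_(idx[a], idx[b])]
                rows, cols = linear_sum_assignment(-sub)
                D[a, b] = D[b, a] = 1.0 - float(sub[rows, cols].sum()) / k
    else:
        raise ValueError("pairing must be 'gini' or 'matching'")
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)

    summed = D.sum(axis=1)
    best = summed.min()
    tied = np.flatnonzero(summed <= best + 1e-12)
    rep = int(min(tied, key=lambda i: (candidates[i].test_ber, i)))
    return DistanceResult(distances=D, summed=summed, representative_idx=rep)
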