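"""Immunophenotyping: ssGSEA scoring, consensus clustering, IH/IL annotation.

Each tumor is scored against five immune expression signatures (IFN-gamma
response, lymphocyte infiltration, macrophages/monocytes, TGF-beta response,
wound healing) with single-sample GSEA.  Consensus clustering of the score
matrix partitions tumors into two robust clusters, and the cluster with
higher immune-activation scores is annotated Immune-High (IH), the other
Immune-Low (IL).  Cytolytic activity (geometric mean of GZMA and PRF1 FPKM)
and a generic two-group t-test round out the stage.

The ssGSEA enrichment score follows the standard single-sample formulation:
features are ranked per sample, and the score is the sum over the ranked
list of the difference between a rank-weighted in-set ECDF (weights
``rank^alpha``, normalized to 1) and the uniform out-of-set ECDF.  Ties get
average ranks so zero-inflated data score deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, ttest_ind
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix, GeneSetCollection
from . import io as _io

#: Signatures whose activation defines the Immune-High cluster.
IH_ACTIVATION_SETS = (
    "IFN-gamma response",
    "Lymphocyte infiltration",
    "Macrophages-monocytes",
)


@dataclass
class PhenotypeLabels:
    """IH/IL call per tumor sample plus the consensus matrix behind it."""

    label: pd.Series  # tumor sample id -> "IH" | "IL"
    consensus: pd.DataFrame  # samples x samples, entries in [0, 1]


@dataclass
class ClusterResult:
    assignments: pd.Series  # sample id -> cluster index (0-based)
    consensus: pd.DataFrame


def default_gene_sets() -> GeneSetCollection:
    """The packaged five-signature GMT (synthetic stand-in gene lists)."""
    with resources.as_file(
        resources.files("imlnc.data") / "immune_signatures_synthetic.gmt"
    ) as p:
        return _io.read_gmt(p)


def ssgsea(
    matrix: Union[ExpressionMatrix, pd.DataFrame],
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores: samples x gene sets.

    Per sample and set, with N features of which the set covers m (after
    intersecting with the matrix): walk the features in descending expression
    order, stepping the in-set ECDF by ``rank^alpha`` (normalized so in-set
    weights sum to 1) and the out-of-set ECDF by ``1/(N-m)``; the enrichment
    score is the sum of the running difference.  When ``normalize`` is set,
    all scores are divided by (max - min) over the whole score matrix.

    Sets whose members are entirely absent from the matrix raise; partially
    absent members are dropped with a warning.  A set that covers every
    feature has no out-of-set ECDF and scores 0 (with a warning).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    feature_index = values.index
    n = len(feature_index)

    masks: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        present = feature_index.isin(members)
        m = int(present.sum())
        if m == 0:
            raise ValueError(f"gene set {name!r} has no members in the expression matrix")
        if m < len(set(members)):
            warnings.warn(
                f"gene set {name!r}: {len(set(members)) - m} member(s) absent from matrix; dropped",
                stacklevel=2,
            )
        if m == n:
            warnings.warn(
                f"gene set {name!r} covers every feature; enrichment score set to 0",
                stacklevel=2,
            )
        masks[name] = present

    arr = values.to_numpy(dtype=float)
    sample_ids = values.columns
    scores = np.zeros((len(sample_ids), len(masks)))
    set_names = list(masks)

    for j in range(arr.shape[1]):
        x = arr[:, j]
        ranks = rankdata(x, method="average")  # ascending, ties averaged
        order = np.lexsort((np.arange(n), -x))  # descending expression, stable
        r_ord = ranks[order]
        w = r_ord**alpha
        for si, name in enumerate(set_names):
            inset = masks[name][order]
            m = int(inset.sum())
            if m == n:
                scores[j, si] = 0.0
                continue
            step_in = np.where(inset, w, 0.0)
            step_in /= step_in.sum()
            step_out = np.where(inset, 0.0, 1.0 / (n - m))
            scores[j, si] = np.cumsum(step_in - step_out).sum()

    es = pd.DataFrame(scores, index=sample_ids, columns=set_names)
    if normalize:
        spread = float(es.to_numpy().max() - es.to_numpy().min())
        if spread > 0:
            es = es / spread
    es.attrs["normalized"] = bool(normalize)
    return es


def consensus_cluster(
    es: pd.DataFrame,
    k: int = 2,
    n_resamples: int = 500,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    zscore_columns: bool = True,
) -> ClusterResult:
    """Resampling-based consensus clustering of the enrichment-score matrix.

    ``n_resamples`` subsamples of ``subsample_frac`` of the samples are each
    partitioned by k-means (10 restarts); the consensus matrix entry (i, j)
    is the fraction of co-clustered resamples among those where both samples
    were drawn.  The final partition is average-linkage hierarchical
    clustering of (1 - consensus) cut at ``k`` groups.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = es.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}, got {n}")
    if not (0.0 < subsample_frac <= 1.0):
        raise ValueError(f"subsample_frac must lie in (0, 1], got {subsample_frac!r}")

    X = es.to_numpy(dtype=float)
    if zscore_columns:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    size = max(int(np.ceil(subsample_frac * n)), k)
    co = np.zeros((n, n))
    drawn = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=size, replace=False)
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(X[idx])
        same = (lab[:, None] == lab[None, :]).astype(float)
        co[np.ix_(idx, idx)] += same
        drawn[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(drawn > 0, co / np.maximum(drawn, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=k, criterion="maxclust") - 1

    ids = es.index
    return ClusterResult(
        assignments=pd.Series(assign, index=ids),
        consensus=pd.DataFrame(consensus, index=ids, columns=ids),
    )


def consensus_k_scan(
    es: pd.DataFrame,
    ks: Sequence[int] = (2, 3, 4, 5),
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean within-cluster consensus for a range of k — a diagnostic only.

    The headline path fixes k = 2; this scan lets users confirm that two
    clusters are the robust choice for their cohort.
    """
    rows = []
    for i, k in enumerate(ks):
        res = consensus_cluster(
            es, k=k, n_resamples=n_resamples, subsample_frac=subsample_frac,
            seed=None if seed is None else seed + i,
        )
        c = res.consensus.to_numpy()
        same = res.assignments.to_numpy()[:, None] == res.assignments.to_numpy()[None, :]
        np.fill_diagonal(same, False)
        rows.append({"k": k, "mean_cluster_consensus": float(c[same].mean())})
    return pd.DataFrame(rows)


def annotate_ih_il(
    es: pd.DataFrame,
    clustering: ClusterResult,
    activation_sets: Sequence[str] = IH_ACTIVATION_SETS,
) -> PhenotypeLabels:
    """Name the cluster with higher immune-activation scores Immune-High.

    The activation score of a cluster is its mean enrichment score averaged
    over the IFN-gamma response, lymphocyte-infiltration and
    macrophages/monocytes columns (those are the signatures that separate the
    clusters; TGF-beta and wound healing do not discriminate).
    """
    clusters = sorted(clustering.assignments.unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(clusters)}")
    cols = [c for c in activation_sets if c in es.columns]
    if not cols:
        raise ValueError(
            f"none of the activation sets {tuple(activation_sets)} found among "
            f"score columns {tuple(es.columns)}"
        )
    means = {
        c: float(es.loc[clustering.assignments[clustering.assignments == c].index, cols].mean().mean())
        for c in clusters
    }
    a, b = clusters
    if means[a] == means[b]:
        raise ValueError("cluster activation means are exactly tied; cannot annotate IH/IL")
    ih_cluster = a if means[a] > means[b] else b
    label = clustering.assignments.map(lambda c: "IH" if c == ih_cluster else "IL")
    return PhenotypeLabels(label=label, consensus=clustering.consensus)


def cytolytic_activity(
    matrix: ExpressionMatrix, gzma_id: str = "GZMA", prf1_id: str = "PRF1"
) -> pd.Series:
    """Per-sample cytolytic activity: geometric mean of GZMA and PRF1 FPKM."""
    for fid in (gzma_id, prf1_id):
        if fid not in matrix.feature_ids:
            raise KeyError(f"feature {fid!r} not present in expression matrix")
    gzma = matrix.values.loc[gzma_id].to_numpy(dtype=float)
    prf1 = matrix.values.loc[prf1_id].to_numpy(dtype=float)
    cyt = np.sqrt(gzma * prf1)
    return pd.Series(cyt, index=matrix.sample_ids, name="CYT")


def compare_groups(
    matrix: ExpressionMatrix,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    feature_ids: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature two-sample Student's t-test on log2(FPKM + pseudocount).

    Equal-variance t; returns a DataFrame with columns ``t`` and ``p`` indexed
    by feature.  Used for group comparisons of immune effectors and
    enrichment-score columns alike.
    """
    a = list(group_a_ids)
    b = list(group_b_ids)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    feats = pd.Index(feature_ids) if feature_ids is not None else matrix.feature_ids
    sub = matrix.values.loc[feats]
    la = np.log2(sub[a].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(sub[b].to_numpy(dtype=float) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(la, lb, axis=1, equal_var=True)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"t": t, "p": p}, index=feats)
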