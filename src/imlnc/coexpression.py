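"""Co-expression of genes with signature lncRNAs, permutation-corrected.

For each (signature lncRNA, gene) pair the Spearman correlation Rho and its
large-sample p-value P_r are computed.  P_r is then corrected empirically:
the gene's expression is held fixed while the correlation test is repeated
against random lncRNAs drawn from the expressed-lncRNA pool, and

    P_e = (#{P_p <= P_r} + 1) / (n_perm + 1)

with a pseudo-count of 1, so P_e is never 0 and its floor is
1/(n_perm + 1).  Edges with Rho > 0.6 and P_e < 0.01 (strict inequalities)
form the co-expression network.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy import stats as _stats


def _rank_rows(df: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, df.to_numpy(dtype=float))


def _rho_matrix(ranks_a: np.ndarray, ranks_b: np.ndarray) -> np.ndarray:
    """Spearman rho of every row of a against every row of b (same n columns)."""
    ca = ranks_a - ranks_a.mean(axis=1, keepdims=True)
    cb = ranks_b - ranks_b.mean(axis=1, keepdims=True)
    na = np.sqrt((ca**2).sum(axis=1))
    nb = np.sqrt((cb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ca @ cb.T) / np.outer(na, nb)
    return rho


def _rho_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the large-sample t approximation, df = n - 2."""
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c**2))
    p = 2 * _stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho_c) >= 1.0, 0.0, p)


def spearman_all(lncrna_exprs: pd.DataFrame, gene_matrix: pd.DataFrame) -> pd.DataFrame:
    """Rho and raw p for every (lncRNA, gene) pair over shared samples.

    Both inputs carry features in rows and samples in columns; columns must
    align.  Pairs involving a constant vector have undefined Rho and are
    skipped with a warning.
    """
    if lncrna_exprs.shape[1] != gene_matrix.shape[1] or not (
        lncrna_exprs.columns == gene_matrix.columns
    ).all():
        raise ValueError("sample columns of the two matrices must match")
    n = lncrna_exprs.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for a Spearman test")

    ra = _rank_rows(lncrna_exprs)
    rb = _rank_rows(gene_matrix)
    const_l = ra.std(axis=1) == 0
    const_g = rb.std(axis=1) == 0
    if const_l.any() or const_g.any():
        warnings.warn(
            f"skipping {int(const_l.sum())} constant lncRNA(s) and "
            f"{int(const_g.sum())} constant gene(s): Rho undefined",
            stacklevel=2,
        )
    rho = _rho_matrix(ra, rb)
    p = _rho_pvalue(rho, n)

    lidx, gidx = np.where(~const_l[:, None] & ~const_g[None, :])
    return pd.DataFrame(
        {
            "lncrna_id": lncrna_exprs.index[lidx],
            "gene_id": gene_matrix.index[gidx],
            "rho": rho[lidx, gidx],
            "p_raw": p[lidx, gidx],
        }
    )


def empirical_pvalue(
    gene_expr: pd.Series,
    target_lncrna: pd.Series,
    lncrna_pool: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    replace: bool = False,
) -> float:
    """Permutation-corrected p for one (gene, lncRNA) pair.

    The gene's expression stays fixed; ``n_perm`` lncRNAs drawn from the pool
    (the target itself is excluded; without replacement unless ``replace``)
    are each correlated with the gene, and P_e is the pseudo-counted fraction
    of permutation p-values at or below the pair's raw p.
    """
    pool = lncrna_pool
    if target_lncrna.name in pool.index:
        pool = pool.drop(index=target_lncrna.name)
    if not replace and pool.shape[0] < n_perm:
        raise ValueError(
            f"pool has {pool.shape[0]} lncRNAs < n_perm={n_perm}; "
            "pass replace=True to sample with replacement"
        )
    n = len(gene_expr)
    g_rank = rankdata(gene_expr.to_numpy(dtype=float))[None, :]
    t_rank = rankdata(target_lncrna.to_numpy(dtype=float))[None, :]
    p_r = float(_rho_pvalue(_rho_matrix(t_rank, g_rank), n)[0, 0])

    rng = np.random.default_rng(seed)
    pick = rng.choice(pool.shape[0], size=n_perm, replace=replace)
    perm_ranks = _rank_rows(pool.iloc[pick])
    p_p = _rho_pvalue(_rho_matrix(perm_ranks, g_rank), n)[:, 0]
    return float((np.sum(p_p <= p_r) + 1) / (n_perm + 1))


def add_empirical_pvalues(
    edges: pd.DataFrame,
    lncrna_pool: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    replace: bool = False,
    rho_prefilter: float | None = None,
) -> pd.DataFrame:
    """Attach ``p_empirical`` to an edge table from :func:`spearman_all`.

    With ``rho_prefilter`` set, the (costly) permutation test runs only for
    edges whose Rho exceeds it — the others can never pass the network filter
    and get ``p_empirical = NaN``.  The permutation draw is seeded per gene so
    all edges of a gene share one null sample.
    """
    out = edges.copy()
    out["p_empirical"] = np.nan
    out["n_permutations"] = n_perm
    todo = out if rho_prefilter is None else out[out["rho"] > rho_prefilter]
    rng = np.random.default_rng(seed)
    for gene_id, block in todo.groupby("gene_id", sort=True):
        gene_seed = int(rng.integers(2**31))
        for i, row in block.iterrows():
            out.loc[i, "p_empirical"] = empirical_pvalue(
                gene_matrix.loc[gene_id],
                lncrna_pool.loc[row["lncrna_id"]],
                lncrna_pool,
                n_perm=n_perm,
                seed=gene_seed,
                replace=replace,
            )
    return out


def build_network(
    edges: pd.DataFrame, rho_thresh: float = 0.6, pe_thresh: float = 0.01
) -> pd.DataFrame:
    """Retain edges with Rho > rho_thresh and P_e < pe_thresh (both strict).

    Sorted by (lncrna_id, descending Rho)."""
    keep = (edges["rho"] > rho_thresh) & (edges["p_empirical"] < pe_thresh)
    kept = edges[keep].copy()
    kept = kept.sort_values(["lncrna_id", "rho"], ascending=[True, False])
    return kept.reset_index(drop=True)


def write_sif(edges: pd.DataFrame, path) -> None:
    """Simple SIF-style export: lncrna <tab> coexpressed <tab> gene."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['lncrna_id']}\tcoexpressed\t{row['gene_id']}\n")
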