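"""End-to-end orchestration of the immunophenotyping / signature pipeline.

``run_all`` chains simulate (optional) -> preprocess -> phenotype -> diffexp
-> select-signature -> score -> associate -> coexpress, writing every stage's
tabular output as TSV plus a JSON run manifest (parameters, derived seeds,
output checksums).  One global seed fans out to per-stage seeds through a
documented hash derivation, so each stage is independently reproducible from
its intermediates.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import coexpression as coexpr_mod
from . import diffexp as de_mod
from . import discovery as disc_mod
from . import io as _io
from . import phenotype as ph_mod
from . import preprocess as pre_mod
from . import scoring as score_mod
from .cohort import CohortSpec, generate_cohort, write_fixture

log = logging.getLogger("imlnc.pipeline")

__version__ = "1.0.0"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},  # extra keys = CohortSpec overrides
    "paths": {},  # expression/annotation/gene_sets/infiltration when not simulating
    "preprocess": {"min_expr_frac": 0.7},
    "phenotype": {
        "alpha": 0.25,
        "normalize": True,
        "k": 2,
        "n_resamples": 500,
        "subsample_frac": 0.8,
        "zscore_columns": True,
    },
    "diffexp": {"fdr_thresh": 0.01, "lfc_thresh": 2.0},
    "discovery": {
        "n_folds": 3,
        "n_repeats": 1000,
        "top_frac": 0.05,
        "size_grid": list(range(1, 16)),
        "ber_tolerance": 0.01,
        "n_negative_controls": 1,
        "rf_trees": 500,
        "min_candidate_pool": 20,
    },
    "scoring": {"n_boot": 2000},
    "coexpression": {"n_perm": 1000, "rho_thresh": 0.6, "pe_thresh": 0.01},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256 of ``"<seed>:<stage>"`` mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_config(**overrides) -> dict:
    """Deep-copied default config with per-stage override dicts merged in."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in overrides.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return make_config(**user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: dict, outdir) -> dict:
    """Run the full pipeline; returns (and writes) the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}}

    def record(stage: str, params: dict, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "seed": stage_seed(seed, stage),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
        }

    # -- simulate ------------------------------------------------------------
    sim_cfg = dict(config.get("simulate", {}))
    simulate = sim_cfg.pop("enabled", False)
    truth = None
    if simulate:
        spec = CohortSpec(**{**sim_cfg, "seed": stage_seed(seed, "simulate")})
        matrix, sets, truth = generate_cohort(spec)
        paths = write_fixture(outdir / "simulate", matrix, sets, truth)
        record("simulate", {"spec": spec.__dict__}, paths)
        infiltration = truth.infiltration
    else:
        p = config["paths"]
        for key in ("expression", "annotation", "gene_sets"):
            if key not in p or not Path(p[key]).exists():
                raise FileNotFoundError(f"missing input file for {key!r}: {p.get(key)}")
        matrix = _io.read_expression(p["expression"], p["annotation"])
        sets = _io.read_gmt(p["gene_sets"])
        infiltration = (
            pd.read_csv(p["infiltration"], sep="\t", index_col=0)
            if p.get("infiltration")
            else None
        )

    # -- preprocess ----------------------------------------------------------
    pp = config["preprocess"]
    filtered = pre_mod.filter_expressed(matrix, min_expr_frac=pp["min_expr_frac"])
    stage_dir = outdir / "preprocess"
    stage_dir.mkdir(exist_ok=True)
    _io.write_expression(filtered, stage_dir / "filtered_expression.tsv")
    record("preprocess", dict(pp), {"filtered_expression": stage_dir / "filtered_expression.tsv"})
    log.info("preprocess: kept %d/%d features", filtered.n_features, matrix.n_features)

    # -- phenotype -----------------------------------------------------------
    phc = config["phenotype"]
    tumors = filtered.subset_samples(filtered.tumor_ids)
    es = ph_mod.ssgsea(tumors, sets, alpha=phc["alpha"], normalize=phc["normalize"])
    clustering = ph_mod.consensus_cluster(
        es,
        k=phc["k"],
        n_resamples=phc["n_resamples"],
        subsample_frac=phc["subsample_frac"],
        seed=stage_seed(seed, "phenotype"),
        zscore_columns=phc["zscore_columns"],
    )
    labels = ph_mod.annotate_ih_il(es, clustering)
    stage_dir = outdir / "phenotype"
    stage_dir.mkdir(exist_ok=True)
    es.rename_axis("sample_id").to_csv(stage_dir / "enrichment_scores.tsv", sep="\t")
    labels.label.rename("phenotype").rename_axis("sample_id").reset_index().to_csv(
        stage_dir / "labels.tsv", sep="\t", index=False
    )
    labels.consensus.rename_axis("sample_id").to_csv(stage_dir / "consensus.tsv", sep="\t")
    record(
        "phenotype",
        dict(phc),
        {
            "enrichment_scores": stage_dir / "enrichment_scores.tsv",
            "labels": stage_dir / "labels.tsv",
            "consensus": stage_dir / "consensus.tsv",
        },
    )

    ih_ids = labels.label.index[labels.label == "IH"].tolist()
    il_ids = labels.label.index[labels.label == "IL"].tolist()
    normal_ids = filtered.normal_ids.tolist()

    # -- diffexp -------------------------------------------------------------
    dec = config["diffexp"]
    ih_res = de_mod.diff_expr(filtered, ih_ids, normal_ids, **dec)
    il_res = de_mod.diff_expr(filtered, il_ids, normal_ids, **dec)
    records = de_mod.categorize(ih_res, il_res)
    # volcano-plot-ready axes
    records["neg_log10_fdr_ih"] = -np.log10(records["fdr_ih"].clip(lower=1e-300))
    records["neg_log10_fdr_il"] = -np.log10(records["fdr_il"].clip(lower=1e-300))
    stage_dir = outdir / "diffexp"
    stage_dir.mkdir(exist_ok=True)
    records.rename_axis("lncrna_id").to_csv(stage_dir / "diff_lncrnas.tsv", sep="\t")
    record("diffexp", dict(dec), {"diff_lncrnas": stage_dir / "diff_lncrnas.tsv"})

    # -- select-signature ----------------------------------------------------
    dc = dict(config["discovery"])
    min_pool = dc.pop("min_candidate_pool", 20)
    de_candidates = records.index[records["category"] != "none"].tolist()
    if len(de_candidates) < min_pool:
        log.warning(
            "only %d differential lncRNAs; using all %d lncRNAs as candidates",
            len(de_candidates),
            len(filtered.lncrna_ids),
        )
        de_candidates = filtered.lncrna_ids.tolist()
    tumor_log2 = pre_mod.log2_transform(filtered.subset_samples(ih_ids + il_ids))
    cand_log2 = tumor_log2.loc[de_candidates]
    nonconst = cand_log2.std(axis=1, ddof=1) > 0
    z_tumor = pre_mod.zscore_rows(cand_log2.loc[nonconst[nonconst].index])
    disc_config = disc_mod.DiscoveryConfig(
        size_grid=tuple(dc.pop("size_grid")), seed=stage_seed(seed, "select-signature"), **dc
    )
    cv = disc_mod.run_cv_framework(z_tumor, labels.label, disc_config)
    dist = disc_mod.pick_representative(cv.candidates, z_tumor)
    representative = cv.candidates[dist.representative_idx]
    stage_dir = outdir / "signature"
    stage_dir.mkdir(exist_ok=True)
    cand_df = pd.DataFrame(
        {
            "repeat": [c.repeat_idx for c in cv.candidates],
            "fold": [c.fold_idx for c in cv.candidates],
            "features": [";".join(c.feature_ids) for c in cv.candidates],
            "test_ber": [c.test_ber for c in cv.candidates],
            "summed_distance": dist.summed,
        }
    )
    _io.write_table(cand_df, stage_dir / "candidates.tsv")
    _io.write_table(cv.ber_by_size, stage_dir / "ber_by_size.tsv")
    _io.write_table(cv.control_ber_by_size, stage_dir / "control_ber_by_size.tsv")
    sig_df = pd.DataFrame(
        {"lncrna_id": representative.feature_ids, "gini_importance": representative.importances}
    )
    _io.write_table(sig_df, stage_dir / "signature.tsv")
    _io.write_json(
        {
            "selected_size": cv.selected_size,
            "representative_idx": int(dist.representative_idx),
            "representative_test_ber": representative.test_ber,
            "representative_summed_distance": float(dist.summed[dist.representative_idx]),
            "mean_negative_control_ber": float(np.mean(cv.control_bers))
            if len(cv.control_bers)
            else None,
        },
        stage_dir / "distance_summary.json",
    )
    record(
        "select-signature",
        {**dc, "size_grid": list(disc_config.size_grid), "n_candidates_pool": len(de_candidates)},
        {
            "candidates": stage_dir / "candidates.tsv",
            "ber_by_size": stage_dir / "ber_by_size.tsv",
            "control_ber_by_size": stage_dir / "control_ber_by_size.tsv",
            "signature": stage_dir / "signature.tsv",
            "distance_summary": stage_dir / "distance_summary.json",
        },
    )

    # -- score ---------------------------------------------------------------
    sc = config["scoring"]
    sig_ids = list(representative.feature_ids)
    z_sig = disc_mod.ZScoreMatrix(
        values=z_tumor.values.loc[sig_ids], provenance=z_tumor.provenance
    )
    imls = score_mod.compute_imlncscore(z_sig, labels.label)
    roc = score_mod.roc_auc(
        imls.score,
        (labels.label.reindex(imls.score.index) == "IH"),
        n_boot=sc["n_boot"],
        seed=stage_seed(seed, "score"),
    )
    cutoff = score_mod.optimal_cutoff(roc)
    stage_dir = outdir / "score"
    stage_dir.mkdir(exist_ok=True)
    scores_df = pd.DataFrame(
        {
            "sample_id": imls.score.index,
            "im_lncScore": imls.score.values,
            "predicted_phenotype": np.where(imls.score.values >= cutoff, "IH", "IL"),
        }
    )
    _io.write_table(scores_df, stage_dir / "scores.tsv")
    _io.write_table(
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}),
        stage_dir / "roc_points.tsv",
    )
    _io.write_json(
        {
            "auc": roc.auc,
            "ci_low": roc.ci_low,
            "ci_high": roc.ci_high,
            "cutoff": cutoff,
            "variance_explained": imls.variance_explained,
        },
        stage_dir / "roc_summary.json",
    )
    record(
        "score",
        dict(sc),
        {
            "scores": stage_dir / "scores.tsv",
            "roc_points": stage_dir / "roc_points.tsv",
            "roc_summary": stage_dir / "roc_summary.json",
        },
    )

    # -- associate -----------------------------------------------------------
    stage_dir = outdir / "associate"
    stage_dir.mkdir(exist_ok=True)
    if infiltration is not None:
        predictors = z_tumor.values.loc[sig_ids].copy()
        predictors.loc["im_lncScore"] = imls.score.reindex(predictors.columns)
        assoc = assoc_mod.associate_all(predictors, infiltration)
        _io.write_table(assoc, stage_dir / "associations.tsv")
        record("associate", {}, {"associations": stage_dir / "associations.tsv"})
    else:
        log.info("associate: no infiltration table supplied; stage skipped")
        manifest["stages"]["associate"] = {"skipped": "no infiltration table"}

    # -- coexpress -----------------------------------------------------------
    cx = config["coexpression"]
    tumor_samples = ih_ids + il_ids
    gene_expr = filtered.values.loc[filtered.gene_ids, tumor_samples]
    lnc_pool = filtered.values.loc[filtered.lncrna_ids, tumor_samples]
    sig_expr = lnc_pool.loc[sig_ids]
    edges = coexpr_mod.spearman_all(sig_expr, gene_expr)
    n_perm = cx["n_perm"]
    replace = lnc_pool.shape[0] - 1 < n_perm
    if replace:
        log.warning(
            "lncRNA pool (%d) smaller than n_perm=%d; sampling with replacement",
            lnc_pool.shape[0],
            n_perm,
        )
    edges = coexpr_mod.add_empirical_pvalues(
        edges,
        lnc_pool,
        gene_expr,
        n_perm=n_perm,
        seed=stage_seed(seed, "coexpress"),
        replace=replace,
        rho_prefilter=cx["rho_thresh"],
    )
    network = coexpr_mod.build_network(
        edges, rho_thresh=cx["rho_thresh"], pe_thresh=cx["pe_thresh"]
    )
    stage_dir = outdir / "coexpress"
    stage_dir.mkdir(exist_ok=True)
    _io.write_table(edges, stage_dir / "edges.tsv")
    _io.write_table(network, stage_dir / "network.tsv")
    coexpr_mod.write_sif(network, stage_dir / "network.sif")
    record(
        "coexpress",
        {**cx, "replace": replace},
        {
            "edges": stage_dir / "edges.tsv",
            "network": stage_dir / "network.tsv",
            "network_sif": stage_dir / "network.sif",
        },
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
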