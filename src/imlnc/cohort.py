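"""Synthetic tumor cohorts with a planted immunophenotype ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against a known answer:

* tumor and normal sample groups,
* a latent two-level immunophenotype (Immune-High / Immune-Low) that drives
  coordinated over-expression of five immune gene sets in the IH tumors,
* a small set of "planted" lncRNAs whose expression tracks the
  immunophenotype (and is elevated in tumors relative to normal tissue, so
  they survive a tumor-vs-normal differential screen),
* per-sample immune-infiltration proxies positively coupled to IH,
* log-normal FPKM noise with configurable zero inflation.

Expression is modeled on the log2 scale (Gaussian per entry, then
exponentiated to FPKM); zeros are injected after exponentiation so the
expressed-fraction filter has something to act on, and dropout is biased
toward weakly expressed entries (an exact ``zero_frac`` of entries, chosen
by lowest noise-perturbed abundance) as in real FPKM data.  A configurable fraction
of background features receives a tumor-vs-normal shift with random sign and
no phenotype dependence, giving the differential-expression stage a realistic
candidate pool that is larger than the planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSetCollection
from . import io as _io

#: Canonical names of the five immune expression signatures used throughout.
IMMUNE_SET_NAMES = (
    "IFN-gamma response",
    "Lymphocyte infiltration",
    "Macrophages-monocytes",
    "TGF-beta response",
    "Wound healing",
)

#: The six tumor-infiltrating immune cell types tracked by the proxies.
INFILTRATION_CELL_TYPES = (
    "B cell",
    "T cell CD4",
    "T cell CD8",
    "Macrophage",
    "Neutrophil",
    "Myeloid dendritic cell",
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the log2-scale mean shift of planted lncRNAs and
    immune-set genes in IH tumors relative to IL tumors and normals.
    ``tumor_shift`` is the extra log2 shift planted lncRNAs carry in *all*
    tumors relative to normals, so they are differentially expressed against
    the normal group as well.  ``frac_tumor_de`` background features receive a
    random-sign tumor-vs-normal shift that is independent of the phenotype.
    """

    n_tumor: int = 144
    n_normal: int = 5
    n_genes: int = 2000
    n_lncrnas: int = 1500
    n_planted_lncrnas: int = 6
    frac_ih: float = 0.4
    effect_size: float = 2.0
    zero_frac: float = 0.1
    noise_sd: float = 1.0
    tumor_shift: float = 3.0
    frac_tumor_de: float = 0.3
    immune_set_size: int = 30
    infiltration_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_genes", "n_lncrnas", "n_planted_lncrnas"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_planted_lncrnas > self.n_lncrnas:
            raise ValueError("n_planted_lncrnas must not exceed n_lncrnas")
        if not (0.0 < self.frac_ih < 1.0):
            raise ValueError(f"frac_ih must lie in (0, 1), got {self.frac_ih!r}")
        if not (0.0 <= self.zero_frac < 1.0):
            raise ValueError(f"zero_frac must lie in [0, 1), got {self.zero_frac!r}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd!r}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be nonnegative, got {self.effect_size!r}")
        if not (0.0 <= self.frac_tumor_de <= 1.0):
            raise ValueError(f"frac_tumor_de must lie in [0, 1], got {self.frac_tumor_de!r}")
        if 5 * self.immune_set_size > self.n_genes:
            raise ValueError("n_genes too small for five disjoint immune sets")


@dataclass
class GroundTruth:
    """What the generator planted: the answer key for downstream stages."""

    phenotype_labels: pd.Series  # sample id -> IH | IL | normal
    planted_lncrna_ids: list[str]
    immune_set_members: dict[str, list[str]]
    infiltration: pd.DataFrame  # tumor samples x 6 cell types, nonnegative
    spec: Optional[CohortSpec] = None

    @property
    def ih_ids(self) -> pd.Index:
        return self.phenotype_labels.index[self.phenotype_labels == "IH"]

    @property
    def il_ids(self) -> pd.Index:
        return self.phenotype_labels.index[self.phenotype_labels == "IL"]


def tcga_gbm_preset(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort preset mirroring the real study's sample layout.

    144 tumors plus 5 normals (149 samples).  The feature space is a
    scaled-down stand-in (2000 genes, 1500 lncRNAs) chosen for desk-scale
    runtimes; the real cohort's ~18k genes and ~18k lncRNAs are reachable by
    overriding ``n_genes``/``n_lncrnas``.
    """
    return CohortSpec(seed=seed, **overrides)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, GeneSetCollection, GroundTruth]:
    """Generate a cohort; a pure function of ``spec`` (same seed, same output)."""
    rng = np.random.default_rng(spec.seed)

    n_features = spec.n_genes + spec.n_lncrnas
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    lnc_ids = [f"L{i:05d}" for i in range(spec.n_lncrnas)]
    feature_ids = gene_ids + lnc_ids
    biotype = pd.Series(
        ["gene"] * spec.n_genes + ["lncRNA"] * spec.n_lncrnas, index=feature_ids
    )

    tumor_ids = [f"T{i:04d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(spec.n_normal)]
    sample_ids = tumor_ids + normal_ids
    groups = pd.Series(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal, index=sample_ids)

    # latent phenotype: random subset of tumors is Immune-High
    n_ih = int(round(spec.frac_ih * spec.n_tumor))
    n_ih = min(max(n_ih, 1), spec.n_tumor - 1)
    ih_mask = np.zeros(spec.n_tumor, dtype=bool)
    ih_mask[rng.choice(spec.n_tumor, size=n_ih, replace=False)] = True
    phenotype = pd.Series(
        np.where(ih_mask, "IH", "IL").tolist() + ["normal"] * spec.n_normal,
        index=sample_ids,
    )

    # immune sets: five disjoint blocks of genes
    immune_genes = rng.choice(spec.n_genes, size=5 * spec.immune_set_size, replace=False)
    set_members = {
        name: sorted(gene_ids[g] for g in immune_genes[i * spec.immune_set_size : (i + 1) * spec.immune_set_size])
        for i, name in enumerate(IMMUNE_SET_NAMES)
    }
    immune_gene_rows = np.zeros(n_features, dtype=bool)
    immune_gene_rows[immune_genes] = True

    # planted lncRNAs
    planted_pos = rng.choice(spec.n_lncrnas, size=spec.n_planted_lncrnas, replace=False)
    planted_rows = np.zeros(n_features, dtype=bool)
    planted_rows[spec.n_genes + planted_pos] = True
    planted_ids = sorted(lnc_ids[p] for p in planted_pos)

    # per-feature baseline log2 expression
    base = rng.normal(3.0, 1.5, size=n_features)

    # tumor-vs-normal shifts: background DE features (phenotype-independent)
    tumor_de_mask = rng.random(n_features) < spec.frac_tumor_de
    tumor_de_mask &= ~immune_gene_rows & ~planted_rows
    tumor_delta = np.zeros(n_features)
    tumor_delta[tumor_de_mask] = rng.uniform(2.5, 4.0, size=tumor_de_mask.sum()) * rng.choice(
        [-1.0, 1.0], size=tumor_de_mask.sum()
    )
    tumor_delta[planted_rows] = spec.tumor_shift

    # mean log2 matrix: features x samples
    mean = np.tile(base[:, None], (1, len(sample_ids)))
    is_tumor = np.array([g == "tumor" for g in groups])
    is_ih = np.array([phenotype[s] == "IH" for s in sample_ids])
    mean[:, is_tumor] += tumor_delta[:, None]
    ih_effect_rows = immune_gene_rows | planted_rows
    mean[np.ix_(ih_effect_rows, is_ih)] += spec.effect_size

    log2_vals = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    fpkm = np.exp2(log2_vals)
    if spec.zero_frac > 0:
        # dropout concentrates in weakly expressed entries, as in real FPKM
        # data: zero exactly zero_frac of entries, picking those with the
        # lowest Gumbel-perturbed log2 abundance (a weighted random draw)
        n_zero = int(round(spec.zero_frac * fpkm.size))
        if n_zero > 0:
            perturbed = log2_vals + rng.gumbel(0.0, 2.0, size=log2_vals.shape)
            flat = fpkm.reshape(-1)
            flat[np.argpartition(perturbed.reshape(-1), n_zero - 1)[:n_zero]] = 0.0

    values = pd.DataFrame(fpkm, index=feature_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values=values, biotype=biotype, sample_group=groups)
    sets = GeneSetCollection(
        sets={k: list(v) for k, v in set_members.items()},
        descriptions={k: "synthetic immune expression signature" for k in set_members},
    )

    # infiltration proxies: log-normal, mean shifted upward in IH tumors
    infil_log = rng.normal(1.0, 0.5, size=(spec.n_tumor, len(INFILTRATION_CELL_TYPES)))
    infil_log[ih_mask] += spec.infiltration_shift
    infiltration = pd.DataFrame(
        np.exp(infil_log), index=tumor_ids, columns=list(INFILTRATION_CELL_TYPES)
    )

    truth = GroundTruth(
        phenotype_labels=phenotype,
        planted_lncrna_ids=planted_ids,
        immune_set_members=set_members,
        infiltration=infiltration,
        spec=spec,
    )
    return matrix, sets, truth


def write_fixture(
    outdir,
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write a cohort to disk as TSV/GMT/JSON; round-trips through :mod:`imlnc.io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "samples.tsv",
        "gene_sets": outdir / "immune_sets.gmt",
        "truth": outdir / "truth.json",
        "infiltration": outdir / "infiltration.tsv",
    }
    _io.write_expression(matrix, paths["expression"])
    _io.write_sample_annotation(matrix.sample_group, paths["annotation"])
    _io.write_gmt(sets, paths["gene_sets"])
    truth.infiltration.rename_axis("sample_id").to_csv(paths["infiltration"], sep="\t")
    payload = {
        "phenotype_labels": truth.phenotype_labels.to_dict(),
        "planted_lncrna_ids": list(truth.planted_lncrna_ids),
        "immune_set_members": {k: list(v) for k, v in truth.immune_set_members.items()},
        "spec": asdict(truth.spec) if truth.spec is not None else None,
    }
    _io.write_json(payload, paths["truth"])
    return paths


def read_truth(truth_path, infiltration_path) -> GroundTruth:
    payload = _io.read_json(truth_path)
    infiltration = pd.read_csv(infiltration_path, sep="\t", index_col=0)
    infiltration.index.name = None
    spec = CohortSpec(**payload["spec"]) if payload.get("spec") else None
    return GroundTruth(
        phenotype_labels=pd.Series(payload["phenotype_labels"]),
        planted_lncrna_ids=list(payload["planted_lncrna_ids"]),
        immune_set_members={k: list(v) for k, v in payload["immune_set_members"].items()},
        infiltration=infiltration,
        spec=spec,
    )
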