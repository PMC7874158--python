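"""Core in-memory containers for expression data and gene sets.

The pipeline's substrate is a feature-by-sample FPKM matrix in which every
feature is annotated with a biotype (``gene`` or ``lncRNA``) and every sample
with a group (``tumor`` or ``normal``).  :class:`ExpressionMatrix` wraps a
:class:`pandas.DataFrame` with those two annotations and validates their
consistency once, so downstream stages can subset by biotype or group without
re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("gene", "lncRNA")
VALID_GROUPS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Feature x sample FPKM matrix with biotype and group annotations.

    Parameters
    ----------
    values
        DataFrame of nonnegative FPKM values, features in rows (index =
        feature ids), samples in columns (columns = sample ids).
    biotype
        Series mapping feature id -> ``"gene"`` or ``"lncRNA"``; must cover
        exactly the features of ``values``.
    sample_group
        Series mapping sample id -> ``"tumor"`` or ``"normal"``; must cover
        exactly the samples of ``values``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    sample_group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        self.biotype = self.biotype.reindex(self.values.index)
        if self.biotype.isna().any():
            missing = self.biotype.index[self.biotype.isna()][:5].tolist()
            raise ValueError(f"features without biotype annotation: {missing}")
        bad = set(self.biotype.unique()) - set(VALID_BIOTYPES)
        if bad:
            raise ValueError(f"invalid biotypes {sorted(bad)}; expected {VALID_BIOTYPES}")
        self.sample_group = self.sample_group.reindex(self.values.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()][:5].tolist()
            raise ValueError(f"samples without group annotation: {missing}")
        bad = set(self.sample_group.unique()) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"invalid sample groups {sorted(bad)}; expected {VALID_GROUPS}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be nonnegative (FPKM scale)")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index[self.biotype == "gene"]

    @property
    def lncrna_ids(self) -> pd.Index:
        return self.values.index[self.biotype == "lncRNA"]

    @property
    def tumor_ids(self) -> pd.Index:
        return self.values.columns[self.sample_group == "tumor"]

    @property
    def normal_ids(self) -> pd.Index:
        return self.values.columns[self.sample_group == "normal"]

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(feature_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown feature ids: {missing[:5].tolist()}")
        return ExpressionMatrix(self.values.loc[idx], self.biotype.loc[idx], self.sample_group)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(sample_ids)
        missing = idx.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown sample ids: {missing[:5].tolist()}")
        return ExpressionMatrix(self.values[idx], self.biotype, self.sample_group.loc[idx])


@dataclass
class ZScoreMatrix:
    """Feature x sample matrix of per-row standardized values.

    ``provenance`` records the transform that produced the matrix (source
    scale, pseudocount, ddof, scaling samples) so that downstream outputs can
    be traced back to their normalization.
    """

    values: pd.DataFrame
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the five immune expression signatures).

    ``sets`` maps a set name to a list of member feature ids.  Optional
    ``descriptions`` carry the second GMT field.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # deduplicate silently-stable: keep first occurrence
                seen: set[str] = set()
                self.sets[name] = [m for m in members if not (m in seen or seen.add(m))]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self) -> Iterable[tuple[str, list[str]]]:
        return self.sets.items()
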