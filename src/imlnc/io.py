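"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices travel as TSV with the first column holding the feature
id and the second the biotype; sample groups live in a separate two-column
annotation TSV.  Gene sets use the standard GMT layout (name, description,
then members, tab separated).  Ground-truth bundles from the synthetic
generator are JSON plus TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .matrix import ExpressionMatrix, GeneSetCollection

PathLike = Union[str, Path]


def read_expression(expr_path: PathLike, annotation_path: PathLike) -> ExpressionMatrix:
    """Load an expression matrix TSV plus its sample annotation TSV."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    if "biotype" not in df.columns:
        raise ValueError(f"{expr_path}: expected a 'biotype' column as second field")
    df.index.name = None
    biotype = df["biotype"]
    values = df.drop(columns=["biotype"]).astype(float)
    groups = read_sample_annotation(annotation_path)
    return ExpressionMatrix(values=values, biotype=biotype, sample_group=groups)


def write_expression(matrix: ExpressionMatrix, expr_path: PathLike) -> None:
    out = matrix.values.copy()
    out.insert(0, "biotype", matrix.biotype)
    out.index.name = "feature_id"
    out.to_csv(expr_path, sep="\t")


def read_sample_annotation(path: PathLike) -> pd.Series:
    ann = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(ann.columns):
        raise ValueError(f"{path}: expected columns 'sample_id' and 'group'")
    return ann.set_index("sample_id")["group"]


def write_sample_annotation(groups: pd.Series, path: PathLike) -> None:
    df = groups.rename("group").rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: PathLike) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs >= 3 tab fields: {line[:60]!r}")
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(df: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
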