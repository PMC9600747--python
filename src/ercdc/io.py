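"""Readers and writers for the plain-text formats used throughout the package.

Conventions
-----------
Expression matrices travel as :class:`pandas.DataFrame` objects with gene
identifiers on the index (named ``gene_id``) and sample identifiers as
columns.  All tabular files are tab-separated with a header row and ``.`` as
the decimal mark.  Gene-set collections use GMT semantics: one set per line,
``name <TAB> description <TAB> member1 <TAB> member2 ...``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

GENE_ID = "gene_id"


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != GENE_ID:
        raise ValueError(
            f"expression TSV must have first column named {GENE_ID!r}, "
            f"found {df.columns[0]!r}"
        )
    df = df.set_index(GENE_ID)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df.astype(float)


def write_expression(m: pd.DataFrame, path: str | Path) -> None:
    out = m.copy()
    out.index.name = GENE_ID
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path: str | Path, index_col: str = "sample_id") -> pd.DataFrame:
    """Read a sample/cohort annotation TSV indexed by ``sample_id``."""
    ann = pd.read_csv(path, sep="\t", dtype={index_col: str})
    return ann.set_index(index_col)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a probe->gene map TSV with columns ``probe_id``, ``gene_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", GENE_ID):
        if col not in df.columns:
            raise ValueError(f"probe map must have a {col!r} column")
    if df["probe_id"].duplicated().any():
        raise ValueError("a probe may map to exactly one gene")
    return df.set_index("probe_id")[GENE_ID]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into ``{name: [members...]}``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
            sets[name] = members
    return sets


def read_gmt_with_descriptions(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """As :func:`read_gmt` but keeping the description field (stimulus labels)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, desc, *members = line.split("\t")
            sets[name] = (desc, [m for m in members if m])
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns subject_id, time, event, covariates."""
    tbl = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    tbl = tbl.set_index("subject_id")
    if (tbl["time"] <= 0).any():
        bad = tbl.index[tbl["time"] <= 0].tolist()
        raise ValueError(f"follow-up time must be > 0; offending subjects: {bad[:5]}")
    if not tbl["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return tbl


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
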