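"""Tab-delimited readers and writers for omics matrices, clinical tables,
annotation sets (GMT) and per-subject cluster assignments.

Dialect: UTF-8 TSV, subjects in rows, features in columns. Clinical variable
typing comes from a schema TSV playing the role of a data dictionary: columns
``variable``, ``kind`` (continuous|binary|categorical) and ``roles``
(comma-separated subset of cell_count,filter,test).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationDB,
    ClinicalTable,
    ClinicalVariable,
    FormatError,
    OmicsMatrix,
    SchemaError,
)

logger = logging.getLogger("omsubtype")

MISSING_CODES = ("", "NA", "NaN", "nan", ".")


def read_omics_matrix(path, omic_name: str) -> OmicsMatrix:
    """Read a subjects x features TSV into an OmicsMatrix (all flags false)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    subjects = [str(s) for s in df.index]
    features = [str(f) for f in df.columns]
    for name, ids in (("subject", subjects), ("feature", features)):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dupes):
            raise FormatError(f"duplicate {name} ID in {path}: {dupes[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[int(np.flatnonzero(bad)[0])]
                raise FormatError(
                    f"non-numeric cell in {path} at row {row!r}, column {col!r}"
                ) from None
        raise
    return OmicsMatrix(omic_name, subjects, features, values)


def write_omics_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_schema(path) -> dict:
    """Read the role/kind declarations: variable -> (kind, roles)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variable", "kind", "roles"}
    if not required <= set(df.columns):
        raise SchemaError(f"schema {path} must have columns {sorted(required)}")
    schema = {}
    for _, row in df.iterrows():
        roles = frozenset(
            r.strip() for r in str(row["roles"]).split(",") if r.strip()
        )
        schema[str(row["variable"])] = (str(row["kind"]).strip(), roles)
    return schema


def write_schema(schema: dict, path) -> None:
    pd.DataFrame(
        [
            {"variable": name, "kind": kind, "roles": ",".join(sorted(roles))}
            for name, (kind, roles) in schema.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_clinical_table(path, schema: dict) -> ClinicalTable:
    """Read a clinical TSV, typing columns per the schema.

    Columns absent from the schema are ignored with a warning; the recognised
    missing codes are mapped to NaN for every variable kind.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        na_values=list(MISSING_CODES), keep_default_na=False,
    )
    subjects = [str(s) for s in df.index]
    variables = []
    for col in df.columns:
        if col not in schema:
            logger.warning("clinical column %r absent from schema; ignored", col)
            continue
        kind, roles = schema[col]
        series = df[col]
        if kind == "continuous":
            series = pd.to_numeric(series, errors="raise")
        variables.append(
            ClinicalVariable(str(col), kind, roles, pd.Series(series.values,
                                                             index=subjects))
        )
    return ClinicalTable(subjects, variables)


def write_clinical_table(table: ClinicalTable, path) -> None:
    pd.DataFrame(
        {v.name: v.values.to_numpy() for v in table.variables},
        index=pd.Index(table.subject_ids, name="subject_id"),
    ).to_csv(path, sep="\t")


def read_annotation_sets(path) -> AnnotationDB:
    """Read a GMT-style file: name <tab> description <tab> member IDs...

    A description of the form ``level=N`` assigns a hierarchy level; anything
    else (or a flat GMT) defaults to level 1. Empty categories are skipped,
    repeated names have their members unioned.
    """
    db = AnnotationDB()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            level = 1
            members_start = 1
            if len(parts) > 1:
                desc = parts[1].strip()
                members_start = 2
                if desc.startswith("level="):
                    try:
                        level = int(desc[len("level="):])
                    except ValueError:
                        logger.warning(
                            "%s:%d: unparsable level tag %r; using 1",
                            path, lineno, desc,
                        )
            members = {m.strip() for m in parts[members_start:] if m.strip()}
            if not members:
                logger.warning("%s:%d: empty category %r skipped", path, lineno, name)
                continue
            db.add(name, members, level)
    return db


def write_annotation_sets(db: AnnotationDB, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in db.categories:
            members = "\t".join(sorted(db.categories[name]))
            handle.write(f"{name}\tlevel={db.levels[name]}\t{members}\n")


def write_assignments(subject_ids, omic: str, labels, path) -> None:
    """Per-subject cluster assignment file (label -1 = outlier)."""
    pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "omic": omic,
            "cluster_label": np.asarray(labels, dtype=int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
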