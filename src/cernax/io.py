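"""Readers and writers for the tab-separated interchange formats.

Expression matrix: TSV, header ``feature_id<TAB>sample1<TAB>...``, one
feature per row, token ``NA`` for missing.  Sample annotations: TSV
keyed by ``sample_id``.  Feature biotypes: TSV with ``feature_id`` and
``biotype``.  A dataset collection is described by a YAML/JSON manifest
listing the file triple per dataset.  Numeric TSV output uses 6
significant digits so that write -> read -> write round-trips
bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import BIOTYPES, ContrastSpec, CtRecord, ExpressionDataset, InteractionTable
from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
NUMERIC_FORMAT = "%.6g"


def _fmt(x: float) -> str:
    return MISSING_TOKEN if pd.isna(x) else NUMERIC_FORMAT % x


def read_expression_dataset(matrix_path, annotations_path, biotypes_path,
                            dataset_id: str | None = None) -> ExpressionDataset:
    """Read one dataset from its (matrix, annotations, biotypes) file triple.

    Features without a biotype row default to mRNA (logged); a sample
    present in the matrix but absent from the annotations is an error.
    """
    matrix_path = Path(matrix_path)
    if dataset_id is None:
        dataset_id = matrix_path.stem

    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "feature_id":
        raise ParseError(
            f"{matrix_path}:1: expected header starting with 'feature_id', got {header[:1]!r}"
        )
    if len(header) < 2:
        raise ParseError(f"{matrix_path}:1: no sample columns in header")
    if len(set(header[1:])) != len(header) - 1:
        raise ParseError(f"{matrix_path}:1: duplicate sample_id in header")

    try:
        values = pd.read_csv(
            matrix_path, sep="\t", index_col=0, na_values=[MISSING_TOKEN],
            keep_default_na=False, dtype=str,
        )
        values = values.apply(pd.to_numeric, errors="raise")
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric expression cell ({exc})") from exc
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dups = sorted(values.index[values.index.duplicated()].unique())
        raise ValidationError(f"{matrix_path}: duplicate feature_id(s): {', '.join(dups)}")

    annotations = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if "sample_id" not in annotations.columns:
        raise ParseError(f"{annotations_path}: missing 'sample_id' column")
    annotations = annotations.set_index("sample_id")

    biotypes_df = pd.read_csv(biotypes_path, sep="\t", dtype=str)
    for col in ("feature_id", "biotype"):
        if col not in biotypes_df.columns:
            raise ParseError(f"{biotypes_path}: missing {col!r} column")
    biotypes = biotypes_df.set_index("feature_id")["biotype"]
    bad = set(biotypes.unique()) - set(BIOTYPES)
    if bad:
        raise ParseError(f"{biotypes_path}: unknown biotype(s): {', '.join(sorted(bad))}")
    unlabelled = [f for f in values.index if f not in biotypes.index]
    if unlabelled:
        log.info("%s: %d feature(s) without biotype row default to mRNA: %s",
                 dataset_id, len(unlabelled), ", ".join(unlabelled[:5]))
        biotypes = pd.concat([biotypes, pd.Series("mRNA", index=unlabelled)])
    biotypes = biotypes.reindex(values.index)

    return ExpressionDataset(
        dataset_id=dataset_id,
        values=values,
        sample_annotations=annotations,
        feature_biotypes=biotypes,
    )


def write_expression_dataset(ds: ExpressionDataset, matrix_path, annotations_path,
                             biotypes_path) -> None:
    """Write the dataset as the TSV triple read by read_expression_dataset."""
    with open(matrix_path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, ds.values.columns)) + "\n")
        for fid, row in ds.values.iterrows():
            fh.write(str(fid) + "\t" + "\t".join(_fmt(v) for v in row.to_numpy()) + "\n")
    ds.sample_annotations.reset_index().rename(
        columns={ds.sample_annotations.index.name or "index": "sample_id"}
    ).to_csv(annotations_path, sep="\t", index=False)
    pd.DataFrame({
        "feature_id": ds.feature_biotypes.index,
        "biotype": ds.feature_biotypes.to_numpy(),
    }).to_csv(biotypes_path, sep="\t", index=False)


def read_manifest(path) -> list[ExpressionDataset]:
    """Read a dataset-collection manifest (YAML or JSON).

    The manifest maps ``datasets`` to a list of entries with keys
    ``dataset_id``, ``matrix``, ``annotations``, ``biotypes``; relative
    paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise ParseError(f"{path}: manifest must contain a 'datasets' list")
    out = []
    for entry in doc["datasets"]:
        for key in ("dataset_id", "matrix", "annotations", "biotypes"):
            if key not in entry:
                raise ParseError(f"{path}: manifest entry missing {key!r}")
        files = {k: path.parent / entry[k] for k in ("matrix", "annotations", "biotypes")}
        for k, f in files.items():
            if not f.exists():
                raise ParseError(f"{path}: {entry['dataset_id']}: missing {k} file {f}")
        out.append(read_expression_dataset(
            files["matrix"], files["annotations"], files["biotypes"],
            dataset_id=entry["dataset_id"],
        ))
    return out


def read_contrasts(path) -> list[ContrastSpec]:
    """Read severity contrasts from YAML: a list of mappings with keys
    clinical_feature, severe_levels, mild_levels, optional label."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["contrasts"] if isinstance(doc, dict) else doc
    out = []
    for e in entries:
        out.append(ContrastSpec(
            clinical_feature=e["clinical_feature"],
            severe_levels=frozenset(map(str, e["severe_levels"])),
            mild_levels=frozenset(map(str, e["mild_levels"])),
            label=e.get("label", ""),
        ))
    return out


_INTERACTION_COLUMNS = {
    "lncrna_mirna_binding": ("lncrna_id", "mirna_id"),
    "mirna_mrna_validated": ("mirna_id", "mrna_id"),
    "mirna_cancer": ("mirna_id", "disease"),
}


def read_interaction_table(path, kind: str) -> InteractionTable:
    """Read an interaction-evidence TSV of the given kind.

    Column names per kind: binding (lncrna_id, mirna_id, source_db),
    validated targets (mirna_id, mrna_id, source_db), cancer
    annotations (mirna_id, disease, direction, source_db).
    """
    if kind not in _INTERACTION_COLUMNS:
        raise ValueError(f"unknown interaction-table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    a_col, b_col = _INTERACTION_COLUMNS[kind]
    for col in (a_col, b_col, "source_db"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    rows = pd.DataFrame({
        "id_a": df[a_col].str.strip(),
        "id_b": df[b_col].str.strip(),
        "source_db": df["source_db"].str.strip(),
        "annotation": df["direction"].str.strip() if "direction" in df.columns else "",
    })
    rows = rows.drop_duplicates(subset=["id_a", "id_b", "source_db"]).reset_index(drop=True)
    return InteractionTable(kind=kind, rows=rows)


def write_interaction_table(table: InteractionTable, path) -> None:
    a_col, b_col = _INTERACTION_COLUMNS[table.kind]
    df = table.rows.rename(columns={"id_a": a_col, "id_b": b_col})
    if table.kind == "mirna_cancer":
        df = df.rename(columns={"annotation": "direction"})
        df = df[[a_col, b_col, "direction", "source_db"]]
    else:
        df = df[[a_col, b_col, "source_db"]]
    df.to_csv(path, sep="\t", index=False)


def read_ct_records(path) -> list[CtRecord]:
    """Read a qPCR Ct table (CSV: sample_id, group, target_id, ct,
    replicate, optional pair_id)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "target_id": str})
    for col in ("sample_id", "group", "target_id", "ct"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        pair = row.get("pair_id")
        records.append(CtRecord(
            sample_id=str(row["sample_id"]),
            group_label=str(row["group"]),
            target_id=str(row["target_id"]),
            ct=float(row["ct"]),
            replicate_index=int(row.get("replicate", 0) or 0),
            pair_id=None if pd.isna(pair) else str(pair),
        ))
    seen = set()
    for rec in records:
        key = (rec.sample_id, rec.target_id, rec.replicate_index)
        if key in seen:
            raise ValidationError(f"{path}: duplicate Ct record {key}")
        seen.add(key)
    return records


def write_ct_records(records: list[CtRecord], path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id,
        "group": r.group_label,
        "target_id": r.target_id,
        "ct": NUMERIC_FORMAT % r.ct,
        "replicate": r.replicate_index,
        "pair_id": "" if r.pair_id is None else r.pair_id,
    } for r in records]).to_csv(path, index=False)
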