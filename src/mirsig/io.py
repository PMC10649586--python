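"""Tab-separated input/output for the pipeline's data model.

Formats
-------
expression TSV
    First column ``mirna_id``, one column per sample, log2 intensities.
groups TSV
    Columns ``sample_id`` and ``group``.
Cq TSV
    Long format: ``sample_id``, ``mirna_id``, ``replicate``, ``cq``.
probe list
    Plain text, one miRNA id per line; ``#`` comments and blanks ignored.
GEO series matrix (minimal)
    Only the tab-delimited block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; header metadata lines are ignored
    apart from ``!Sample_geo_accession`` (used to label columns when present
    in the table header).  Full SOFT parsing is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import CqTable, ExpressionMatrix


def read_expression_tsv(path: str | Path, groups: pd.Series) -> ExpressionMatrix:
    """Read an expression TSV and attach group labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "mirna_id"
    return ExpressionMatrix(df, groups)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, sep="\t")


def read_groups_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: groups file must have a '{col}' column")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample ids in groups file: {dup}")
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_groups_tsv(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_cq_tsv(path: str | Path) -> CqTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CqTable.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: Cq file missing columns: {missing}")
    bad = df[pd.to_numeric(df["cq"], errors="coerce").isna()]
    if not bad.empty:
        # +2: header line plus 1-based numbering
        lines = (bad.index + 2).tolist()
        raise ValueError(f"{path}: non-numeric Cq values at lines {lines}")
    df["cq"] = df["cq"].astype(float)
    return CqTable(df)


def write_cq_tsv(cq: CqTable, path: str | Path) -> None:
    cq.data.to_csv(path, sep="\t", index=False)


def read_probe_list(path: str | Path) -> set[str]:
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.add(entry)
    return ids


def write_probe_list(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def write_ground_truth_json(study, path: str | Path) -> None:
    payload = {
        "seed": study.seed,
        "effects": study.effects,
        "normalizer_ids": study.normalizer_ids,
        "sample_offsets": study.sample_offsets.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the expression table of a GEO series-matrix file.

    Returns a DataFrame indexed by probe/miRNA id with one column per sample
    (GSM accessions when the header provides them).  Values outside the
    ``!series_matrix_table_begin`` ... ``!series_matrix_table_end`` block are
    ignored; quoted fields are unquoted.
    """
    lines = Path(path).read_text().splitlines()
    try:
        begin = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
    except StopIteration:
        raise ValueError(f"{path}: no !series_matrix_table_begin marker") from None
    try:
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path}: no !series_matrix_table_end marker") from None
    block = lines[begin + 1 : end]
    if not block:
        raise ValueError(f"{path}: empty series-matrix table")

    def split(line: str) -> list[str]:
        return [f.strip().strip('"') for f in line.split("\t")]

    header = split(block[0])
    rows = []
    for offset, line in enumerate(block[1:], start=begin + 3):
        fields = split(line)
        if len(fields) != len(header):
            raise ValueError(
                f"{path}: line {offset}: expected {len(header)} fields, got {len(fields)}"
            )
        rows.append(fields)
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "mirna_id"
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate probe ids: {dup}")
    return df.astype(float)
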