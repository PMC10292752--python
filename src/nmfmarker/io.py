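"""Readers and writers for the tabular interchange formats.

All inputs are plain delimited text: the expression matrix (genes as rows,
header row of sample ids), a two-column sample/group label table, a one-id-
per-line gene list, and a differential-expression table with gene, log2
fold-change and adjusted-p columns.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import pandas as pd

from .matrix import ExpressionMatrix, normalize_gene_id

DISEASE = "disease"
NORMAL = "normal"


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_expression_matrix(
    path: str | Path, scale_tag: str = "tpm", delimiter: str | None = None
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample matrix.

    First column holds gene ids, the header row holds sample ids.  The
    delimiter is auto-detected between tab and comma unless given explicitly.
    Negative, missing or non-numeric entries raise ``ValueError``.
    """
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    return ExpressionMatrix(frame, scale_tag=scale_tag)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    m.data.to_csv(path, sep=delimiter, index_label="gene")


def read_sample_labels(
    path: str | Path,
    disease_name: str = "glaucoma",
    normal_name: str = "normal",
    delimiter: str | None = None,
) -> dict[str, str]:
    """Read a two-column (sample_id, group) table into a label mapping.

    Group names are mapped onto the canonical ``disease`` / ``normal``
    values; any other group name raises ``ValueError``.
    """
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns (sample_id, group)")
    first = frame.iloc[0]
    header_words = {"group", "label", "condition", "phenotype"}
    if (str(first[0]).strip().lower() in {"sample", "sample_id", "id"}
            or str(first[1]).strip().lower() in header_words):
        frame = frame.iloc[1:]  # tolerate a header row
    labels: dict[str, str] = {}
    for _, row in frame.iterrows():
        sample, group = str(row[0]).strip(), str(row[1]).strip()
        if group in (disease_name, DISEASE):
            labels[sample] = DISEASE
        elif group in (normal_name, NORMAL):
            labels[sample] = NORMAL
        else:
            raise ValueError(
                f"unknown group {group!r} for sample {sample!r} "
                f"(expected {disease_name!r} or {normal_name!r})"
            )
    if not labels:
        raise ValueError(f"no labels found in {path}")
    return labels


def check_labels(labels: Mapping[str, str], m: ExpressionMatrix) -> None:
    """Validate a label mapping against a matrix (spec: every labeled sample
    exists; at least one sample per group)."""
    samples = set(m.sample_ids)
    unknown = [s for s in labels if s not in samples]
    if unknown:
        raise ValueError(f"labeled samples not in matrix: {unknown[:10]}")
    groups = set(labels.values())
    if not {DISEASE, NORMAL} <= groups:
        raise ValueError(f"need at least one sample per group, got groups {groups}")


def write_sample_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one id per line, ``#`` comments allowed).

    Ids are normalized (trimmed, case-folded) and de-duplicated preserving
    first-occurrence order.
    """
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            norm = normalize_gene_id(line)
            if norm not in seen:
                seen.add(norm)
                out.append(line)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_de_table(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "logFC",
    p_col: str = "adj_p",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a differential-expression table into canonical columns.

    Returns a DataFrame with columns ``gene``, ``logFC``, ``adj_p``; gene ids
    must be unique and adjusted p-values must lie in [0, 1].
    """
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep)
    for col in (gene_col, lfc_col, p_col):
        if col not in frame.columns:
            raise ValueError(f"DE table {path} lacks column {col!r}; has {list(frame.columns)}")
    out = frame[[gene_col, lfc_col, p_col]].rename(
        columns={gene_col: "gene", lfc_col: "logFC", p_col: "adj_p"}
    )
    out["gene"] = out["gene"].astype(str)
    if out["gene"].duplicated().any():
        dupes = out.loc[out["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate genes in DE table: {dupes[:10]}")
    if ((out["adj_p"] < 0) | (out["adj_p"] > 1)).any():
        raise ValueError("adjusted p-values outside [0, 1]")
    return out
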