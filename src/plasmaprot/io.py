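"""Readers and writers for the pipeline's tab-separated formats.

The protein-group reader understands a MaxQuant-``proteinGroups``-like layout:
columns "Protein IDs", "Gene names", the artifact flag columns "Reverse",
"Only identified by site", "Potential contaminant" (a "+" marks the flag), and
one "LFQ intensity <sample>" column per sample. Zero or blank intensity cells
parse to missing. All text I/O is UTF-8, tab-separated, decimal point only.
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import pandas as pd

from .tables import ClinicalTable, ProteinGroupTable, SampleSheet, ValidationError

__all__ = [
    "read_protein_groups",
    "read_sample_sheet",
    "read_clinical",
    "read_tissue_expression",
    "write_table",
    "FormatError",
    "ParseError",
]

DEFAULT_INTENSITY_PREFIX = "LFQ intensity "
ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
FLAG_COLUMNS = {
    "Reverse": "flag_reverse",
    "Potential contaminant": "flag_contaminant",
    "Only identified by site": "flag_site_only",
}


class FormatError(ValueError):
    """The file does not have the expected layout."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


def _split_semicolon(cell: Any) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(s for s in str(cell).split(";") if s)


def read_protein_groups(
    path: str | os.PathLike,
    intensity_prefix: str = DEFAULT_INTENSITY_PREFIX,
    id_column: str = ID_COLUMN,
    gene_column: str = GENE_COLUMN,
) -> ProteinGroupTable:
    """Parse a protein-group quantification TSV.

    "+" in a flag column sets the corresponding boolean; semicolon-separated
    IDs and gene names are split into lists (first gene is the display name);
    0 or blank intensities become missing.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if id_column not in raw.columns:
        raise FormatError(f"missing ID column {id_column!r}")
    int_cols = [c for c in raw.columns if c.startswith(intensity_prefix)]
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r} found"
        )

    group_ids = raw[id_column].astype(str)
    if group_ids.duplicated().any():
        dups = group_ids[group_ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate group_id values: {dups[:5]}")

    meta = pd.DataFrame(index=pd.Index(group_ids, name="group_id"))
    meta["protein_ids"] = [_split_semicolon(v) for v in raw[id_column]]
    genes = (
        [_split_semicolon(v) for v in raw[gene_column]]
        if gene_column in raw.columns
        else [() for _ in range(len(raw))]
    )
    meta["gene_names"] = genes
    meta["gene"] = [g[0] if g else "" for g in genes]
    for col, attr in FLAG_COLUMNS.items():
        meta[attr] = (
            raw[col].str.strip().eq("+").to_numpy()
            if col in raw.columns
            else np.zeros(len(raw), dtype=bool)
        )

    intensities = pd.DataFrame(index=meta.index)
    for col in int_cols:
        sample = col[len(intensity_prefix):]
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "" or cell == "0":
                parsed[i] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric intensity {cell!r} at row {i} "
                    f"(group {group_ids.iloc[i]!r}), column {col!r}"
                ) from None
            if v == 0:
                parsed[i] = np.nan
            elif v < 0 or not np.isfinite(v):
                raise ParseError(
                    f"invalid intensity {cell!r} at row {i}, column {col!r}: "
                    "intensities must be positive"
                )
            else:
                parsed[i] = v
        intensities[sample] = parsed

    return ProteinGroupTable(meta=meta, intensities=intensities)


def read_sample_sheet(
    path: str | os.PathLike, allowed_groups: list[str] | None = None
) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SampleSheet.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet lacks columns {missing}")
    try:
        df["replicate_index"] = df["replicate_index"].astype(int)
    except ValueError as e:
        raise ParseError(f"non-integer replicate_index: {e}") from None
    if "acquisition_order" in df.columns:
        df["acquisition_order"] = pd.to_numeric(df["acquisition_order"], errors="coerce")
    sheet = SampleSheet(df)
    if allowed_groups is not None:
        unknown = set(sheet.groups) - set(allowed_groups)
        if unknown:
            raise ValidationError(f"undeclared group labels: {sorted(unknown)}")
    return sheet


def read_clinical(path: str | os.PathLike) -> ClinicalTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    first = raw.columns[0]
    if raw[first].duplicated().any():
        dups = raw[first][raw[first].duplicated()].unique().tolist()
        raise ValidationError(f"duplicate subject_id values: {dups[:5]}")
    out = pd.DataFrame(index=pd.Index(raw[first], name="subject_id"))
    for col in raw.columns[1:]:
        parsed = np.empty(len(raw), dtype=float)
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell == "":
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} for subject "
                    f"{raw[first].iloc[i]!r}, variable {col!r}"
                ) from None
        out[col] = parsed
    return ClinicalTable(out)


def read_tissue_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x tissue table of nonnegative expression levels (TPM-like)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if np.any(np.nan_to_num(vals, nan=0.0) < 0):
        raise ValidationError("tissue expression values must be nonnegative")
    return df


def write_table(result: Any, path: str | os.PathLike, float_digits: int = 6) -> None:
    """Write a pipeline result as TSV with a stable column order.

    Accepts a plain DataFrame or any result object exposing ``to_frame()``
    (DiffResult, AnovaResult, QCReport, CorrMap, ...). Numeric fields are
    printed with ``float_digits`` significant digits; categorical fields
    round-trip exactly through the matching reader.
    """
    if hasattr(result, "to_frame"):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    elif isinstance(result, pd.Series):
        df = result.to_frame()
    else:
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    df.to_csv(path, sep="\t", float_format=f"%.{float_digits}g")


def read_result_table(path: str | os.PathLike, index_col: int = 0) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col)
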