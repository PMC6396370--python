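"""Domain tables: protein-group quantification, sample sheet, clinical variables.

The protein-group table mirrors the layout of a MaxQuant ``proteinGroups``
export: one row per protein group (a set of accessions indistinguishable by
their observed peptides), artifact flags, and one linear LFQ-intensity column
per sample where zero or blank encodes "not quantified".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinGroupTable",
    "SampleSheet",
    "ClinicalTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


META_COLUMNS = [
    "protein_ids",
    "gene_names",
    "gene",
    "flag_reverse",
    "flag_contaminant",
    "flag_site_only",
]


@dataclass
class ProteinGroupTable:
    """Protein groups with per-sample linear LFQ intensities.

    Attributes
    ----------
    meta : pd.DataFrame
        Indexed by unique ``group_id``; columns ``protein_ids`` (tuple of
        accessions), ``gene_names`` (tuple of symbols; first is the display
        name), ``gene`` (display name), and the three artifact flags.
    intensities : pd.DataFrame
        Indexed like ``meta``; one float column per sample. Values are
        strictly positive; missing is ``NaN``.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.meta.index.is_unique:
            dups = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate group_id values: {dups[:5]}")
        if not self.meta.index.equals(self.intensities.index):
            raise ValidationError("meta and intensities indices differ")
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValidationError(f"meta lacks columns {missing_cols}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.any(np.nan_to_num(vals, nan=1.0) <= 0):
            raise ValidationError("intensities must be strictly positive or missing")

    @property
    def group_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    def subset(self, keep: pd.Index | list[str]) -> "ProteinGroupTable":
        return ProteinGroupTable(self.meta.loc[keep].copy(), self.intensities.loc[keep].copy())

    def gene_index(self) -> pd.Series:
        """Display gene per group_id (first semicolon-separated entry)."""
        return self.meta["gene"]


@dataclass
class SampleSheet:
    """Maps samples to subjects, experimental groups and technical replicates."""

    df: pd.DataFrame  # columns: sample_id, subject_id, group, replicate_index[, acquisition_order]

    REQUIRED = ("sample_id", "subject_id", "group", "replicate_index")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample sheet lacks columns {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        for subj, sub in self.df.groupby("subject_id", sort=False):
            if sub["group"].nunique() > 1:
                raise ValidationError(
                    f"subject {subj!r} assigned to multiple groups: "
                    f"{sorted(sub['group'].unique())}"
                )
            reps = sub["replicate_index"].astype(int)
            if reps.duplicated().any():
                raise ValidationError(f"subject {subj!r} has duplicate replicate_index")
            if reps.min() < 1:
                raise ValidationError(f"subject {subj!r} has replicate_index < 1")

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def subjects(self) -> list[str]:
        return self.df["subject_id"].drop_duplicates().tolist()

    @property
    def groups(self) -> list[str]:
        return self.df["group"].drop_duplicates().tolist()

    def subject_group(self) -> pd.Series:
        """subject_id -> group label."""
        return self.df.drop_duplicates("subject_id").set_index("subject_id")["group"]

    def replicates_of(self, subject_id: str) -> list[str]:
        sub = self.df[self.df["subject_id"] == subject_id]
        return sub.sort_values("replicate_index")["sample_id"].tolist()

    def sample_subject(self) -> pd.Series:
        """sample_id -> subject_id."""
        return self.df.set_index("sample_id")["subject_id"]


@dataclass
class ClinicalTable:
    """Per-subject numeric clinical variables (ALT, AST, BMI, ...)."""

    df: pd.DataFrame  # indexed by subject_id, numeric columns, NaN = missing

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.df.index.is_unique:
            raise ValidationError("duplicate subject_id in clinical table")
        if self.df.columns.duplicated().any():
            raise ValidationError("duplicate variable name in clinical table")
        vals = self.df.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("clinical values must be finite where present")

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.df.index)


def check_samples_covered(table: ProteinGroupTable, sheet: SampleSheet) -> None:
    """Every intensity column must appear in the sample sheet."""
    extra = set(table.samples) - set(sheet.sample_ids)
    if extra:
        raise ValidationError(
            f"intensity columns not in sample sheet: {sorted(extra)[:5]}"
        )
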