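"""From parsed protein groups to analysis-ready matrices.

The main branch runs: artifact-flag filtering, replicate-validity filtering
(>=2 valid values within at least one subject's technical replicates), median
aggregation over technical replicates, group-completeness filtering (70% in at
least one experimental group), log2 transform, and downshifted-Gaussian
imputation of the remaining missing values. The correlation branch instead
filters for 70% completeness over all subjects and performs no imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix, ScaleError
from .tables import ProteinGroupTable, SampleSheet, ValidationError

__all__ = [
    "filter_flags",
    "filter_replicate_validity",
    "aggregate_replicates",
    "filter_completeness",
    "log2_transform",
    "impute_downshift",
    "zscore_rows",
]


def filter_flags(table: ProteinGroupTable) -> tuple[ProteinGroupTable, dict[str, int]]:
    """Drop reverse-decoy, contaminant and only-identified-by-site groups.

    Returns the filtered table and per-flag removal counts (a row carrying
    several flags counts under each).
    """
    m = table.meta
    counts = {
        "reverse": int(m["flag_reverse"].sum()),
        "contaminant": int(m["flag_contaminant"].sum()),
        "site_only": int(m["flag_site_only"].sum()),
    }
    keep = ~(m["flag_reverse"] | m["flag_contaminant"] | m["flag_site_only"])
    return table.subset(m.index[keep]), counts


def filter_replicate_validity(
    table: ProteinGroupTable, sheet: SampleSheet, min_valid: int = 2
) -> ProteinGroupTable:
    """Keep a protein iff >=1 subject has >= min_valid quantified replicates."""
    max_reps = max(
        len(sheet.replicates_of(s)) for s in sheet.subjects
    )
    if min_valid > max_reps:
        raise ValidationError(
            f"min_valid={min_valid} exceeds the replicate count ({max_reps}) "
            "of every subject"
        )
    keep = np.zeros(table.n_proteins, dtype=bool)
    for subject in sheet.subjects:
        cols = [c for c in sheet.replicates_of(subject) if c in table.intensities.columns]
        if not cols:
            continue
        n_valid = table.intensities[cols].notna().sum(axis=1)
        keep |= (n_valid >= min_valid).to_numpy()
    return table.subset(table.meta.index[keep])


def aggregate_replicates(
    table: ProteinGroupTable, sheet: SampleSheet, method: str = "median"
) -> IntensityMatrix:
    """Collapse technical replicates to one value per subject.

    The per-subject value is the median (or mean) of the quantified replicate
    intensities; a subject with no quantified replicate stays missing.
    """
    if method not in ("median", "mean"):
        raise ValidationError(f"unknown aggregation method {method!r}")
    agg = {}
    for subject in sheet.subjects:
        cols = [c for c in sheet.replicates_of(subject) if c in table.intensities.columns]
        block = table.intensities[cols]
        agg[subject] = block.median(axis=1) if method == "median" else block.mean(axis=1)
    values = pd.DataFrame(agg)
    return IntensityMatrix(
        values=values,
        genes=table.gene_index(),
        scale="linear",
        provenance=[{"op": "aggregate_replicates", "method": method}],
    )


def filter_completeness(
    matrix: IntensityMatrix,
    groups: pd.Series | dict | None = None,
    frac: float = 0.70,
    mode: str = "any_group",
) -> IntensityMatrix:
    """Keep proteins quantified in >= frac of columns (ties pass).

    mode="any_group": the fraction must be reached within at least one
    experimental group; mode="overall": over all columns.
    """
    if mode not in ("any_group", "overall"):
        raise ValidationError(f"unknown completeness mode {mode!r}")
    valid = matrix.values.notna()
    if mode == "overall":
        keep = valid.mean(axis=1) >= frac
    else:
        if groups is None:
            raise ValidationError("any_group mode requires a column->group mapping")
        groups = pd.Series(groups)
        unassigned = [c for c in matrix.columns if c not in groups.index]
        if unassigned:
            raise ValidationError(f"columns without group assignment: {unassigned[:5]}")
        keep = pd.Series(False, index=matrix.values.index)
        for _, cols in groups.loc[matrix.columns].groupby(groups.loc[matrix.columns]):
            keep |= valid[list(cols.index)].mean(axis=1) >= frac
    return matrix.derive(
        matrix.values.loc[keep].copy(), op="filter_completeness", frac=frac, mode=mode
    )


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    matrix.require_scale("linear", "log2_transform")
    return matrix.derive(np.log2(matrix.values), op="log2_transform", scale="log2")


def impute_downshift(
    matrix: IntensityMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    scope: str = "per_column",
    seed: int | None = None,
) -> IntensityMatrix:
    """Replace missing values with draws from a downshifted Normal.

    For each scope unit (each column by default, or the whole matrix), the
    observed log2 values give mean mu and SD sigma; missing cells are drawn
    from Normal(mu - shift*sigma, (width*sigma)^2), modeling the
    missing-not-at-random dropout of low-abundance proteins. Observed cells
    are untouched. Draws consume the seeded generator in column-major order
    over missing cells, so identical seeds give identical output.
    """
    matrix.require_scale("log2", "impute_downshift")
    if scope not in ("per_column", "global"):
        raise ValidationError(f"unknown imputation scope {scope!r}")
    values = matrix.values.copy()
    rng = np.random.default_rng(seed)
    arr = values.to_numpy(dtype=float)
    if not np.isnan(arr).any():
        return matrix.derive(values, op="impute_downshift", shift=shift,
                             width=width, scope=scope, seed=seed, n_imputed=0)
    if scope == "global":
        obs = arr[~np.isnan(arr)]
        if obs.size < 3:
            raise ValidationError("fewer than 3 observed values in the matrix")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
    n_imputed = 0
    for j in range(arr.shape[1]):
        col = arr[:, j]
        miss = np.isnan(col)
        if scope == "per_column":
            obs = col[~miss]
            if obs.size < 3:
                raise ValidationError(
                    f"column {values.columns[j]!r} has fewer than 3 observed "
                    "values; SD is unstable"
                )
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        if miss.any():
            col[miss] = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
            n_imputed += int(miss.sum())
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return matrix.derive(out, op="impute_downshift", shift=shift, width=width,
                         scope=scope, seed=seed, n_imputed=n_imputed)


def zscore_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Standardize each protein row to mean 0, SD 1 (n-1 denominator)."""
    if matrix.values.isna().any().any():
        raise ValidationError("zscore_rows requires a complete (imputed) matrix")
    if matrix.values.shape[1] < 2:
        raise ValidationError("zscore_rows requires >=2 columns")
    sd = matrix.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = matrix.values.index[sd == 0].tolist()
        raise ValidationError(f"constant rows cannot be z-scored: {bad[:5]}")
    z = matrix.values.sub(matrix.values.mean(axis=1), axis=0).div(sd, axis=0)
    return matrix.derive(z, op="zscore_rows", scale="unitless")
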