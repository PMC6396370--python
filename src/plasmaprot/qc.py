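"""Study-quality diagnostics for plasma proteome cohorts.

Covers the four standard panels: proteins quantified per sample, dynamic range
of protein abundances, contamination marker-panel indices (erythrocyte lysis
via hemoglobin subunits, coagulation via fibrinogen chains), and technical
precision as per-protein replicate CVs with threshold counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .tables import ProteinGroupTable, SampleSheet, ValidationError

__all__ = [
    "DEFAULT_PANELS",
    "QCReport",
    "panel_index",
    "replicate_cv",
    "quantified_per_sample",
    "dynamic_range",
    "run_qc",
]

# Plasma contamination quality panels: hemoglobin subunits mark erythrocyte
# lysis, fibrinogen chains mark incomplete or delayed coagulation handling.
DEFAULT_PANELS: dict[str, list[str]] = {
    "erythrocyte": ["HBA1", "HBB", "HBD"],
    "coagulation": ["FGA", "FGB", "FGG"],
}

# HBA is the conventional shorthand for the alpha subunits.
_SYMBOL_EXPANSIONS = {"HBA": ["HBA1", "HBA2"]}

DEFAULT_CV_THRESHOLDS = (0.10, 0.20, 0.30)

MAD_TO_SD = 1.4826  # consistency factor for a Normal distribution


@dataclass
class QCReport:
    per_sample: pd.DataFrame  # n_quantified + one index/outlier column per panel
    per_protein: pd.DataFrame  # median_cv per group_id
    cv_threshold_counts: dict[float, int]
    dynamic_range_orders: float
    mean_quantified: float

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample

    def summary(self) -> dict:
        return {
            "mean_quantified_per_sample": self.mean_quantified,
            "dynamic_range_orders": self.dynamic_range_orders,
            **{f"cv_below_{int(t * 100)}pct": c for t, c in self.cv_threshold_counts.items()},
        }


def _expand_panel(panel: list[str]) -> list[str]:
    out: list[str] = []
    for g in panel:
        out.extend(_SYMBOL_EXPANSIONS.get(g.upper(), [g]))
    return out


def panel_index(
    matrix: IntensityMatrix, panel: list[str], one_sided: bool = True
) -> pd.DataFrame:
    """Per-sample contamination index for a marker panel.

    Each panel protein's log2 intensities are centered by that protein's
    cohort median; the sample index is the median of the centered panel
    values, so 0 means a typical sample. A sample is an outlier if its index
    exceeds the cohort median index by more than 3 robust SDs (1.4826*MAD);
    one-sided by default since only contamination excess is of concern.
    """
    matrix.require_scale("log2", "panel_index")
    wanted = [g.upper() for g in _expand_panel(panel)]
    gene_upper = matrix.genes.fillna("").str.upper()
    rows = matrix.values.index[gene_upper.isin(wanted)]
    if len(rows) == 0:
        raise ValidationError(f"no panel genes found in matrix: {sorted(set(wanted))}")
    block = matrix.values.loc[rows]
    centered = block.sub(block.median(axis=1), axis=0)
    index = centered.median(axis=0)
    med = index.median()
    mad = (index - med).abs().median()
    robust_sd = MAD_TO_SD * mad
    if robust_sd == 0:
        outlier = pd.Series(False, index=index.index)
    else:
        dev = index - med
        outlier = dev > 3 * robust_sd
        if not one_sided:
            outlier |= dev < -3 * robust_sd
    return pd.DataFrame({"index": index, "outlier": outlier})


def replicate_cv(
    table: ProteinGroupTable,
    sheet: SampleSheet,
    thresholds: tuple[float, ...] = DEFAULT_CV_THRESHOLDS,
) -> tuple[pd.Series, dict[float, int]]:
    """Per-protein median technical CV and counts below each threshold.

    CV = SD/mean (n-1 denominator, linear intensities) over each subject's
    quantified replicates (needs >=2); the per-protein value is the median
    over subjects. Counts are proteins with median CV strictly below the
    threshold.
    """
    per_subject = {}
    for subject in sheet.subjects:
        cols = [c for c in sheet.replicates_of(subject) if c in table.intensities.columns]
        if len(cols) < 2:
            continue
        block = table.intensities[cols]
        n_valid = block.notna().sum(axis=1)
        cv = block.std(axis=1, ddof=1) / block.mean(axis=1)
        cv[n_valid < 2] = np.nan
        per_subject[subject] = cv
    if not per_subject:
        warnings.warn("no subject with >=2 replicates; CV report is empty")
        empty = pd.Series(dtype=float, name="median_cv")
        return empty, {t: 0 for t in thresholds}
    cv_df = pd.DataFrame(per_subject)
    median_cv = cv_df.median(axis=1)
    median_cv.name = "median_cv"
    counts = {t: int((median_cv < t).sum()) for t in sorted(thresholds)}
    return median_cv, counts


def quantified_per_sample(table: ProteinGroupTable) -> pd.Series:
    """Number of quantified (non-missing) proteins per sample."""
    counts = table.intensities.notna().sum(axis=0)
    counts.name = "n_quantified"
    return counts


def dynamic_range(matrix: IntensityMatrix) -> float:
    """Orders of magnitude spanned by per-protein median abundances."""
    matrix.require_scale("linear", "dynamic_range")
    medians = matrix.values.median(axis=1).dropna()
    if len(medians) < 2:
        raise ValidationError("dynamic_range needs >=2 proteins with a median")
    return float(np.log10(medians.max() / medians.min()))


def run_qc(
    table: ProteinGroupTable,
    sheet: SampleSheet,
    panels: dict[str, list[str]] | None = None,
    cv_thresholds: tuple[float, ...] = DEFAULT_CV_THRESHOLDS,
) -> QCReport:
    """Full QC report on the raw (unfiltered, linear) protein-group table."""
    panels = DEFAULT_PANELS if panels is None else panels
    counts = quantified_per_sample(table)
    per_sample = counts.to_frame()

    log2_matrix = IntensityMatrix(
        values=np.log2(table.intensities),
        genes=table.gene_index(),
        scale="log2",
        provenance=[{"op": "log2_transform"}],
    )
    for name, genes in panels.items():
        res = panel_index(log2_matrix, genes)
        per_sample[f"{name}_index"] = res["index"]
        per_sample[f"{name}_outlier"] = res["outlier"]

    median_cv, cv_counts = replicate_cv(table, sheet, cv_thresholds)
    linear = IntensityMatrix(
        values=table.intensities, genes=table.gene_index(), scale="linear"
    )
    return QCReport(
        per_sample=per_sample,
        per_protein=median_cv.to_frame(),
        cv_threshold_counts=cv_counts,
        dynamic_range_orders=dynamic_range(linear),
        mean_quantified=float(counts.mean()),
    )
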