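"""End-to-end orchestration: simulate/ingest -> QC -> preprocess ->
differential contrasts + ANOVA screen -> correlation map -> annotation.

The main branch runs flag filtering, replicate-validity filtering, triplicate
median aggregation, any-group completeness filtering, log2 transform and
downshifted imputation before testing. The correlation branch forks from the
pre-imputation log2 matrix with overall completeness filtering and no
imputation. Every stage writes a TSV, the run log records protein counts
after each filter, and a provenance record captures parameters, seeds and
input checksums so any number in the report is reproducible from config +
seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import differential as da
from . import io as pio
from . import preprocess as pp
from . import qc as pqc
from . import simulate as sim
from .config import RunConfig
from .correlation import anchor_cluster, build_corr_map, cluster_map
from .matrix import IntensityMatrix
from .tables import ClinicalTable, ProteinGroupTable, SampleSheet, check_samples_covered
from .tissue import classify_specificity, specificity_summary

logger = logging.getLogger("plasmaprot")

__all__ = ["ReportBundle", "run_pipeline"]


@dataclass
class ReportBundle:
    outdir: Path
    qc_report: pqc.QCReport
    imputed: IntensityMatrix
    corr_input: IntensityMatrix
    diffs: dict[str, da.DiffResult]
    anova: da.AnovaResult | None
    corr_map: Any
    anchor_members: pd.DataFrame | None
    annotation: pd.DataFrame | None
    counts: dict[str, int]
    truth: sim.SyntheticTruth | None = None


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(m: IntensityMatrix, path: Path) -> None:
    out = m.values.copy()
    out.insert(0, "gene", m.genes.reindex(out.index).to_numpy())
    out.index.name = "group_id"
    out.to_csv(path, sep="\t")


def _obtain_inputs(
    config: RunConfig, outdir: Path
) -> tuple[ProteinGroupTable, SampleSheet, ClinicalTable, pd.DataFrame | None, sim.SyntheticTruth | None]:
    if config.simulate is not None:
        preset = config.simulate.get("preset", "human")
        maker = {"human": sim.human_config, "mouse": sim.mouse_config,
                 "null": sim.null_config}[preset]
        overrides = {
            k: v for k, v in config.simulate.items() if k not in ("preset",)
        }
        cfg = maker(**overrides)
        table, sheet, clinical, truth = sim.generate_cohort(cfg, config.seed)
        expr = sim.tissue_expression_table(truth, seed=config.seed)
        logger.info("simulated cohort: %d protein groups, %d samples",
                    table.n_proteins, len(table.samples))
        return table, sheet, clinical, expr, truth
    inputs = config.inputs or {}
    table = pio.read_protein_groups(inputs["protein_groups"])
    sheet = pio.read_sample_sheet(inputs["sample_sheet"])
    check_samples_covered(table, sheet)
    clinical = (
        pio.read_clinical(inputs["clinical"])
        if "clinical" in inputs
        else ClinicalTable(pd.DataFrame(index=pd.Index(sheet.subjects, name="subject_id")))
    )
    expr = (
        pio.read_tissue_expression(inputs["tissue_expression"])
        if "tissue_expression" in inputs
        else None
    )
    return table, sheet, clinical, expr, None


def run_pipeline(config: RunConfig, outdir: str | Path) -> ReportBundle:
    """Execute all declared stages; returns the in-memory bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        return _run(config, outdir, counts)
    except Exception as e:
        (outdir / "FAILED").write_text(f"{type(e).__name__}: {e}\n", encoding="utf-8")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, counts: dict[str, int]) -> ReportBundle:
    table, sheet, clinical, expr, truth = _obtain_inputs(config, outdir)
    counts["raw_protein_groups"] = table.n_proteins

    if config.simulate is not None:
        _write_simulated(outdir, table, sheet, clinical, expr, truth)

    # ---- QC on the raw table -------------------------------------------
    panels = config.qc.get("panels") if config.qc else None
    qc_report = pqc.run_qc(table, sheet, panels=panels)
    pio.write_table(qc_report.per_sample, outdir / "qc_per_sample.tsv")
    pio.write_table(qc_report.per_protein, outdir / "qc_per_protein.tsv")
    logger.info("qc: %s", qc_report.summary())

    # ---- preprocessing --------------------------------------------------
    p = config.preprocess
    table_f, flag_counts = pp.filter_flags(table)
    counts["after_flag_filter"] = table_f.n_proteins
    logger.info("flag filter removed %s; %d protein groups remain",
                flag_counts, table_f.n_proteins)

    table_v = pp.filter_replicate_validity(table_f, sheet, min_valid=p["min_valid"])
    counts["after_replicate_validity"] = table_v.n_proteins
    logger.info("replicate-validity filter (>=%d valid): %d protein groups",
                p["min_valid"], table_v.n_proteins)

    subj_matrix = pp.aggregate_replicates(table_v, sheet, method=p["aggregate"])
    groups = sheet.subject_group()

    main = pp.filter_completeness(
        subj_matrix, groups, frac=p["completeness_frac"], mode="any_group"
    )
    counts["after_completeness_any_group"] = main.n_proteins
    logger.info("any-group completeness >= %.0f%%: %d protein groups, "
                "%.1f%% missing values", 100 * p["completeness_frac"],
                main.n_proteins, 100 * main.missing_fraction())

    main_log2 = pp.log2_transform(main)
    imputed = pp.impute_downshift(
        main_log2, shift=p["shift"], width=p["width"], scope=p["scope"],
        seed=config.seed,
    )
    _write_matrix(imputed, outdir / "matrix_imputed.tsv")

    # correlation branch: overall completeness, no imputation
    corr_input = pp.filter_completeness(
        pp.log2_transform(subj_matrix), frac=p["completeness_frac"], mode="overall"
    )
    counts["correlation_branch_proteins"] = corr_input.n_proteins
    _write_matrix(corr_input, outdir / "matrix_correlation.tsv")
    logger.info("correlation branch (overall completeness, no imputation): "
                "%d protein groups", corr_input.n_proteins)

    # ---- differential ---------------------------------------------------
    diffs: dict[str, da.DiffResult] = {}
    anova = None
    d = config.differential
    if config.contrasts:
        anova = da.anova_screen(imputed, groups, alpha=d["anova_alpha"])
        pio.write_table(anova, outdir / "anova_screen.tsv")
        panel_frames = []
        for contrast in config.contrasts:
            if contrast.method == "permutation_s0":
                res = da.permutation_fdr(imputed, groups, contrast)
            else:
                res = da.bh_fc_test(imputed, groups, contrast)
            res = da.apply_anova_screen(res, anova)
            diffs[contrast.name] = res
            pio.write_table(res, outdir / f"diff_{contrast.name}.tsv")
            n_sig = int(res.table["significant"].sum())
            logger.info("contrast %s (%s): %d significant, threshold %s",
                        contrast.name, contrast.method, n_sig,
                        res.metadata.get("threshold_found"))
            hits = res.table[res.table["in_panel"]].copy()
            hits.insert(0, "contrast", contrast.name)
            panel_frames.append(hits)
        panel = (
            pd.concat(panel_frames)
            if panel_frames
            else pd.DataFrame(columns=["contrast"])
        )
        pio.write_table(panel, outdir / "panel.tsv")

    # ---- correlation map ------------------------------------------------
    c = config.correlation
    corr = build_corr_map(corr_input, clinical if len(clinical.variables) else None,
                          min_n=c["min_n"])
    anchor_members = None
    if corr.r.shape[0] >= 2:
        corr = cluster_map(corr, linkage=c["linkage"])
        pio.write_table(corr.r, outdir / "correlation_r.tsv")
        pio.write_table(corr.n_pairs, outdir / "correlation_n.tsv")
        anchors = [a for a in c["anchors"] if a in (corr.clustered_vars or [])]
        if anchors and len(anchors) == len(c["anchors"]):
            anchor_members = anchor_cluster(corr, anchors)
            pio.write_table(anchor_members, outdir / "anchor_cluster.tsv")
            logger.info("anchor cluster members: %s",
                        anchor_members.index.tolist())

    # ---- tissue annotation ---------------------------------------------
    annotation = None
    if expr is not None:
        a = config.annotation
        annotation = classify_specificity(expr, tissue=a["tissue"], ratio=a["ratio"])
        pio.write_table(annotation, outdir / "tissue_annotation.tsv")
        for name, res in diffs.items():
            summ = specificity_summary(res, annotation)
            logger.info("specificity summary %s: %s", name, summ)

    _write_provenance(config, outdir, counts)
    return ReportBundle(
        outdir=outdir, qc_report=qc_report, imputed=imputed,
        corr_input=corr_input, diffs=diffs, anova=anova, corr_map=corr,
        anchor_members=anchor_members, annotation=annotation, counts=counts,
        truth=truth,
    )


def _write_simulated(outdir, table, sheet, clinical, expr, truth) -> None:
    simdir = outdir / "simulated"
    simdir.mkdir(exist_ok=True)
    export = pd.DataFrame(
        {
            "Protein IDs": [";".join(p) for p in table.meta["protein_ids"]],
            "Gene names": [";".join(g) for g in table.meta["gene_names"]],
            "Reverse": np.where(table.meta["flag_reverse"], "+", ""),
            "Only identified by site": np.where(table.meta["flag_site_only"], "+", ""),
            "Potential contaminant": np.where(table.meta["flag_contaminant"], "+", ""),
        },
        index=table.meta.index,
    )
    for s in table.samples:
        export[f"LFQ intensity {s}"] = table.intensities[s].fillna(0.0)
    export.to_csv(simdir / "protein_groups.tsv", sep="\t", index=False)
    sheet.df.to_csv(simdir / "sample_sheet.tsv", sep="\t", index=False)
    clinical.df.to_csv(simdir / "clinical.tsv", sep="\t")
    if expr is not None:
        expr.to_csv(simdir / "tissue_expression.tsv", sep="\t")
    truth.to_frame().to_csv(simdir / "truth.tsv", sep="\t")


def _write_provenance(config: RunConfig, outdir: Path, counts: dict[str, int]) -> None:
    record: dict[str, Any] = {
        "seed": config.seed,
        "groups": config.groups,
        "contrasts": [
            {
                "name": c.name,
                "groups_a": sorted(c.groups_a),
                "groups_b": sorted(c.groups_b),
                "method": c.method,
                "s0": c.s0, "fdr": c.fdr,
                "n_permutations": c.n_permutations,
                "min_abs_log2fc": c.min_abs_log2fc,
                "seed": c.seed,
            }
            for c in config.contrasts
        ],
        "preprocess": config.preprocess,
        "differential": config.differential,
        "correlation": config.correlation,
        "annotation": config.annotation,
        "filter_counts": counts,
    }
    if config.inputs:
        record["input_checksums"] = {
            k: _checksum(Path(v)) for k, v in config.inputs.items()
        }
    if config.simulate is not None:
        record["simulate"] = config.simulate
    (outdir / "provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
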