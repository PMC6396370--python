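"""Synthetic plasma-proteome cohorts with full ground truth.

The generator emulates the statistical structure the analysis assumes:
protein baselines log-uniform over ~6 orders of linear abundance; subject
values = baseline + planted group effect (log2(1+pct/100)) + between-subject
Normal noise; technical replicates with lognormal noise calibrated to a
target CV; abundance-dependent (missing-not-at-random) dropout with logistic
probability in log2 abundance; clinical variables built as noisy weighted
sums of designated driver proteins so that a liver-enzyme correlation cluster
is planted; optional contamination events that shift a sample's marker-panel
proteins. Everything is reproducible from one root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .tables import ClinicalTable, ProteinGroupTable, SampleSheet, ValidationError

__all__ = [
    "CohortConfig",
    "ClinicalSpec",
    "ContaminationEvent",
    "SyntheticTruth",
    "generate_cohort",
    "mnar_mask",
    "plant_effects",
    "tissue_expression_table",
    "human_config",
    "mouse_config",
    "null_config",
]

# Planted percent changes (A/B - 1 convention, vs the matching control group).
HUMAN_EFFECTS: dict[str, dict[str, float]] = {
    "PIGR": {"NAFLD_NGT": 186.0, "NAFLD_T2D": 157.0, "cirrhosis": 298.0},
    "ALDOB": {"NAFLD_NGT": 341.0},
    "VTN": {"NAFLD_NGT": 22.0},
    "LGALS3BP": {"NAFLD_T2D": 102.0, "cirrhosis": 170.0},
    "AFM": {"NAFLD_T2D": 58.0},
    "APOM": {"NAFLD_T2D": -25.0, "cirrhosis": -21.0},
}

MOUSE_EFFECTS: dict[str, dict[str, float]] = {
    "Saa1": {"HFD_6m": 400.0, "GIP": 120.0, "GLP1": 90.0, "GLP1_GIP": 80.0},
    "Pigr": {"HFD_6m": 298.0, "GIP": 110.0, "GLP1": 90.0, "GLP1_GIP": 70.0},
    "Aldob": {"HFD_6m": 341.0, "GIP": 100.0, "GLP1": 80.0, "GLP1_GIP": 60.0},
    "Dpp4": {"HFD_6m": 322.0, "GIP": 100.0, "GLP1": 90.0, "GLP1_GIP": 70.0},
    "Lap3": {"HFD_6m": 273.0, "GIP": 90.0, "GLP1": 70.0, "GLP1_GIP": 60.0},
    "Enpep": {"HFD_6m": 327.0, "GIP": 110.0, "GLP1": 80.0, "GLP1_GIP": 70.0},
}

DRIVER_GENES = ["DPP4", "ANPEP", "TGFBI", "APOE", "PIGR"]
ENZYME_NAMES = ["ALT", "AST", "ALP", "GGT"]
EXTRA_CLINICAL = [
    "BMI", "age", "glucose", "HbA1c", "insulin", "HOMA_IR", "cholesterol",
    "LDL", "HDL", "triglycerides", "CRP", "albumin", "bilirubin",
    "platelets", "INR", "creatinine", "urea",
]
# plausible clinical units: variable -> (offset, scale)
CLINICAL_UNITS = {
    "ALT": (40.0, 25.0), "AST": (35.0, 18.0), "ALP": (80.0, 30.0),
    "GGT": (45.0, 30.0), "BMI": (28.0, 5.0), "age": (50.0, 12.0),
    "glucose": (5.8, 1.2), "HbA1c": (5.9, 0.8), "insulin": (12.0, 6.0),
    "HOMA_IR": (3.0, 1.5), "cholesterol": (5.2, 1.0), "LDL": (3.1, 0.8),
    "HDL": (1.3, 0.35), "triglycerides": (1.6, 0.7), "CRP": (3.0, 2.5),
    "albumin": (42.0, 4.0), "bilirubin": (12.0, 5.0), "platelets": (240.0, 60.0),
    "INR": (1.1, 0.15), "creatinine": (75.0, 15.0), "urea": (5.5, 1.5),
}

PANEL_GENES = ["HBA1", "HBB", "HBD", "FGA", "FGB", "FGG"]

LIVER_GENES = {"ALDOB", "AFM", "APOM", "AHSG", "F2", "SERPINC1"}


@dataclass(frozen=True)
class ClinicalSpec:
    """How clinical variables derive from designated driver proteins."""

    enzymes: tuple[str, ...] = tuple(ENZYME_NAMES)
    drivers: tuple[str, ...] = tuple(DRIVER_GENES)
    noise_sd: float = 0.5  # on the standardized enzyme score
    extra_variables: tuple[str, ...] = tuple(EXTRA_CLINICAL)
    # latent structure of the driver block
    driver_latent_sd: float = 0.35
    driver_severity_sd: float = 0.5
    driver_resid_sd: float = 0.15


@dataclass(frozen=True)
class ContaminationEvent:
    sample_id: str
    genes: tuple[str, ...]
    log2_shift: float


@dataclass(frozen=True)
class CohortConfig:
    groups: dict[str, int]  # group label -> number of subjects
    n_replicates: int = 3
    n_proteins: int = 600
    span_orders: float = 6.0
    base_log2_min: float = math.log2(1e4)
    between_subject_sd_log2: float = 0.35
    replicate_cv_target: float = 0.15
    mnar_midpoint_log2: float = 21.0
    mnar_steepness: float = 0.25
    # protein-to-protein scatter of the detection midpoint (log2 units),
    # modeling ionization/flyability differences between proteins
    mnar_midpoint_sd: float = 1.5
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    group_severity: dict[str, float] = field(default_factory=dict)
    clinical: ClinicalSpec | None = None
    contamination_events: tuple[ContaminationEvent, ...] = ()
    n_decoys: int = 5
    n_contaminants: int = 5
    n_site_only: int = 3
    liver_specific_fraction: float = 0.25

    def validate(self) -> None:
        for gene, per_group in self.effects.items():
            for g, pct in per_group.items():
                if g not in self.groups:
                    raise ValidationError(
                        f"effect on {gene!r} references undeclared group {g!r}"
                    )
                if pct <= -100:
                    raise ValidationError(
                        f"effect {pct}% on {gene!r} would make abundance nonpositive"
                    )
        for g in self.group_severity:
            if g not in self.groups:
                raise ValidationError(f"severity for undeclared group {g!r}")
        if self.mnar_steepness <= 0:
            raise ValidationError("mnar_steepness must be positive")


@dataclass
class SyntheticTruth:
    """Generative ground truth of one synthetic cohort."""

    proteins: pd.DataFrame  # index group_id; gene, baseline_log2, is_liver_specific
    effects: dict[str, dict[str, float]]  # gene -> group -> percent change
    noise: dict[str, float]  # between_subject_sd_log2, replicate_cv_target
    mnar: dict[str, float]  # midpoint_log2, steepness
    clinical_spec: ClinicalSpec | None
    driver_genes: tuple[str, ...]
    contamination_events: tuple[ContaminationEvent, ...]
    seed: int

    def effect_log2(self, gene: str, group: str) -> float:
        pct = self.effects.get(gene, {}).get(group, 0.0)
        return math.log2(1.0 + pct / 100.0)

    def to_frame(self) -> pd.DataFrame:
        df = self.proteins.copy()
        for gene, per_group in self.effects.items():
            for g, pct in per_group.items():
                col = f"pct_{g}"
                if col not in df.columns:
                    df[col] = 0.0
                df.loc[df["gene"] == gene, col] = pct
        return df


def human_config(**overrides: Any) -> CohortConfig:
    """Default five-group human cohort: 48 subjects in technical triplicates."""
    cfg = CohortConfig(
        groups={"ctrl_NGT": 10, "NAFLD_NGT": 10, "ctrl_T2D": 8,
                "NAFLD_T2D": 10, "cirrhosis": 10},
        effects={k: dict(v) for k, v in HUMAN_EFFECTS.items()},
        group_severity={"ctrl_NGT": 0.0, "NAFLD_NGT": 1.0, "ctrl_T2D": 0.0,
                        "NAFLD_T2D": 1.0, "cirrhosis": 2.0},
        clinical=ClinicalSpec(),
    )
    return replace(cfg, **overrides) if overrides else cfg


def mouse_config(**overrides: Any) -> CohortConfig:
    """Five-group single-measurement design mirroring a diet/treatment study."""
    cfg = CohortConfig(
        groups={"HFD_1_2m": 6, "HFD_6m": 6, "GIP": 7, "GLP1": 8, "GLP1_GIP": 6},
        n_replicates=1,
        effects={k: dict(v) for k, v in MOUSE_EFFECTS.items()},
        group_severity={"HFD_1_2m": 0.0, "HFD_6m": 2.0, "GIP": 1.0,
                        "GLP1": 1.0, "GLP1_GIP": 0.5},
        clinical=None,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(n_proteins: int = 500, n_per_group: int = 10, **overrides: Any) -> CohortConfig:
    """Two groups, no planted effects, no clinical drivers: a global null."""
    cfg = CohortConfig(
        groups={"A": n_per_group, "B": n_per_group},
        n_proteins=n_proteins,
        effects={},
        clinical=None,
        n_decoys=0, n_contaminants=0, n_site_only=0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def mnar_mask(
    log2_values: np.ndarray,
    midpoint_log2: float,
    steepness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean missing mask; P(missing) = logistic((midpoint - x) * steepness)."""
    if steepness <= 0:
        raise ValidationError("mnar steepness must be positive")
    x = np.asarray(log2_values, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(midpoint_log2 - x) * steepness))
    return rng.random(x.shape) < p


def plant_effects(
    truth: SyntheticTruth, gene: str, group: str, pct_change: float
) -> SyntheticTruth:
    """Return a truth with one additional planted percent change."""
    if pct_change <= -100:
        raise ValidationError("percent change must exceed -100")
    if gene not in set(truth.proteins["gene"]):
        raise ValidationError(f"unknown protein {gene!r}")
    effects = {g: dict(v) for g, v in truth.effects.items()}
    effects.setdefault(gene, {})[group] = pct_change
    return SyntheticTruth(
        proteins=truth.proteins,
        effects=effects,
        noise=truth.noise,
        mnar=truth.mnar,
        clinical_spec=truth.clinical_spec,
        driver_genes=truth.driver_genes,
        contamination_events=truth.contamination_events,
        seed=truth.seed,
    )


def _gene_names(config: CohortConfig) -> list[str]:
    named = list(config.effects)
    if config.clinical is not None:
        named += [g for g in config.clinical.drivers if g not in named]
    named += [g for g in PANEL_GENES if g not in named]
    if len(named) > config.n_proteins:
        raise ValidationError("more named proteins than n_proteins")
    generic = [f"GEN{i:04d}" for i in range(config.n_proteins - len(named))]
    return named + generic


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[ProteinGroupTable, SampleSheet, ClinicalTable, SyntheticTruth]:
    """Generate one full synthetic study (tables + ground truth)."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    (ss_base, ss_subj, ss_rep, ss_mnar, ss_clin, ss_misc) = ss.spawn(6)
    rng_base = np.random.default_rng(ss_base)
    rng_subj = np.random.default_rng(ss_subj)
    rng_rep = np.random.default_rng(ss_rep)
    rng_mnar = np.random.default_rng(ss_mnar)
    rng_clin = np.random.default_rng(ss_clin)
    rng_misc = np.random.default_rng(ss_misc)

    genes = _gene_names(config)
    n_named = sum(
        1 for g in genes if not g.startswith("GEN")
    )
    p = config.n_proteins
    lo = config.base_log2_min
    hi = lo + config.span_orders * math.log2(10)
    baselines = rng_base.uniform(lo, hi, size=p)
    # named proteins (planted effects, drivers, QC panels) sit in the abundant
    # top of the range so filtering never removes them
    baselines[:n_named] = rng_base.uniform(hi - 1.5 * math.log2(10), hi, size=n_named)

    is_liver = np.zeros(p, dtype=bool)
    is_liver[[i for i, g in enumerate(genes) if g in LIVER_GENES]] = True
    generic_idx = np.array([i for i, g in enumerate(genes) if g.startswith("GEN")])
    if len(generic_idx):
        extra = rng_base.random(len(generic_idx)) < config.liver_specific_fraction
        is_liver[generic_idx[extra]] = True

    # subjects
    subjects: list[str] = []
    subject_group: list[str] = []
    for g, n in config.groups.items():
        for k in range(1, n + 1):
            subjects.append(f"{g}_{k:02d}")
            subject_group.append(g)
    n_subj = len(subjects)
    group_arr = np.array(subject_group)

    severity = np.array([config.group_severity.get(g, 0.0) for g in subject_group])
    sev_sd = severity.std(ddof=0)
    severity_z = (severity - severity.mean()) / sev_sd if sev_sd > 0 else np.zeros(n_subj)

    # planted effects in log2 per protein x subject
    eff = np.zeros((p, n_subj))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene, per_group in config.effects.items():
        for g, pct in per_group.items():
            eff[gene_pos[gene], group_arr == g] = math.log2(1.0 + pct / 100.0)

    # between-subject biological noise; driver proteins additionally share a
    # latent hepatic factor (and a disease-severity component when they carry
    # no explicit planted effect), which plants the enzyme correlation block
    noise = rng_subj.normal(0.0, config.between_subject_sd_log2, size=(p, n_subj))
    drivers: tuple[str, ...] = ()
    if config.clinical is not None:
        spec = config.clinical
        drivers = spec.drivers
        latent = rng_subj.normal(0.0, 1.0, size=n_subj)
        for gene in drivers:
            i = gene_pos[gene]
            row = rng_subj.normal(0.0, spec.driver_resid_sd, size=n_subj)
            row += spec.driver_latent_sd * latent
            if gene not in config.effects:
                row += spec.driver_severity_sd * severity_z
            noise[i] = row

    subj_log2 = baselines[:, None] + eff + noise

    # technical replicates with lognormal noise at the target CV
    sigma_rep = math.sqrt(math.log(1.0 + config.replicate_cv_target**2))
    sample_ids: list[str] = []
    sample_subject: list[str] = []
    sample_group: list[str] = []
    rep_index: list[int] = []
    cols = []
    for j, subj in enumerate(subjects):
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{subj}_r{r}")
            sample_subject.append(subj)
            sample_group.append(subject_group[j])
            rep_index.append(r)
            cols.append(j)
    rep_log2 = subj_log2[:, cols] + rng_rep.normal(
        0.0, sigma_rep / math.log(2), size=(p, len(cols))
    )

    # contamination events shift panel proteins of chosen samples
    for ev in config.contamination_events:
        if ev.sample_id not in sample_ids:
            raise ValidationError(f"contamination event names unknown sample {ev.sample_id!r}")
        sj = sample_ids.index(ev.sample_id)
        for gene in ev.genes:
            if gene in gene_pos:
                rep_log2[gene_pos[gene], sj] += ev.log2_shift

    # MNAR dropout per replicate measurement; each protein has its own
    # detection midpoint (peptide flyability differs between proteins)
    midpoint_offsets = rng_mnar.normal(0.0, config.mnar_midpoint_sd, size=p)
    missing = np.zeros_like(rep_log2, dtype=bool)
    for i in range(p):
        missing[i] = mnar_mask(
            rep_log2[i],
            config.mnar_midpoint_log2 + midpoint_offsets[i],
            config.mnar_steepness,
            rng_mnar,
        )
    linear = np.power(2.0, rep_log2)
    linear[missing] = np.nan

    group_ids = [f"PG{i:04d}" for i in range(p)]
    meta = pd.DataFrame(
        {
            "protein_ids": [(f"P{i:05d}",) for i in range(p)],
            "gene_names": [(g,) for g in genes],
            "gene": genes,
            "flag_reverse": False,
            "flag_contaminant": False,
            "flag_site_only": False,
        },
        index=pd.Index(group_ids, name="group_id"),
    )
    intensities = pd.DataFrame(linear, index=meta.index, columns=sample_ids)

    # artifact rows a search engine would report: decoys, contaminants,
    # site-only identifications
    artifact_rows = []
    for kind, n_rows, flag in (
        ("REV", config.n_decoys, "flag_reverse"),
        ("CON", config.n_contaminants, "flag_contaminant"),
        ("SIT", config.n_site_only, "flag_site_only"),
    ):
        for k in range(n_rows):
            gid = f"{kind}{k:03d}"
            row = {
                "protein_ids": (f"{kind}_P{k:03d}",),
                "gene_names": (f"{kind}G{k:03d}",),
                "gene": f"{kind}G{k:03d}",
                "flag_reverse": False,
                "flag_contaminant": False,
                "flag_site_only": False,
            }
            row[flag] = True
            vals = np.power(2.0, rng_misc.uniform(lo, hi)) * np.exp(
                rng_misc.normal(0, sigma_rep, size=len(sample_ids))
            )
            artifact_rows.append((gid, row, vals))
    if artifact_rows:
        art_meta = pd.DataFrame(
            [r for _, r, _ in artifact_rows],
            index=pd.Index([g for g, _, _ in artifact_rows], name="group_id"),
        )
        art_int = pd.DataFrame(
            np.vstack([v for _, _, v in artifact_rows]),
            index=art_meta.index,
            columns=sample_ids,
        )
        meta = pd.concat([meta, art_meta])
        intensities = pd.concat([intensities, art_int])

    table = ProteinGroupTable(meta=meta, intensities=intensities)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": sample_subject,
                "group": sample_group,
                "replicate_index": rep_index,
            }
        )
    )

    # clinical variables
    clinical = None
    if config.clinical is not None:
        spec = config.clinical
        clin = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
        driver_vals = subj_log2[[gene_pos[g] for g in drivers], :]
        dz = (driver_vals - driver_vals.mean(axis=1, keepdims=True)) / driver_vals.std(
            axis=1, ddof=1, keepdims=True
        )
        score = dz.mean(axis=0)
        for name in spec.enzymes:
            z = score + rng_clin.normal(0.0, spec.noise_sd, size=n_subj)
            off, sc = CLINICAL_UNITS.get(name, (0.0, 1.0))
            clin[name] = off + sc * z
        for name in spec.extra_variables:
            z = rng_clin.normal(0.0, 1.0, size=n_subj)
            off, sc = CLINICAL_UNITS.get(name, (0.0, 1.0))
            clin[name] = off + sc * z
        clinical = ClinicalTable(clin)
    else:
        clinical = ClinicalTable(
            pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
        )

    truth = SyntheticTruth(
        proteins=pd.DataFrame(
            {"gene": genes, "baseline_log2": baselines, "is_liver_specific": is_liver},
            index=pd.Index(group_ids, name="group_id"),
        ),
        effects={g: dict(v) for g, v in config.effects.items()},
        noise={
            "between_subject_sd_log2": config.between_subject_sd_log2,
            "replicate_cv_target": config.replicate_cv_target,
        },
        mnar={
            "midpoint_log2": config.mnar_midpoint_log2,
            "steepness": config.mnar_steepness,
            "midpoint_sd": config.mnar_midpoint_sd,
        },
        clinical_spec=config.clinical,
        driver_genes=drivers,
        contamination_events=config.contamination_events,
        seed=seed,
    )
    return table, sheet, clinical, truth


def tissue_expression_table(
    truth: SyntheticTruth, seed: int, tissues: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Synthetic gene x tissue mRNA table consistent with the truth's
    liver-specificity flags (a stand-in for an expression atlas)."""
    if tissues is None:
        tissues = ("liver", "kidney", "lung", "brain", "muscle", "pancreas",
                   "spleen", "heart", "intestine", "skin")
    rng = np.random.default_rng(seed)
    genes = truth.proteins["gene"].tolist()
    is_liver = truth.proteins["is_liver_specific"].to_numpy()
    n_t = len(tissues)
    rows = []
    for gi, gene in enumerate(genes):
        base = rng.lognormal(2.0, 1.0, size=n_t)
        if is_liver[gi]:
            base[0] = base.max() * rng.uniform(6.0, 30.0)
        rows.append(base)
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=tissues)
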