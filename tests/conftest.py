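from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import plasmaprot as P

PG_TSV = """Protein IDs\tGene names\tReverse\tOnly identified by site\tPotential contaminant\tLFQ intensity S1\tLFQ intensity S2\tLFQ intensity S3
P11111\tIGHM;IGHG1\t\t\t\t1200000\t0\t900000
REV__P22222\tDECOY1\t+\t\t\t500\t600\t700
P33333\tALB\t\t\t\t2.5e9\t2.4e9\t2.6e9
"""

SHEET_TSV = """sample_id\tsubject_id\tgroup\treplicate_index
S1\tsubj1\tcontrol\t1
S2\tsubj1\tcontrol\t2
S3\tsubj1\tcontrol\t3
S4\tsubj2\tdisease\t1
S5\tsubj2\tdisease\t2
S6\tsubj2\tdisease\t3
"""

CLIN_TSV = """subject_id\tALT\tAST
subj1\t34.5\t
subj2\t80\t55
"""


@pytest.fixture
def pg_path(tmp_path):
    p = tmp_path / "proteinGroups.tsv"
    p.write_text(PG_TSV)
    return p


@pytest.fixture
def sheet_path(tmp_path):
    p = tmp_path / "samples.tsv"
    p.write_text(SHEET_TSV)
    return p


@pytest.fixture
def clin_path(tmp_path):
    p = tmp_path / "clinical.tsv"
    p.write_text(CLIN_TSV)
    return p


def make_table(values: np.ndarray, samples: list[str], genes: list[str] | None = None,
               flags: dict[str, list[bool]] | None = None) -> P.ProteinGroupTable:
    """Build a ProteinGroupTable from a dense array (NaN = missing)."""
    n = values.shape[0]
    genes = genes if genes is not None else [f"G{i}" for i in range(n)]
    gids = pd.Index([f"PG{i}" for i in range(n)], name="group_id")
    meta = pd.DataFrame(
        {
            "protein_ids": [(f"P{i}",) for i in range(n)],
            "gene_names": [(g,) for g in genes],
            "gene": genes,
            "flag_reverse": (flags or {}).get("reverse", [False] * n),
            "flag_contaminant": (flags or {}).get("contaminant", [False] * n),
            "flag_site_only": (flags or {}).get("site_only", [False] * n),
        },
        index=gids,
    )
    return P.ProteinGroupTable(
        meta=meta, intensities=pd.DataFrame(values, index=gids, columns=samples)
    )


def make_matrix(values: np.ndarray, columns: list[str], scale: str = "log2",
                genes: list[str] | None = None) -> P.IntensityMatrix:
    n = values.shape[0]
    genes = genes if genes is not None else [f"G{i}" for i in range(n)]
    idx = pd.Index([f"PG{i}" for i in range(n)], name="group_id")
    return P.IntensityMatrix(
        values=pd.DataFrame(values, index=idx, columns=columns),
        genes=pd.Series(genes, index=idx),
        scale=scale,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One default human cohort, generated once for read-only tests."""
    return P.generate_cohort(P.human_config(), seed=11)


@pytest.fixture(scope="session")
def preprocessed(small_cohort):
    table, sheet, clinical, truth = small_cohort
    tf, _ = P.filter_flags(table)
    tv = P.filter_replicate_validity(tf, sheet)
    subj = P.aggregate_replicates(tv, sheet)
    main = P.filter_completeness(subj, sheet.subject_group(), frac=0.70, mode="any_group")
    imputed = P.impute_downshift(P.log2_transform(main), seed=11)
    corr_in = P.filter_completeness(P.log2_transform(subj), frac=0.70, mode="overall")
    return {
        "sheet": sheet, "clinical": clinical, "truth": truth,
        "subjects": subj, "main": main, "imputed": imputed, "corr_input": corr_in,
    }
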