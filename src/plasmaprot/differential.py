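"""Differential abundance statistics.

Two routes mirror the two study arms:

* the human arm uses a two-sided pooled-variance Student's t-test moderated by
  the SAM-style ``s0`` constant, ``stat = d / (se + s0)``, with significance
  controlled by a permutation-based false discovery rate: group labels are
  permuted, null exceedance counts at candidate thresholds are averaged, and
  the smallest threshold with estimated FDR at or below the target defines the
  significant set;
* the "mouse" arm uses plain t-tests with Benjamini-Hochberg adjustment plus a
  minimum absolute log2 fold-change floor.

A one-way ANOVA across all experimental groups screens pairwise hits: a
protein significant in one contrast but flat across the full design is flagged
and excluded from the reported panel. Percent fold changes follow the
A/B - 1 convention on linear intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import IntensityMatrix
from .tables import ValidationError

__all__ = [
    "Contrast",
    "DiffResult",
    "AnovaResult",
    "student_t",
    "s0_statistic",
    "permutation_fdr",
    "bh_adjust",
    "mouse_criteria",
    "bh_fc_test",
    "anova_screen",
    "apply_anova_screen",
    "fold_change_pct",
    "assumption_checks",
]


@dataclass(frozen=True)
class Contrast:
    """One two-group comparison; group sets are pooled before testing."""

    name: str
    groups_a: frozenset
    groups_b: frozenset
    method: str = "permutation_s0"  # or "bh_fc"
    s0: float = 0.01
    fdr: float = 0.05
    n_permutations: int = 250
    min_abs_log2fc: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        ga = frozenset(self.groups_a)
        gb = frozenset(self.groups_b)
        object.__setattr__(self, "groups_a", ga)
        object.__setattr__(self, "groups_b", gb)
        if not ga or not gb:
            raise ValidationError(f"contrast {self.name!r}: both group sets must be nonempty")
        if ga & gb:
            raise ValidationError(f"contrast {self.name!r}: group sets overlap: {sorted(ga & gb)}")
        if self.method not in ("permutation_s0", "bh_fc"):
            raise ValidationError(f"contrast {self.name!r}: unknown method {self.method!r}")
        if self.s0 < 0:
            raise ValidationError("s0 must be >= 0")


@dataclass
class DiffResult:
    """Per-protein statistics for one contrast plus method metadata."""

    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    COLUMNS = [
        "gene", "mean_a", "mean_b", "log2_diff", "pct_change", "t_stat",
        "p_value", "s0_stat", "q_estimate", "significant", "direction",
    ]

    def to_frame(self) -> pd.DataFrame:
        return self.table

    @property
    def significant_ids(self) -> list:
        return self.table.index[self.table["significant"]].tolist()


@dataclass
class AnovaResult:
    table: pd.DataFrame  # F_stat, p_value, passed
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return self.table


def student_t(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, p, se of the difference)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("student_t needs >=2 values per side")
    d = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if se == 0:
        if d == 0:
            return 0.0, 1.0, 0.0
        warnings.warn("zero variance with unequal means; p degenerates to 0")
        return math.copysign(math.inf, d), 0.0, 0.0
    t = d / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(se)


def s0_statistic(d: float, se: float, s0: float) -> float:
    """SAM-style moderated statistic d/(se + s0); s0=0 gives the t statistic."""
    if se + s0 == 0:
        raise ValidationError("se + s0 must be positive")
    return d / (se + s0)


def _group_columns(
    matrix: IntensityMatrix, groups: pd.Series, labels: frozenset
) -> list[str]:
    groups = groups.reindex(matrix.columns)
    return [c for c in matrix.columns if groups[c] in labels]


def _pooled_stats(
    X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row mean difference and pooled-variance SE."""
    na, nb = len(idx_a), len(idx_b)
    A, B = X[:, idx_a], X[:, idx_b]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    return ma, mb, ma - mb, se


def _all_relabelings(n: int, k: int) -> np.ndarray:
    """All C(n, k) index sets of size k from range(n), row per relabeling."""
    return np.array(list(combinations(range(n), k)), dtype=int)


def permutation_fdr(
    matrix: IntensityMatrix,
    groups: pd.Series | dict,
    contrast: Contrast,
) -> DiffResult:
    """s0-moderated test with permutation-based FDR over one pooled contrast.

    The observed statistic per protein is ``|d/(se+s0)|``. Group labels are
    permuted (exhaustively when the number of distinct relabelings does not
    exceed ``n_permutations``, each relabeling used once; otherwise by seeded
    uniform draws). For each candidate threshold c taken from the sorted
    observed statistics, FDR(c) = mean over permutations of the null count at
    or above c, divided by the observed count at or above c. The decision
    threshold is the smallest c with FDR(c) <= contrast.fdr; ties at the
    threshold are significant. Per-protein q is the smallest FDR(c) over
    thresholds at or below the protein's own statistic.
    """
    matrix.require_scale("log2", "permutation_fdr")
    if matrix.values.isna().any().any():
        raise ValidationError("permutation_fdr requires a complete (imputed) matrix")
    groups = pd.Series(groups)
    cols_a = _group_columns(matrix, groups, contrast.groups_a)
    cols_b = _group_columns(matrix, groups, contrast.groups_b)
    na, nb = len(cols_a), len(cols_b)
    if na < 3 or nb < 3:
        raise ValidationError(
            f"contrast {contrast.name!r}: needs >=3 columns per side, got {na} vs {nb}"
        )
    cols = cols_a + cols_b
    X = matrix.values[cols].to_numpy(dtype=float)
    n = na + nb
    idx_a0 = np.arange(na)
    idx_b0 = np.arange(na, n)

    ma, mb, d, se = _pooled_stats(X, idx_a0, idx_b0)
    obs_stat = d / (se + contrast.s0)
    obs_abs = np.abs(obs_stat)

    n_exhaustive = math.comb(n, na)
    rng = np.random.default_rng(contrast.seed)
    if n_exhaustive <= contrast.n_permutations:
        sets_a = _all_relabelings(n, na)
    else:
        sets_a = np.empty((contrast.n_permutations, na), dtype=int)
        for i in range(contrast.n_permutations):
            sets_a[i] = rng.permutation(n)[:na]
    n_perm = sets_a.shape[0]

    # Null exceedance counts at the observed order statistics. For each
    # permutation, count null |stat| >= c via sorted search.
    candidates = np.sort(obs_abs)  # ascending
    obs_count = len(candidates) - np.searchsorted(candidates, candidates, side="left")
    null_ge = np.zeros(len(candidates), dtype=float)
    all_idx = np.arange(n)
    mask = np.zeros(n, dtype=bool)
    for row in sets_a:
        mask[:] = False
        mask[row] = True
        idx_a = all_idx[mask]
        idx_b = all_idx[~mask]
        _, _, dp, sep = _pooled_stats(X, idx_a, idx_b)
        null_abs = np.sort(np.abs(dp / (sep + contrast.s0)))
        null_ge += len(null_abs) - np.searchsorted(null_abs, candidates, side="left")
    mean_null = null_ge / n_perm
    fdr_at = np.minimum(mean_null / np.maximum(obs_count, 1), 1.0)

    ok = fdr_at <= contrast.fdr
    if ok.any():
        threshold = float(candidates[np.argmax(ok)])  # smallest passing c
    else:
        warnings.warn(
            f"contrast {contrast.name!r}: no threshold attains FDR "
            f"{contrast.fdr}; zero significant"
        )
        threshold = math.inf
    significant = obs_abs >= threshold

    # q per protein: min FDR(c) over candidate thresholds c <= |stat_i|,
    # i.e. over every threshold at which the protein would be called;
    # automatically nonincreasing in |stat|.
    run_min = np.minimum.accumulate(fdr_at)
    pos = np.searchsorted(candidates, obs_abs, side="right") - 1
    q = run_min[pos]

    # plain t-test p-values alongside (reporting; the decision is by FDR)
    t_stat = np.where(se > 0, d / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(
        se > 0, 2 * stats.t.sf(np.abs(t_stat), n - 2), np.where(d == 0, 1.0, 0.0)
    )

    linear = 2.0 ** X
    med_a = np.median(linear[:, idx_a0], axis=1)
    med_b = np.median(linear[:, idx_b0], axis=1)
    pct = (med_a / med_b - 1.0) * 100.0

    table = pd.DataFrame(
        {
            "gene": matrix.genes.reindex(matrix.values.index).to_numpy(),
            "mean_a": ma,
            "mean_b": mb,
            "log2_diff": d,
            "pct_change": pct,
            "t_stat": t_stat,
            "p_value": p,
            "s0_stat": obs_stat,
            "q_estimate": q,
            "significant": significant,
            "direction": np.where(d >= 0, "up", "down"),
        },
        index=matrix.values.index,
    )
    metadata = {
        "contrast": contrast.name,
        "method": "permutation_s0",
        "n_a": na,
        "n_b": nb,
        "s0": contrast.s0,
        "fdr": contrast.fdr,
        "threshold_found": threshold,
        "n_permutations_used": n_perm,
        "exhaustive": n_exhaustive <= contrast.n_permutations,
        "seed": contrast.seed,
    }
    return DiffResult(table=table, metadata=metadata)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonized)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bh_fc_test(
    matrix: IntensityMatrix,
    groups: pd.Series | dict,
    contrast: Contrast,
    variant: str = "pooled",
) -> DiffResult:
    """Per-protein t-tests with BH adjustment; significance additionally
    requires the fold-change floor (see :func:`mouse_criteria`)."""
    matrix.require_scale("log2", "bh_fc_test")
    groups = pd.Series(groups)
    cols_a = _group_columns(matrix, groups, contrast.groups_a)
    cols_b = _group_columns(matrix, groups, contrast.groups_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError(f"contrast {contrast.name!r}: needs >=2 columns per side")
    rows = []
    for gid in matrix.values.index:
        a = matrix.values.loc[gid, cols_a].dropna().to_numpy(dtype=float)
        b = matrix.values.loc[gid, cols_b].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append((np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        t, p, se = student_t(a, b, variant=variant)
        d = a.mean() - b.mean()
        pct = fold_change_pct(2.0 ** a, 2.0 ** b)
        rows.append((a.mean(), b.mean(), d, pct, t, p))
    arr = pd.DataFrame(
        rows,
        index=matrix.values.index,
        columns=["mean_a", "mean_b", "log2_diff", "pct_change", "t_stat", "p_value"],
    )
    tested = arr["p_value"].notna()
    q = np.full(len(arr), np.nan)
    q[tested.to_numpy()] = bh_adjust(arr.loc[tested, "p_value"].to_numpy())
    table = arr.copy()
    table.insert(0, "gene", matrix.genes.reindex(matrix.values.index).to_numpy())
    table["s0_stat"] = table["t_stat"]
    table["q_estimate"] = q
    table["significant"] = False
    table["direction"] = np.where(table["log2_diff"] >= 0, "up", "down")
    result = DiffResult(
        table=table,
        metadata={
            "contrast": contrast.name,
            "method": "bh_fc",
            "n_a": len(cols_a),
            "n_b": len(cols_b),
            "fdr": contrast.fdr,
            "min_abs_log2fc": contrast.min_abs_log2fc,
            "seed": contrast.seed,
        },
    )
    return mouse_criteria(result, fdr=contrast.fdr, min_abs_log2fc=contrast.min_abs_log2fc)


def mouse_criteria(
    diff: DiffResult, fdr: float = 0.05, min_abs_log2fc: float = 1.0
) -> DiffResult:
    """Significance rule of the five-group arm: BH q below the FDR level AND
    absolute log2 fold change at or above the floor."""
    t = diff.table
    if t["q_estimate"].isna().all():
        raise ValidationError("mouse_criteria requires BH-adjusted q values")
    sig = (t["q_estimate"] < fdr) & (t["log2_diff"].abs() >= min_abs_log2fc)
    out = t.copy()
    out["significant"] = sig.fillna(False)
    out["direction"] = np.where(out["log2_diff"] >= 0, "up", "down")
    md = dict(diff.metadata)
    md.update({"fdr": fdr, "min_abs_log2fc": min_abs_log2fc})
    return DiffResult(table=out, metadata=md)


def anova_screen(
    matrix: IntensityMatrix, groups: pd.Series | dict, alpha: float = 0.05
) -> AnovaResult:
    """One-way fixed-effects ANOVA per protein across all experimental groups."""
    groups = pd.Series(groups).reindex(matrix.columns)
    blocks: list[list[str]] = []
    for label, cols in groups.groupby(groups):
        ids = list(cols.index)
        if len(ids) < 2:
            warnings.warn(f"group {label!r} has <2 columns; dropped from ANOVA")
            continue
        blocks.append(ids)
    if len(blocks) < 2:
        raise ValidationError("anova_screen needs >=2 groups with >=2 columns")
    F = np.empty(matrix.n_proteins)
    p = np.empty(matrix.n_proteins)
    X = matrix.values
    for i, gid in enumerate(X.index):
        samples = [X.loc[gid, ids].dropna().to_numpy(dtype=float) for ids in blocks]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            F[i], p[i] = np.nan, np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F[i], p[i] = stats.f_oneway(*samples)
        if not np.isfinite(F[i]):  # all-constant degenerate input
            F[i], p[i] = 0.0, 1.0
    table = pd.DataFrame(
        {"F_stat": F, "p_value": p, "passed": p < alpha}, index=X.index
    )
    return AnovaResult(table=table, alpha=alpha)


def apply_anova_screen(diff: DiffResult, anova: AnovaResult) -> DiffResult:
    """Flag pairwise hits that fail the across-all-groups ANOVA.

    Flagged proteins stay in the full table with ``anova_excluded=True`` and
    are left out of the reported panel (``in_panel`` column).
    """
    t = diff.table.copy()
    passed = anova.table["passed"].reindex(t.index).fillna(False)
    t["anova_excluded"] = t["significant"] & ~passed
    t["in_panel"] = t["significant"] & passed
    md = dict(diff.metadata)
    md["anova_alpha"] = anova.alpha
    return DiffResult(table=t, metadata=md)


def fold_change_pct(
    values_a: Sequence[float],
    values_b: Sequence[float],
    center: Callable[[np.ndarray], float] = np.median,
) -> float:
    """Percent fold change, center(A)/center(B) - 1, on linear intensities."""
    ca = float(center(np.asarray(values_a, dtype=float)))
    cb = float(center(np.asarray(values_b, dtype=float)))
    if cb == 0:
        raise ValidationError("fold_change_pct: center of condition B is zero")
    return (ca / cb - 1.0) * 100.0


def assumption_checks(
    matrix: IntensityMatrix,
    groups: pd.Series | dict,
    contrasts: Sequence[Contrast] = (),
    alpha: float = 0.05,
    levene_center: str = "median",
) -> dict[str, Any]:
    """Distributional checks behind the t-tests.

    Shapiro-Wilk normality on each protein's pooled within-group residuals;
    Levene's test for equality of variances in each two-group contrast
    (median-centered by default, which holds its nominal level at small n;
    ``levene_center="mean"`` gives the classic variant). Returns per-protein
    p-values and the fraction passing each test at ``alpha``.
    """
    groups = pd.Series(groups).reindex(matrix.columns)
    X = matrix.values
    shapiro_p = np.full(matrix.n_proteins, np.nan)
    for i, gid in enumerate(X.index):
        resid: list[np.ndarray] = []
        for _, cols in groups.groupby(groups):
            v = X.loc[gid, list(cols.index)].dropna().to_numpy(dtype=float)
            if len(v) >= 2:
                resid.append(v - v.mean())
        pooled = np.concatenate(resid) if resid else np.array([])
        if len(pooled) >= 3 and np.ptp(pooled) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapiro_p[i] = stats.shapiro(pooled).pvalue
    out: dict[str, Any] = {
        "shapiro_p": pd.Series(shapiro_p, index=X.index),
        "shapiro_pass_fraction": float(np.nanmean(shapiro_p >= alpha)),
        "levene": {},
    }
    for contrast in contrasts:
        cols_a = _group_columns(matrix, groups, contrast.groups_a)
        cols_b = _group_columns(matrix, groups, contrast.groups_b)
        lev_p = np.full(matrix.n_proteins, np.nan)
        for i, gid in enumerate(X.index):
            a = X.loc[gid, cols_a].dropna().to_numpy(dtype=float)
            b = X.loc[gid, cols_b].dropna().to_numpy(dtype=float)
            if len(a) >= 2 and len(b) >= 2 and (np.ptp(a) > 0 or np.ptp(b) > 0):
                lev_p[i] = stats.levene(a, b, center=levene_center).pvalue
        out["levene"][contrast.name] = {
            "p": pd.Series(lev_p, index=X.index),
            "pass_fraction": float(np.nanmean(lev_p >= alpha)),
        }
    return out
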