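"""Tissue-specificity classification from mRNA expression ratios.

Implements the expression-atlas style classes: a gene is *tissue enriched* if
the target tissue's mRNA level is at least ``ratio``-fold (default five-fold,
i.e. "500% higher") above every other tissue; *group enriched* if a group of
2-7 tissues containing the target jointly exceeds the rest by the same ratio;
*tissue enhanced* if the target exceeds the all-tissue mean by the ratio;
otherwise *not specific*. A protein counts as "liver-specific" when any of the
three classes applies with liver as the target tissue.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .differential import DiffResult
from .tables import ValidationError

__all__ = ["classify_specificity", "specificity_summary", "CLASSES"]

CLASSES = ("tissue_enriched", "group_enriched", "tissue_enhanced", "not_specific")

MAX_GROUP_SIZE = 7


def _classify_row(
    expr: pd.Series, tissue: str, ratio: float
) -> tuple[str, str | None, float | None]:
    target = float(expr[tissue])
    others = expr.drop(tissue).astype(float)
    if float(expr.sum()) == 0:
        return "not_specific", None, None
    max_other = float(others.max()) if len(others) else 0.0
    # tissue enriched: target >= ratio x every other tissue
    if target > 0 and target >= ratio * max_other:
        support = np.inf if max_other == 0 else target / max_other
        return "tissue_enriched", tissue, float(support)
    # group enriched: greedy group of 2-7 top tissues containing the target
    ranked = expr.sort_values(ascending=False, kind="stable")
    names = list(ranked.index)
    if tissue in names:
        pos = names.index(tissue)
        for size in range(2, MAX_GROUP_SIZE + 1):
            if size <= pos:  # target not inside the top-`size` set
                continue
            if size >= len(names):
                break
            group_min = float(ranked.iloc[:size].min())
            rest_max = float(ranked.iloc[size:].max())
            if group_min > 0 and group_min >= ratio * rest_max:
                support = np.inf if rest_max == 0 else group_min / rest_max
                return "group_enriched", tissue, float(support)
    # tissue enhanced: target >= ratio x mean over all tissues
    mean_all = float(expr.mean())
    if target > 0 and mean_all > 0 and target >= ratio * mean_all:
        return "tissue_enhanced", tissue, float(target / mean_all)
    return "not_specific", None, None


def classify_specificity(
    expr: pd.DataFrame, tissue: str = "liver", ratio: float = 5.0
) -> pd.DataFrame:
    """Classify every gene's specificity for ``tissue``.

    ``expr`` is a gene x tissue table of nonnegative expression levels.
    Returns a frame with ``class``, ``target_tissue``, ``support`` (the ratio
    that triggered the class) and ``is_specific``.
    """
    if expr.shape[1] < 2:
        raise ValidationError("need >=2 tissues")
    if tissue not in expr.columns:
        raise ValidationError(f"target tissue {tissue!r} not in the table")
    if (expr.to_numpy(dtype=float) < 0).any():
        raise ValidationError("expression levels must be nonnegative")
    rows = [_classify_row(expr.loc[g], tissue, ratio) for g in expr.index]
    out = pd.DataFrame(rows, index=expr.index, columns=["class", "target_tissue", "support"])
    out["is_specific"] = out["class"] != "not_specific"
    return out


def specificity_summary(diff: DiffResult, classes: pd.DataFrame) -> dict[str, Any]:
    """Fraction of liver-specific proteins among down- and up-regulated hits.

    Significant proteins are matched to ``classes`` by gene symbol; a
    direction with zero significant proteins reports an absent fraction.
    """
    t = diff.table
    sig = t[t["significant"]]
    specific = set(classes.index[classes["is_specific"]])
    out: dict[str, Any] = {}
    for direction in ("down", "up"):
        hits = sig[sig["direction"] == direction]
        n = len(hits)
        k = int(hits["gene"].isin(specific).sum())
        out[direction] = (
            None if n == 0 else {"fraction": k / n, "numerator": k, "denominator": n}
        )
    return out
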