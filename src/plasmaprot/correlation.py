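"""Global correlation map over proteins and clinical variables.

Pairwise-complete Pearson correlation of every variable pair across subjects,
hierarchical clustering of the resulting matrix on the 1 - r distance, and
extraction of the anchor cluster: the smallest dendrogram node whose leaves
contain a given set of variables (by default the four liver enzymes ALT, AST,
ALP, GGT), which surfaces the proteins co-varying with liver damage markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .matrix import IntensityMatrix
from .tables import ClinicalTable, ValidationError

__all__ = [
    "CorrMap",
    "DEFAULT_ANCHORS",
    "build_corr_map",
    "pearson_p",
    "cluster_map",
    "anchor_cluster",
    "correlate_against",
]

DEFAULT_ANCHORS = ["ALT", "AST", "ALP", "GGT"]


@dataclass
class CorrMap:
    """Symmetric correlation structure over mixed protein+clinical variables."""

    kinds: pd.Series  # variable name -> "protein" | "clinical"
    r: pd.DataFrame  # symmetric Pearson coefficients, NaN where n < min_n
    n_pairs: pd.DataFrame  # pairwise-complete observation counts
    data: pd.DataFrame  # variables x subjects, used for clustering/targets
    min_n: int = 10
    linkage: np.ndarray | None = None
    clustered_vars: list[str] | None = None
    leaf_order: list[str] | None = None
    clusters: pd.Series | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.r.index)

    def to_frame(self) -> pd.DataFrame:
        return self.r


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson coefficient via the t transform, n-2 df."""
    if n < 3:
        raise ValidationError("pearson_p requires n >= 3")
    if abs(r) > 1:
        raise ValidationError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * stats.t.sf(abs(t), n - 2))


def build_corr_map(
    matrix: IntensityMatrix,
    clinical: ClinicalTable | None = None,
    min_n: int = 10,
) -> CorrMap:
    """Pairwise-complete Pearson correlation over proteins (+ clinical vars).

    The matrix is the log2, overall-completeness-filtered, NOT imputed
    protein matrix; clinical variables are joined on shared subject ids.
    Pairs with fewer than ``min_n`` complete observations are left missing.
    """
    matrix.require_scale("log2", "build_corr_map")
    genes = matrix.genes.reindex(matrix.values.index).fillna("")
    # unique variable names: display gene, falling back to the group id
    names, seen = [], set()
    for gid, gene in genes.items():
        name = gene if gene and gene not in seen else str(gid)
        seen.add(name)
        names.append(name)
    prot = matrix.values.copy()
    prot.index = names
    kinds = pd.Series("protein", index=prot.index)

    if clinical is not None:
        shared = [s for s in prot.columns if s in clinical.df.index]
        if not shared:
            raise ValidationError("no shared subjects between matrix and clinical table")
        clin = clinical.df.loc[shared].T  # variables x subjects
        prot = prot[shared]
        clash = set(clin.index) & set(prot.index)
        if clash:
            raise ValidationError(f"clinical variable names clash with genes: {sorted(clash)}")
        data = pd.concat([prot, clin])
        kinds = pd.concat([kinds, pd.Series("clinical", index=clin.index)])
    else:
        data = prot

    constant = data.std(axis=1, ddof=1).fillna(0) == 0
    if constant.any():
        warnings.warn(
            f"constant variables have undefined correlations: "
            f"{data.index[constant].tolist()[:5]}"
        )

    obs = data.notna()
    n_pairs = obs.astype(int) @ obs.astype(int).T
    r = data.T.corr(min_periods=min_n)  # pairwise-complete Pearson
    r = r.where(n_pairs >= min_n)
    diag_ok = np.diag(n_pairs.to_numpy()) >= 2
    rv = r.to_numpy()
    rv[np.diag_indices_from(rv)] = np.where(diag_ok, 1.0, np.nan)
    r = pd.DataFrame(rv, index=r.index, columns=r.columns)
    return CorrMap(kinds=kinds, r=r, n_pairs=n_pairs, data=data, min_n=min_n)


def cluster_map(
    cmap: CorrMap, linkage: str = "average", distance: str = "one_minus_r"
) -> CorrMap:
    """Agglomerative clustering of the correlation map on d = 1 - r.

    Variables with any missing correlation against the clustered set are
    dropped (greedily, most-missing first) with a warning; ties break by
    variable index so the result is order-independent up to relabeling.
    """
    if distance != "one_minus_r":
        raise ValidationError(f"unknown distance {distance!r}")
    r = cmap.r.copy()
    order = list(r.index)
    while True:
        off = r.isna().to_numpy()
        np.fill_diagonal(off, False)
        counts = off.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = int(np.argmax(counts))  # first index among ties
        name = r.index[worst]
        warnings.warn(f"dropping {name!r}: missing correlations against the map")
        r = r.drop(index=name, columns=name)
    keep = list(r.index)
    if len(keep) < 2:
        raise ValidationError("fewer than 2 fully-correlated variables to cluster")
    d = 1.0 - r.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    condensed = d[np.triu_indices(len(keep), k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return CorrMap(
        kinds=cmap.kinds,
        r=cmap.r,
        n_pairs=cmap.n_pairs,
        data=cmap.data,
        min_n=cmap.min_n,
        linkage=Z,
        clustered_vars=keep,
        leaf_order=[keep[i] for i in leaves],
        clusters=None,
    )


def anchor_cluster(cmap: CorrMap, anchors: Sequence[str]) -> pd.DataFrame:
    """Members of the smallest dendrogram node containing all anchors.

    Returns a frame with each member's kind and mean correlation to the other
    cluster members.
    """
    if cmap.linkage is None or cmap.clustered_vars is None:
        raise ValidationError("cluster_map must run before anchor_cluster")
    keep = cmap.clustered_vars
    missing = [a for a in anchors if a not in keep]
    if missing:
        raise ValidationError(f"anchors not in the clustered map: {missing}")
    if len(set(anchors)) == 1:
        members = [anchors[0]]
    else:
        anchor_idx = {keep.index(a) for a in anchors}
        tree = hierarchy.to_tree(cmap.linkage)

        def smallest(node):
            # descend while one child still holds every anchor
            while not node.is_leaf():
                left = set(node.get_left().pre_order())
                if anchor_idx <= left:
                    node = node.get_left()
                elif anchor_idx <= set(node.get_right().pre_order()):
                    node = node.get_right()
                else:
                    return node
            return node

        node = smallest(tree)
        members = [keep[i] for i in node.pre_order()]

    sub = cmap.r.loc[members, members].to_numpy()
    if len(members) > 1:
        np.fill_diagonal(sub, np.nan)
        mean_r = np.nanmean(sub, axis=1)
    else:
        mean_r = np.array([np.nan])
    return pd.DataFrame(
        {
            "kind": cmap.kinds.reindex(members).to_numpy(),
            "mean_within_r": mean_r,
        },
        index=pd.Index(members, name="variable"),
    )


def correlate_against(
    cmap: CorrMap, target: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate every protein with one target variable; BH across proteins."""
    if target not in cmap.data.index:
        raise ValidationError(f"target {target!r} not in the map")
    y = cmap.data.loc[target]
    if y.std(ddof=1) == 0 or y.dropna().nunique() <= 1:
        raise ValidationError(f"target {target!r} is constant")
    rows = []
    proteins = [v for v in cmap.data.index if cmap.kinds.get(v) == "protein"]
    for v in proteins:
        x = cmap.data.loc[v]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < max(3, cmap.min_n):
            rows.append((np.nan, n, np.nan))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append((r, n, pearson_p(r, n)))
    out = pd.DataFrame(rows, index=proteins, columns=["r", "n", "p"])
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        from .differential import bh_adjust

        q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = out["q"] < alpha
    return out.sort_values("p")
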