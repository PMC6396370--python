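"""IntensityMatrix: the proteins-by-samples object every pipeline stage transforms."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "ScaleError"]


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong scale."""


@dataclass
class IntensityMatrix:
    """Proteins x samples (or x subjects) quantification matrix.

    ``values`` is indexed by ``group_id`` with one column per sample or
    subject; ``NaN`` marks missing. ``scale`` is ``"linear"`` (strictly
    positive) or ``"log2"``. ``provenance`` is an append-only list of
    transformation records ``{"op": name, **params}``.
    """

    values: pd.DataFrame
    genes: pd.Series  # group_id -> display gene symbol
    scale: str = "linear"
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2", "unitless"):
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.scale == "linear":
            vals = self.values.to_numpy(dtype=float)
            if np.any(np.nan_to_num(vals, nan=1.0) <= 0):
                raise ScaleError("linear-scale matrix must be strictly positive")
        self.genes = self.genes.reindex(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def derive(
        self,
        values: pd.DataFrame,
        op: str,
        scale: str | None = None,
        **params: Any,
    ) -> "IntensityMatrix":
        """New matrix with one provenance record appended."""
        record = {"op": op, **params}
        return IntensityMatrix(
            values=values,
            genes=self.genes.reindex(values.index),
            scale=scale if scale is not None else self.scale,
            provenance=copy.deepcopy(self.provenance) + [record],
        )

    def require_scale(self, scale: str, op: str) -> None:
        if self.scale != scale:
            raise ScaleError(f"{op} requires a {scale}-scale matrix, got {self.scale}")
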