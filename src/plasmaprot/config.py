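"""Run configuration: one YAML file drives an end-to-end analysis.

Defaults carry the study parameters: s0 = 0.01, permutation FDR 0.05,
downshift 1.8 SD at width 0.3, 70% completeness, min 2 valid replicates,
|log2FC| >= 1 for the BH + fold-change route. Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import yaml

from .differential import Contrast
from .tables import ValidationError

__all__ = ["RunConfig", "validate_config", "load_config"]


DEFAULTS: dict[str, dict[str, Any]] = {
    "preprocess": {
        "min_valid": 2,
        "completeness_frac": 0.70,
        "shift": 1.8,
        "width": 0.3,
        "scope": "per_column",
        "aggregate": "median",
    },
    "differential": {
        "s0": 0.01,
        "fdr": 0.05,
        "n_permutations": 250,
        "anova_alpha": 0.05,
        "min_abs_log2fc": 1.0,
    },
    "correlation": {
        "min_n": 10,
        "linkage": "average",
        "anchors": ["ALT", "AST", "ALP", "GGT"],
    },
    "annotation": {"tissue": "liver", "ratio": 5.0},
}

TOP_KEYS = {
    "seed", "groups", "simulate", "inputs", "contrasts",
    "preprocess", "differential", "correlation", "annotation", "qc",
}
SIMULATE_KEYS = {
    "preset", "groups", "n_replicates", "n_proteins", "span_orders",
    "between_subject_sd_log2", "replicate_cv_target",
    "mnar_midpoint_log2", "mnar_steepness",
}
INPUT_KEYS = {"protein_groups", "sample_sheet", "clinical", "tissue_expression"}
CONTRAST_KEYS = {"name", "groups_a", "groups_b", "method"}


@dataclass
class RunConfig:
    seed: int
    groups: list[str]
    contrasts: list[Contrast]
    preprocess: dict[str, Any]
    differential: dict[str, Any]
    correlation: dict[str, Any]
    annotation: dict[str, Any]
    qc: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {sorted(unknown)}")


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Fill defaults, check cross-references, reject unknown keys."""
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    _check_keys(raw, TOP_KEYS, "config")
    if "seed" not in raw:
        raise ValidationError("seed is mandatory (simulation and imputation are stochastic)")
    seed = int(raw["seed"])

    simulate = raw.get("simulate")
    inputs = raw.get("inputs")
    if simulate is None and inputs is None:
        raise ValidationError("config needs either a 'simulate' block or 'inputs' paths")
    if simulate is not None:
        _check_keys(simulate, SIMULATE_KEYS, "simulate")
    if inputs is not None:
        _check_keys(inputs, INPUT_KEYS, "inputs")
        for k in ("protein_groups", "sample_sheet"):
            if k not in inputs:
                raise ValidationError(f"inputs must declare {k!r}")

    sections = {}
    for name, defaults in DEFAULTS.items():
        merged = dict(defaults)
        given = raw.get(name) or {}
        _check_keys(given, set(defaults), name)
        merged.update(given)
        sections[name] = merged
    pp = sections["preprocess"]
    if pp["width"] <= 0 or pp["shift"] < 0:
        raise ValidationError("imputation width must be > 0 and shift >= 0")
    if not 0 < pp["completeness_frac"] <= 1:
        raise ValidationError("completeness_frac must lie in (0, 1]")

    groups = list(raw.get("groups") or [])
    if not groups and simulate is not None:
        preset = simulate.get("preset", "human")
        from . import simulate as sim

        preset_cfg = {"human": sim.human_config, "mouse": sim.mouse_config,
                      "null": sim.null_config}.get(preset)
        if preset_cfg is None:
            raise ValidationError(f"unknown simulate preset {preset!r}")
        groups = list(simulate.get("groups") or preset_cfg().groups)

    diff = sections["differential"]
    contrasts = []
    for entry in raw.get("contrasts") or []:
        _check_keys(entry, CONTRAST_KEYS, f"contrast {entry.get('name', '?')!r}")
        for key in ("name", "groups_a", "groups_b"):
            if key not in entry:
                raise ValidationError(f"contrast lacks {key!r}")
        for side in ("groups_a", "groups_b"):
            bad = set(entry[side]) - set(groups)
            if bad:
                raise ValidationError(
                    f"contrast {entry['name']!r} references undeclared groups: {sorted(bad)}"
                )
        contrasts.append(
            Contrast(
                name=entry["name"],
                groups_a=frozenset(entry["groups_a"]),
                groups_b=frozenset(entry["groups_b"]),
                method=entry.get("method", "permutation_s0"),
                s0=diff["s0"],
                fdr=diff["fdr"],
                n_permutations=diff["n_permutations"],
                min_abs_log2fc=diff["min_abs_log2fc"],
                seed=seed,
            )
        )

    return RunConfig(
        seed=seed,
        groups=groups,
        contrasts=contrasts,
        preprocess=pp,
        differential=diff,
        correlation=sections["correlation"],
        annotation=sections["annotation"],
        qc=raw.get("qc") or {},
        simulate=simulate,
        inputs=inputs,
    )


def load_config(path: str) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
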