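"""Pipeline configuration: defaults, parsing and range validation.

The config file is a flat-ish YAML mapping mirroring the simulation
config types plus the pipeline tunables.  ``validate_config`` returns a
fully-defaulted :class:`PipelineConfig`, aggregating every unknown key
and out-of-range value into one error report.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "ConfigValidationError", "validate_config", "DEFAULTS"]


class ConfigValidationError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "quantify": True,
        "classify": True,
        "phenotype": True,
        "associate": True,
        "senescence": True,
        "mouse": True,
    },
    "inputs": {
        # optional externally supplied tables; empty string = use synthetic
        "junction_counts": "",
        "cohort": "",
        "expression": "",
        "senescence_qpcr": "",
        "mouse_panel": "",
        "gene_sets": "",
    },
    "quantify": {
        "min_bsj_reads": 2,
        "canonical_per_gene_once": False,
    },
    "classify": {
        "k_per_class": 5,
        "top_fraction": 0.10,
    },
    "associate": {
        "alpha": 0.05,
        "decimals": 3,
        "orientation_overrides": {},
    },
    "pool_sim": {
        "n_circ_total": 2207,
        "n_shared": 184,
        "n_young_only": 431,
        "n_old_only": 1592,
        "mean_bsj_reads": 100.0,
        "dispersion": 10.0,
        "canonical_mean": 500.0,
        "rnase_r_linear_retention": 0.05,
        "rnase_r_circ_enrichment": 5.0,
        "shared_log2fc_sd": 0.8,
    },
    "cohort_sim": {
        "n_participants": 306,
        "noise_sd": 0.25,
        "premature_fraction": 0.05,
        "parent_missing_fraction": 0.05,
        "planted_pls_beta": -0.065,
    },
    "senescence_sim": {
        "shift_ct": -1.0,
        "n_shifted": 5,
    },
    "mouse_sim": {
        "planted_young_spleen_slope": 0.01,
        "n_animals_per_group": 3,
    },
}

_RANGES: dict[str, tuple[float, float]] = {
    "quantify.min_bsj_reads": (0, 1_000_000),
    "classify.k_per_class": (1, 10_000),
    "classify.top_fraction": (1e-9, 1.0),
    "associate.alpha": (1e-12, 1.0),
    "associate.decimals": (0, 12),
    "pool_sim.n_circ_total": (0, 10_000_000),
    "pool_sim.n_shared": (0, 10_000_000),
    "pool_sim.n_young_only": (0, 10_000_000),
    "pool_sim.n_old_only": (0, 10_000_000),
    "pool_sim.mean_bsj_reads": (1e-9, 1e9),
    "pool_sim.dispersion": (1e-9, 1e9),
    "pool_sim.canonical_mean": (1e-9, 1e9),
    "pool_sim.rnase_r_linear_retention": (0.0, 1.0),
    "pool_sim.rnase_r_circ_enrichment": (1.0, 1e6),
    "pool_sim.shared_log2fc_sd": (0.0, 100.0),
    "cohort_sim.n_participants": (25, 10_000_000),
    "cohort_sim.noise_sd": (0.0, 1e9),
    "cohort_sim.premature_fraction": (1e-9, 1.0 - 1e-9),
    "cohort_sim.parent_missing_fraction": (0.0, 1.0),
    "senescence_sim.n_shifted": (0, 10_000),
    "mouse_sim.n_animals_per_group": (1, 10_000),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str) -> Any:
        node: Any = self.values
        for part in key.split("."):
            node = node[part]
        return node

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def semantic_hash(self) -> str:
        """sha256 over the canonical JSON of the semantic config values."""
        canonical = json.dumps(self.values, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()


def _walk(
    defaults: Mapping[str, Any],
    supplied: Mapping[str, Any],
    prefix: str,
    merged: dict[str, Any],
    problems: list[str],
) -> None:
    for key, value in supplied.items():
        dotted = f"{prefix}{key}"
        if key not in defaults:
            problems.append(f"unknown key: {dotted}")
            continue
        default = defaults[key]
        if isinstance(default, dict) and dotted not in (
            "associate.orientation_overrides",
        ):
            if not isinstance(value, Mapping):
                problems.append(f"{dotted}: expected a mapping")
                continue
            _walk(default, value, dotted + ".", merged[key], problems)
        else:
            if dotted in _RANGES and value is not None:
                lo, hi = _RANGES[dotted]
                try:
                    numeric = float(value)
                except (TypeError, ValueError):
                    problems.append(f"{dotted}: not a number ({value!r})")
                    continue
                if not lo <= numeric <= hi:
                    problems.append(f"{dotted}: value {value!r} outside [{lo}, {hi}]")
                    continue
            merged[key] = value


def validate_config(source: str | Path | Mapping[str, Any] | None = None) -> PipelineConfig:
    """Parse + validate a config file (YAML), mapping, or None (defaults).

    Unknown keys, unparseable values and out-of-range tunables are
    aggregated into a single :class:`ConfigValidationError`.  Non-empty
    input paths must exist.
    """
    if source is None:
        supplied: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        supplied = source
    else:
        text = Path(source).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigValidationError([f"config root must be a mapping, got {type(loaded).__name__}"])
        supplied = loaded

    merged = copy.deepcopy(DEFAULTS)
    problems: list[str] = []
    _walk(DEFAULTS, supplied, "", merged, problems)

    pool = merged["pool_sim"]
    if pool["n_shared"] + pool["n_young_only"] + pool["n_old_only"] != pool["n_circ_total"]:
        problems.append(
            "pool_sim: n_shared + n_young_only + n_old_only must equal n_circ_total"
        )
    for name, path in merged["inputs"].items():
        if path and not Path(path).exists():
            problems.append(f"inputs.{name}: path does not exist: {path}")
    if problems:
        raise ConfigValidationError(problems)
    return PipelineConfig(values=merged)
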