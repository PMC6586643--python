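"""Pipeline configuration.

One flat dataclass holds every tunable knob; :func:`load_config` reads the
nested YAML schema (``signal.mode``, ``cleavage.monobasic_mode``,
``spacer.min_acidic``, ``ptm.max_oxidations``, ``match.tolerance_ppm``, ...).
Precedence when running from the CLI is flag > YAML > built-in default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


@dataclass
class PipelineConfig:
    # --- signal region ---
    signal_mode: str = "heuristic"            # "heuristic" | "provided"
    signal_provided_map: dict[str, int] = field(default_factory=dict)
    # --- cleavage sites ---
    monobasic_mode: str = "strict"            # "strict" | "permissive" | "off"
    # --- acidic-spacer classification ---
    spacer_min_acidic: int = 3
    spacer_min_fraction: float = 0.25
    # --- PTM variant enumeration ---
    max_oxidations: int = 1
    max_deamidations: int = 1
    max_total_variants: int = 16
    apply_disulfide_mass: bool = False
    # --- MS matching ---
    min_peptide_len: int = 8                  # detectability window, inclusive
    max_peptide_len: int = 22
    tolerance_ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.signal_mode not in ("heuristic", "provided"):
            raise ValueError(f"unknown signal mode {self.signal_mode!r}")
        if self.monobasic_mode not in ("strict", "permissive", "off"):
            raise ValueError(f"unknown monobasic mode {self.monobasic_mode!r}")


_YAML_KEYMAP = {
    ("signal", "mode"): "signal_mode",
    ("signal", "provided_map"): "signal_provided_map",
    ("cleavage", "monobasic_mode"): "monobasic_mode",
    ("spacer", "min_acidic"): "spacer_min_acidic",
    ("spacer", "min_fraction"): "spacer_min_fraction",
    ("ptm", "max_oxidations"): "max_oxidations",
    ("ptm", "max_deamidations"): "max_deamidations",
    ("ptm", "max_total_variants"): "max_total_variants",
    ("ptm", "apply_disulfide_mass"): "apply_disulfide_mass",
    ("match", "min_len"): "min_peptide_len",
    ("match", "max_len"): "max_peptide_len",
    ("match", "tolerance_ppm"): "tolerance_ppm",
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, object] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file plus overrides."""
    kwargs: dict[str, object] = {}
    if path is not None:
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for section, values in data.items():
            if not isinstance(values, dict):
                raise ValueError(f"{path}: section {section!r} must be a mapping")
            for key, value in values.items():
                name = _YAML_KEYMAP.get((section, key))
                if name is None:
                    raise ValueError(f"{path}: unknown config key {section}.{key}")
                kwargs[name] = value
    if overrides:
        valid = {f.name for f in dataclasses.fields(PipelineConfig)}
        for key, value in overrides.items():
            if key not in valid:
                raise ValueError(f"unknown config override {key!r}")
            if value is not None:
                kwargs[key] = value
    return PipelineConfig(**kwargs)
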