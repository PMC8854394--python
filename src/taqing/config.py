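"""Run configuration: one structured YAML file covering every tunable.

Unknown keys are rejected so typos never silently fall back to defaults;
missing keys take the documented default.  ``effective_config`` echoes the
fully-resolved configuration for the output directory.
"""

from __future__ import annotations

import copy
from typing import Dict, Optional

import yaml

from .errors import ConfigError

DEFAULTS: Dict = {
    "seed": 0,
    "genome": {
        "n_chromosomes": 6,
        "chrom_length": 300_000,
        "ploidy": 3,
        "base_probs": [0.25, 0.25, 0.25, 0.25],
        "het_snv_rate": 2e-3,
        "het_indel_rate": 2e-4,
        "pattern": "two-alike",
        "telomere_unit": "GGGTGTCT",
        "telomere_units": [5, 20],
    },
    "events": {
        # the default scenario: every rearrangement class is represented
        "TL": 1, "DEL": 2, "BIR": 2, "GCV": 3,
        "ANEUPLOIDY": 1, "PARTIAL_DUP": 1,
        "min_het_sites": 10,
    },
    "evidence": {
        "depth_per_copy": 30.0,
        "window": 5_000,
        "error_rate": 0.01,
        "junction_capture": 0.5,
        "read_length": 150,
        "jitter": 0,
    },
    "junction": {
        "max_gap": 10,
        "min_support": 3,
        "min_size": 1_000,
        "motif_window": 5,
        "require_motif": "any",
    },
    "dosage": {
        "min_windows": 2,
        "arm_fraction": 0.10,
        "min_depth": 10,
        "margin_threshold": 2.0,
        "max_gap": 20_000,
        "min_sites": 5,
        "end_tolerance": 10_000,
    },
    "score": {"pos_tolerance": 25_000},
}


def _merge(defaults: Dict, override: Dict, path: str = "") -> Dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {where} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str] = None, overrides: Optional[Dict] = None
                ) -> Dict:
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def write_config(cfg: Dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
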