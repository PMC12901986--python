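"""Run configuration: every stage default in one validated structure.

Config files are YAML with one mapping per stage (flat key/value within a
stage). Unknown stages or keys are rejected before anything runs, and the
merged configuration is serialized verbatim into each run's output
directory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["RunConfig", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "global": {
        "seed": 0,
        "outdir": "run_output",
        "log_level": "INFO",
    },
    "stages": {
        "simulate": True,
        "auc": True,
        "integrity": True,
        "spikenorm": True,
        "dipcall": True,
    },
    "simulate": {
        "n_transcripts": 120,
        "biotype_fractions": {
            "protein_coding": 0.75,
            "mito_mRNA": 0.08,
            "nuclear_ncRNA": 0.12,
            "spike_in": 0.05,
        },
        "n_spikeins": 92,
        "seq_length_range": [800, 2000],
        "abundance_mu": 4.0,
        "abundance_sigma": 1.0,
        "site_density_per_kb": 3.0,
        "loop_mask_fraction": 0.35,
        "class_multiplier_pc": 0.06,
        "abundance_slope": 0.0,
        "timepoints": [0, 200],
        "n_molecules_scale": 0.5,
        "read_depth": 0.5,
        "full_length_prob": 0.2,
        "depletion_log2fc": -1.0,
        "n_replicates": 3,
        "nb_dispersion": 0.05,
        "cq_noise_sd": 0.15,
        "qpcr_efficiency": 0.95,
    },
    "auc": {
        "region": [200.0, 1700.0],
        "normalize": True,
    },
    "integrity": {},
    "spikenorm": {
        "pseudocount": 0.5,
        "min_count": 5.0,
        "timepoint": 200,
        "threshold": None,
        "control_condition": "non_targeting",
    },
    "dipcall": {
        "smooth_window": 5,
        "baseline_window": 50,
        "depth_ratio_threshold": 0.5,
        "width_min": 8,
        "width_max": 30,
        "edge_exclusion": 25,
        "min_mean_depth": 20.0,
        "upstream_search": 5,
        "flank": 5,
    },
}


def _check_keys(defaults: dict, given: dict, path: str = "") -> None:
    for key, value in given.items():
        if key not in defaults:
            raise ValidationError(f"unknown config key {path + str(key)!r}")
        if isinstance(defaults[key], dict) and not path.startswith("simulate"):
            if not isinstance(value, dict):
                raise ValidationError(
                    f"config key {path + str(key)!r} must be a mapping"
                )
            _check_keys(defaults[key], value, path=f"{path}{key}.")


def _merge(defaults: dict, given: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        if isinstance(out.get(key), dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        _check_keys(DEFAULT_CONFIG, overrides)
        return cls(_merge(DEFAULT_CONFIG, overrides))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(overrides)

    def __getitem__(self, stage: str) -> dict:
        return self.data[stage]

    @property
    def seed(self) -> int:
        return int(self.data["global"]["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.data["global"]["outdir"])

    def stage_enabled(self, stage: str) -> bool:
        return bool(self.data["stages"].get(stage, False))

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)
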