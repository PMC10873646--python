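"""Pipeline configuration: defaults, validation and YAML round-trip."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "paths": {"out_dir": "results"},
    "imaging": {
        "csat_nM": 40.0,
        "partition_ratio": 7.5,
        "condensate_radius_um": 0.5,
        "psf_sigma_um": 0.15,
        "pixel_size_um": 0.1,
    },
    "detection": {"k_sigma": 3.0, "min_size": 4},
    "phase": {"n_bootstrap": 1000, "zero_level": 0.02},
    "fusion": {"rms_tolerance": 0.1, "n_events": 14, "frame_interval_s": 0.5},
    "coloc": {"rule": "centroid", "min_overlap": 0.5},
    "timecourse": {"epsilon": 0.05},
    "qpcr": {"reference_gene": "ACTB"},
    "de": {"p_threshold": 0.01, "lfc_threshold": 0.58, "fdr_threshold": 0.1},
}

_NUMERIC_POSITIVE = {
    ("imaging", "csat_nM"), ("imaging", "partition_ratio"),
    ("imaging", "pixel_size_um"), ("detection", "k_sigma"),
    ("phase", "n_bootstrap"), ("de", "p_threshold"),
    ("de", "lfc_threshold"), ("de", "fdr_threshold"),
}


@dataclass
class PipelineConfig:
    """Nested parameter blocks with spec-level defaults.

    Unknown keys are rejected at load time so typos surface as errors
    naming the offending field.
    """

    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def validate(self) -> None:
        for block, sub in self.params.items():
            if block not in DEFAULTS:
                raise ValueError(f"unknown config block {block!r}")
            if isinstance(DEFAULTS[block], dict):
                for k in sub:
                    if k not in DEFAULTS[block]:
                        raise ValueError(f"unknown config field {block}.{k}")
        for block, key in _NUMERIC_POSITIVE:
            v = self.params.get(block, {}).get(key, DEFAULTS[block][key])
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"config field {block}.{key} must be a positive number")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        params = copy.deepcopy(DEFAULTS)
        for block, sub in user.items():
            if isinstance(sub, dict) and isinstance(params.get(block), dict):
                params[block].update(sub)
            else:
                params[block] = sub
        cfg = cls(params=params)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=False)
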