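"""Run configuration: one structured YAML file drives the whole pipeline.

Every statistical threshold carries its study default (fold-change 1.5,
q < 0.05, >10 RPKM in >= 2 samples, OD->DCW factor 0.23); stage logic never
hard-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "gasferm_out"
    # simulation
    noise_sd: float = 0.02
    stripped_fraction: float = 0.05
    n_genes: int = 2000
    n_timepoints: int = 25
    working_volume_L: float = 0.75
    # off-gas analysis
    molar_volume_mL_mmol: float = 22.414
    window_residence_times: float = 4.0
    cv_threshold: float = 0.02
    # bioprocess
    od_to_dcw: float = 0.23
    biomass_cmol_per_gdcw: float = 0.0417
    q_cysteine: float = 0.0
    henry_M_atm: float = 0.0246
    pka1: float = 6.30
    # flux model
    flux_tolerance: float = 0.02
    # transcriptomics
    fc_threshold: float = 1.5
    q_threshold: float = 0.05
    rpkm_threshold: float = 10.0
    rpkm_min_samples: int = 2
    slope_alpha: float = 0.05
    # DEG simulation
    deg_n_up: int = 100
    deg_n_down: int = 100
    deg_slope: float = 1.0
    deg_dispersion: float = 0.005

    def validate(self) -> "RunConfig":
        positive = ["n_genes", "n_timepoints", "working_volume_L",
                    "molar_volume_mL_mmol", "od_to_dcw",
                    "biomass_cmol_per_gdcw", "fc_threshold"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ["noise_sd", "stripped_fraction", "q_threshold",
                     "slope_alpha", "flux_tolerance", "cv_threshold"]:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be a non-negative 31-bit integer")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config (or defaults) and apply keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()
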