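"""YAML run configuration: substrate + parameters + scenario in one file.

A config round-trips losslessly and rejects unknown keys, so a run is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json

import yaml

from .params import ModelParams
from .substrate import SubstrateSpec, make_dna_srs

_TOP_KEYS = {"substrate", "params", "scenario", "n_dna", "seed", "outdir",
             "sweep", "label"}
_SUBSTRATE_KEYS = {"length_bp", "srs_offset_bp", "srs_length_bp", "triplex",
                   "label"}
_SWEEP_KEYS = {"preset", "parameter", "values", "statistic", "replicates",
               "n_dna", "base_seed"}


class ConfigError(ValueError):
    pass


class RunConfig:
    """One simulation (or sweep) specification."""

    def __init__(self, substrate: dict | None = None, params: dict | None = None,
                 scenario: str = "no_atp", n_dna: int = 1000, seed: int = 0,
                 outdir: str = ".", sweep: dict | None = None, label: str = ""):
        self.substrate = dict(substrate or {})
        self.params_dict = dict(params or {})
        self.scenario = scenario
        self.n_dna = int(n_dna)
        self.seed = int(seed)
        self.outdir = outdir
        self.sweep = dict(sweep) if sweep else None
        self.label = label
        self._validate_keys()

    def _validate_keys(self):
        bad = set(self.substrate) - _SUBSTRATE_KEYS
        if bad:
            raise ConfigError(f"unknown substrate keys: {sorted(bad)}")
        bad = set(self.params_dict) - set(ModelParams.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown params keys: {sorted(bad)}")
        if self.sweep is not None:
            bad = set(self.sweep) - _SWEEP_KEYS
            if bad:
                raise ConfigError(f"unknown sweep keys: {sorted(bad)}")

    # -- materialization --------------------------------------------------

    def build_spec(self) -> SubstrateSpec:
        return make_dna_srs(**self.substrate)

    def build_params(self) -> ModelParams:
        return ModelParams.from_dict(self.params_dict) if self.params_dict \
            else ModelParams()

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = {"substrate": self.substrate, "params": self.params_dict,
             "scenario": self.scenario, "n_dna": self.n_dna,
             "seed": self.seed, "outdir": self.outdir, "label": self.label}
        if self.sweep is not None:
            d["sweep"] = self.sweep
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        bad = set(d) - _TOP_KEYS
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(substrate=d.get("substrate"), params=d.get("params"),
                   scenario=d.get("scenario", "no_atp"),
                   n_dna=d.get("n_dna", 1000), seed=d.get("seed", 0),
                   outdir=d.get("outdir", "."), sweep=d.get("sweep"),
                   label=d.get("label", ""))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path} is not a mapping")
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable content hash recorded in run outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
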