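"""Model parameters of the SpoIIIE/DNA lattice model.

All event probabilities are per Monte Carlo step (MCS) and dimensionless;
sliding lengths are in base pairs; the translocation velocity is in bp/s and
is converted to a per-MCS step through the time calibration ``dt`` (s/MCS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict


class ParameterError(ValueError):
    """Raised when a parameter set violates its constraints."""


@dataclass(frozen=True)
class ModelParams:
    """One complete parameter set.

    Defaults are the published values reproducing the AFM and
    triplex-displacement experiments: equal association on SRS and
    non-specific DNA (0.022/MCS), ~2.3-fold slower dissociation from SRS
    (0.006 vs 0.014), anomalous sliding (145 +/- 36 bp on non-specific DNA,
    1.0 +/- 0.25 bp on SRS), ATP activation 0.012/MCS on non-specific sites
    (equal on SRS unless overridden), translocation at 5 kb/s, unbiased
    direction choice (p_dir = 0.5) and certain triplex displacement
    (p_triplex = 1).
    """

    p_on_srs: float = 0.022
    p_on_ns: float = 0.022
    p_off_srs: float = 0.006
    p_off_ns: float = 0.014
    p_atp_srs: float = 0.012
    p_atp_ns: float = 0.012
    p_dir: float = 0.5
    p_triplex: float = 1.0
    sld_srs_mean: float = 1.0
    sld_srs_sd: float = 0.25
    sld_ns_mean: float = 145.0
    sld_ns_sd: float = 36.0
    v_trans: float = 5000.0          # bp per second
    dt: float = 0.07                 # seconds per MCS
    equilibration_mcs: int = 2000
    sampling_mcs: int = 1000

    def __post_init__(self):
        for name in ("p_on_srs", "p_on_ns", "p_off_srs", "p_off_ns",
                     "p_atp_srs", "p_atp_ns", "p_dir", "p_triplex"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} = {v} outside [0, 1]")
        for name in ("sld_srs_mean", "sld_srs_sd", "sld_ns_mean", "sld_ns_sd",
                     "v_trans"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.equilibration_mcs < 0 or self.sampling_mcs < 1:
            raise ParameterError("invalid equilibration/sampling window")

    @property
    def v_step(self) -> int:
        """Translocation step in bp per MCS (deterministic, uniform)."""
        return int(round(self.v_trans * self.dt))

    def require_v_step(self) -> int:
        v = self.v_step
        if self.v_trans > 0 and v < 1:
            raise ParameterError(
                f"v_trans = {self.v_trans} bp/s with dt = {self.dt} s/MCS "
                "gives a sub-site translocation step; increase dt or v_trans"
            )
        return v

    def evolve(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def table_defaults() -> ModelParams:
    """The published optimal parameter set."""
    return ModelParams()
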