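"""Run configuration: structured YAML in, validated objects out.

The interface units are the ones experimentalists use (eV, fs); conversion
to atomic units happens inside the pulse/propagator objects.  Defaults
follow the reference propagation parameters: 0.3 fs nuclear step, 51
electronic substeps, 14.1 fs total time, 0.5 eV energy-conservation
tolerance, PFM decoherence with omega = 4.825e-3 hartree and population
threshold 1e-4.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .presets import model_from_config
from .propagator import DecoherenceConfig, PropagatorConfig
from .pulse import GaussianPulse

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Complete specification of a sampling + propagation + analysis run."""

    model: dict = field(default_factory=lambda: {"preset": "two_state_crossing"})
    wigner: dict = field(default_factory=lambda: {"n_geometries": 100, "seed": 2024})
    pulses: list = field(
        default_factory=lambda: [
            {"omega_L_eV": 7.05, "delta_omega_eV": 2.83,
             "polarization": [0.0, 0.0, 1.0], "amplitude": 1.0}
        ]
    )
    propagation: dict = field(
        default_factory=lambda: {
            "dt_fs": 0.3, "n_substeps": 51, "t_final_fs": 14.1,
            "energy_tolerance_eV": 0.5, "seed": 7,
        }
    )
    decoherence: dict = field(
        default_factory=lambda: {
            "scheme": "pfm", "omega_pfm": 4.825e-3, "eta": 1e-4, "edc_C": 0.1,
        }
    )
    ensemble: dict = field(default_factory=lambda: {"scheme": "axe", "windows_eV": None})
    output: dict = field(default_factory=lambda: {"dir": "run_output"})

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config sections: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    # -- materialized objects ----------------------------------------------
    def build_model(self):
        return model_from_config(self.model)

    def build_pulses(self) -> list[GaussianPulse]:
        return [
            GaussianPulse.from_ev(
                p["omega_L_eV"],
                p["delta_omega_eV"],
                p.get("polarization", (0, 0, 1)),
                p.get("amplitude", 1.0),
            )
            for p in self.pulses
        ]

    def build_propagator_config(self) -> PropagatorConfig:
        p = self.propagation
        return PropagatorConfig(
            dt_fs=p.get("dt_fs", 0.3),
            n_substeps=p.get("n_substeps", 51),
            t_final_fs=p.get("t_final_fs", 14.1),
            energy_tolerance_ev=p.get("energy_tolerance_eV", 0.5),
            seed=p.get("seed", 0),
        )

    def build_decoherence_config(self) -> DecoherenceConfig:
        d = self.decoherence
        return DecoherenceConfig(
            scheme=d.get("scheme", "pfm"),
            omega_pfm=d.get("omega_pfm", 4.825e-3),
            eta=d.get("eta", 1e-4),
            edc_C=d.get("edc_C", 0.1),
        )


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)
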