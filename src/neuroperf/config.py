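"""Schema-validated experiment configuration and parameter provenance.

The configuration mirrors the physical experiment: device geometry, pump
flow rates, fluid properties, the perfusion/imaging protocol, and the
analysis parameters.  Several numeric defaults reconstruct quantities the
original protocol leaves unstated; each such default is marked
``reconstructed: true`` in the provenance block emitted with every report
so downstream users can tell reported facts from reconstructions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .events import DetectorParams
from .perfusion import DeviceGeometry, FlowSetup, FluidProperties
from .synthetic import NeuronModel, Protocol, Segment

__all__ = ["DoseResponseConfig", "ExperimentConfig", "provenance_block"]

_DEFAULT_PROTOCOL = Protocol(
    frame_rate=2.0,
    segments=(
        Segment(label="baseline", duration_s=300.0),
        Segment(label="drug", duration_s=300.0, compound="glutamate", concentration_M=3e-6),
        Segment(label="wash", duration_s=120.0),
        Segment(label="kcl", duration_s=60.0, compound="KCl", concentration_M=25e-3),
    ),
)


class DoseResponseConfig(BaseModel):
    """Synthetic concentration–response study settings (half-decade grid)."""

    model_config = ConfigDict(frozen=True)

    concentrations_M: tuple[float, ...] = (
        1e-8, 3.16e-8, 1e-7, 3.16e-7, 1e-6, 3.16e-6, 1e-5, 3.16e-5, 1e-4, 3.16e-4, 1e-3,
    )
    r_max: float = Field(default=1.0, gt=0)
    ec50_M: float = Field(default=4.7e-6, gt=0)
    hill_n: float = Field(default=1.2, gt=0)
    n_neurons_per_conc: int = Field(default=50, ge=1)
    noise_sd: float = Field(default=0.05, ge=0)


class ExperimentConfig(BaseModel):
    """Full pipeline configuration: device, flow, protocol, analysis, seeds."""

    model_config = ConfigDict(frozen=True)

    geometry: DeviceGeometry = DeviceGeometry()
    flow: FlowSetup = FlowSetup()
    fluid: FluidProperties = FluidProperties()
    protocol: Protocol = _DEFAULT_PROTOCOL
    detector: DetectorParams = DetectorParams()
    neuron: NeuronModel = NeuronModel()
    n_neurons: int = Field(default=50, ge=1)
    dose_response: Optional[DoseResponseConfig] = None
    hrt_s: float = Field(default=25.0, gt=0)  # treated as a given protocol input
    distance_mm: float = Field(default=4.75, ge=0)
    seed: int = Field(default=0, ge=0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def provenance_block(config: ExperimentConfig) -> dict:
    """Numeric defaults annotated with their origin.

    ``reported`` values come from the published device/protocol description;
    ``reconstructed`` values fill gaps the protocol leaves unstated (pump
    injection rate, working well volume, fluid properties, detector rule
    thresholds, transient kinetics).
    """
    g, f, fl, d = config.geometry, config.flow, config.fluid, config.detector
    return {
        "chamber_height_um": {"value": g.chamber_height_um, "reconstructed": False},
        "chamber_width_mm": {"value": g.chamber_width_mm, "reconstructed": False},
        "chamber_length_mm": {"value": g.chamber_length_mm, "reconstructed": False},
        "microchannel_dims_um": {
            "value": [g.microchannel_height_um, g.microchannel_width_um, g.microchannel_length_um],
            "reconstructed": False,
        },
        "q_chamber_ul_min": {
            "value": f.q_injection_ul_min - f.q_inlet_withdraw_ul_min,
            "reconstructed": False,
        },
        "q_injection_ul_min": {"value": f.q_injection_ul_min, "reconstructed": True},
        "inlet_well_volume_ul": {"value": f.inlet_well_volume_ul, "reconstructed": True},
        "hrt_s": {"value": config.hrt_s, "reconstructed": False},
        "fluid_density_kg_m3": {"value": fl.density_kg_m3, "reconstructed": True},
        "fluid_viscosity_pa_s": {"value": fl.dynamic_viscosity_pa_s, "reconstructed": True},
        "solute_diffusivity_m2_s": {"value": fl.diffusivity_m2_s, "reconstructed": True},
        "frame_rate_hz": {"value": config.protocol.frame_rate, "reconstructed": False},
        "filter_window_frames": {"value": d.filter_window, "reconstructed": False},
        "baseline_frames": {"value": d.baseline_frames, "reconstructed": False},
        "detector_k_sd": {"value": d.k_sd, "reconstructed": False},
        "detector_window_s": {"value": d.window_s, "reconstructed": False},
        "kcl_rule_thresholds": {
            "value": {"k_kcl": 5.0, "immediate_window_s": 10.0, "sustain_fraction": 0.8},
            "reconstructed": True,
        },
        "transient_taus_s": {
            "value": [config.neuron.rise_tau_s, config.neuron.decay_tau_s],
            "reconstructed": True,
        },
    }
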