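"""Hydrodynamics of the dual-chamber perfusion device.

The device perfuses one culture chamber with a steady flow rate Q_Ch set by
three syringe pumps: an injection pump into the inlet well (Q_inj), a
withdrawal pump at the inlet well (Q_iw) and a withdrawal pump at the outlet
well (Q_ow).  A stable chamber flow requires

    Q_inj > Q_iw >> Q_ow          (ordering)
    Q_inj - Q_iw = Q_Ch = Q_ow    (balance)

which together produce a self-adjusting hydrostatic pressure difference
between inlet and outlet wells.  Solution exchange at a point a distance L
down the chamber is characterised by

    T_ex ≈ HRT + S_Ch · L / Q_Ch

where HRT = V_well / Q_inj is the hydraulic retention time of the inlet well
and S_Ch the chamber cross-section.  Reynolds and Péclet numbers verify that
the flow is laminar (Re < 1) and advection-dominated (Pe > 100).

Unit conventions: flow rates in μl·min⁻¹ (= mm³·min⁻¹), volumes in μl,
lengths in the units their field names state (μm or mm), times in seconds,
fluid properties in SI.  Conversions are centralised in the helpers below.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import BalanceError, DomainError, ValidationError

__all__ = [
    "DeviceGeometry",
    "FlowSetup",
    "FluidProperties",
    "chamber_flow_rate",
    "hydraulic_retention_time",
    "exchange_time",
    "mean_velocity",
    "reynolds_number",
    "peclet_number",
    "advection_delay",
    "simulate_pulse_profile",
]

#: mm³·min⁻¹ (= μl·min⁻¹) → m³·s⁻¹
_MM3_MIN_TO_M3_S = 1e-9 / 60.0
_MM_TO_M = 1e-3
_MM2_TO_M2 = 1e-6


class DeviceGeometry(BaseModel):
    """Dimensions of one culture chamber, its wells and the microchannel array.

    Defaults reproduce the study device: 80 μm × 2 mm × 9.5 mm chambers,
    4 mm diameter punched wells, 7 μm × 10 μm × 450 μm microchannels.
    """

    model_config = ConfigDict(frozen=True)

    chamber_height_um: float = Field(default=80.0, gt=0)
    chamber_width_mm: float = Field(default=2.0, gt=0)
    chamber_length_mm: float = Field(default=9.5, gt=0)
    well_diameter_mm: float = Field(default=4.0, gt=0)
    microchannel_height_um: float = Field(default=7.0, gt=0)
    microchannel_width_um: float = Field(default=10.0, gt=0)
    microchannel_length_um: float = Field(default=450.0, gt=0)

    @property
    def chamber_cross_section_mm2(self) -> float:
        """S_Ch = height × width, in mm²."""
        return (self.chamber_height_um * 1e-3) * self.chamber_width_mm

    @property
    def chamber_hydraulic_diameter_m(self) -> float:
        """D_h = 2wh/(w+h) for the rectangular chamber section, in metres."""
        w = self.chamber_width_mm * _MM_TO_M
        h = self.chamber_height_um * 1e-6
        return 2.0 * w * h / (w + h)


class FlowSetup(BaseModel):
    """Commanded pump rates (μl·min⁻¹) and the inlet-well working volume (μl).

    Defaults are a reconstruction that jointly reproduces the study's
    HRT ≈ 25 s and Q_Ch = 4 μl·min⁻¹; the injection rate and working well
    volume during perfusion are not printed in the source protocol.
    """

    model_config = ConfigDict(frozen=True)

    q_injection_ul_min: float = Field(default=24.0, gt=0)
    q_inlet_withdraw_ul_min: float = Field(default=20.0, gt=0)
    q_outlet_withdraw_ul_min: float = Field(default=4.0, gt=0)
    inlet_well_volume_ul: float = Field(default=10.0, gt=0)


class FluidProperties(BaseModel):
    """Perfusate physical properties (SI). Defaults: water + small solute."""

    model_config = ConfigDict(frozen=True)

    density_kg_m3: float = Field(default=1000.0, gt=0)
    dynamic_viscosity_pa_s: float = Field(default=1.0e-3, gt=0)
    diffusivity_m2_s: float = Field(default=1.0e-9, gt=0)


def chamber_flow_rate(
    setup: FlowSetup,
    *,
    dominance_factor: float = 5.0,
    balance_rtol: float = 0.01,
) -> float:
    """Chamber flow rate Q_Ch = Q_inj − Q_iw (μl·min⁻¹), after validation.

    Raises :class:`ValidationError` if the pump ordering Q_inj > Q_iw or the
    dominance condition Q_iw ≥ dominance_factor × Q_ow fails, and
    :class:`BalanceError` if Q_inj − Q_iw differs from Q_ow by more than
    ``balance_rtol`` relative to Q_ow.
    """
    qi, qw, qo = (
        setup.q_injection_ul_min,
        setup.q_inlet_withdraw_ul_min,
        setup.q_outlet_withdraw_ul_min,
    )
    if not qi > qw:
        raise ValidationError(
            f"pump ordering violated: Q_injection ({qi}) must exceed "
            f"Q_inlet_withdraw ({qw})"
        )
    if not qw >= dominance_factor * qo:
        raise ValidationError(
            f"pump ordering violated: Q_inlet_withdraw ({qw}) must be >= "
            f"{dominance_factor} x Q_outlet_withdraw ({qo})"
        )
    q_ch = qi - qw
    if abs(q_ch - qo) > balance_rtol * qo:
        raise BalanceError(
            f"flow balance violated: Q_injection - Q_inlet_withdraw = {q_ch} "
            f"but Q_outlet_withdraw = {qo}"
        )
    return q_ch


def hydraulic_retention_time(inlet_well_volume_ul: float, q_injection_ul_min: float) -> float:
    """HRT = V_well / Q_inj, in seconds."""
    if inlet_well_volume_ul <= 0 or q_injection_ul_min <= 0:
        raise DomainError("well volume and injection rate must be positive")
    return 60.0 * inlet_well_volume_ul / q_injection_ul_min


def exchange_time(
    hrt_s: float,
    geometry: DeviceGeometry,
    distance_mm: float,
    q_chamber_ul_min: float,
) -> float:
    """Solution exchange time T_ex ≈ HRT + S_Ch·L/Q_Ch, in seconds.

    ``distance_mm`` is the along-flow distance L from the inlet well; it must
    not exceed the chamber length.
    """
    if hrt_s < 0:
        raise DomainError("HRT must be non-negative")
    if distance_mm < 0 or distance_mm > geometry.chamber_length_mm:
        raise DomainError(
            f"distance L = {distance_mm} mm outside [0, {geometry.chamber_length_mm}] mm"
        )
    if q_chamber_ul_min <= 0:
        raise DomainError("chamber flow rate must be positive")
    return hrt_s + 60.0 * geometry.chamber_cross_section_mm2 * distance_mm / q_chamber_ul_min


def mean_velocity(geometry: DeviceGeometry, q_chamber_ul_min: float) -> float:
    """Mean chamber velocity v = Q_Ch / S_Ch, in m·s⁻¹."""
    if q_chamber_ul_min < 0:
        raise DomainError("flow rate must be non-negative")
    q_m3_s = q_chamber_ul_min * _MM3_MIN_TO_M3_S
    s_m2 = geometry.chamber_cross_section_mm2 * _MM2_TO_M2
    return q_m3_s / s_m2


def reynolds_number(
    geometry: DeviceGeometry,
    q_chamber_ul_min: float,
    fluid: FluidProperties,
) -> float:
    """Re = ρ·v·D_h/μ using the chamber's hydraulic diameter."""
    v = mean_velocity(geometry, q_chamber_ul_min)
    return (
        fluid.density_kg_m3 * v * geometry.chamber_hydraulic_diameter_m
        / fluid.dynamic_viscosity_pa_s
    )


def peclet_number(
    geometry: DeviceGeometry,
    q_chamber_ul_min: float,
    fluid: FluidProperties,
    characteristic_length_mm: float,
) -> float:
    """Pe = v·L_c/D with the along-flow distance as characteristic length."""
    if characteristic_length_mm < 0:
        raise DomainError("characteristic length must be non-negative")
    v = mean_velocity(geometry, q_chamber_ul_min)
    return v * characteristic_length_mm * _MM_TO_M / fluid.diffusivity_m2_s


def advection_delay(
    geometry: DeviceGeometry, distance_mm: float, q_chamber_ul_min: float
) -> float:
    """Plug-flow travel time S_Ch·L/Q_Ch from the well to a point L, seconds."""
    if q_chamber_ul_min <= 0:
        raise DomainError("chamber flow rate must be positive")
    if distance_mm < 0 or distance_mm > geometry.chamber_length_mm:
        raise DomainError("distance outside chamber")
    return 60.0 * geometry.chamber_cross_section_mm2 * distance_mm / q_chamber_ul_min


def simulate_pulse_profile(
    schedule: Sequence[tuple[float, float]],
    times_s: np.ndarray,
    setup: FlowSetup,
    geometry: DeviceGeometry,
    distance_mm: float,
) -> np.ndarray:
    """Concentration at a point L down the chamber for a pump-switch schedule.

    ``schedule`` is a list of ``(switch_time_s, source_concentration)`` pairs:
    from each switch time the inlet well is fed with the given source
    concentration.  The well is treated as well-mixed with first-order
    exchange at time constant HRT, and the chamber as plug flow, so the
    concentration at L is the well concentration delayed by the advection
    time S_Ch·L/Q_Ch.  Before the first switch the source (and the well) is
    at concentration zero.

    Returns the concentration at each entry of ``times_s``; the output is
    bounded by [0, max source concentration].
    """
    if len(schedule) == 0:
        return np.zeros_like(np.asarray(times_s, dtype=float))
    sw_t = np.asarray([s[0] for s in schedule], dtype=float)
    sw_c = np.asarray([s[1] for s in schedule], dtype=float)
    if np.any(np.diff(sw_t) <= 0):
        raise ValidationError("schedule switch times must be strictly increasing")
    if np.any(sw_c < 0):
        raise ValidationError("source concentrations must be non-negative")

    tau = hydraulic_retention_time(setup.inlet_well_volume_ul, setup.q_injection_ul_min)
    q_ch = chamber_flow_rate(setup)
    delay = advection_delay(geometry, distance_mm, q_ch)

    # well concentration at each switch time, propagated piecewise-analytically
    w_at_switch = np.empty_like(sw_t)
    w_at_switch[0] = 0.0
    for k in range(len(sw_t) - 1):
        dt = sw_t[k + 1] - sw_t[k]
        w_at_switch[k + 1] = sw_c[k] + (w_at_switch[k] - sw_c[k]) * np.exp(-dt / tau)

    ts = np.asarray(times_s, dtype=float) - delay
    out = np.zeros_like(ts)
    active = ts >= sw_t[0]
    idx = np.searchsorted(sw_t, ts[active], side="right") - 1
    out[active] = sw_c[idx] + (w_at_switch[idx] - sw_c[idx]) * np.exp(
        -(ts[active] - sw_t[idx]) / tau
    )
    return np.clip(out, 0.0, sw_c.max(initial=0.0))
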