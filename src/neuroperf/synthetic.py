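"""Synthetic assays with known ground truth for recovery testing.

No recordings from the original experiments are redistributable, so this
module generates data with the statistical structure the analysis assumes:

* per-neuron baseline fluorescence with i.i.d. Gaussian frame noise,
* spontaneous calcium transients as a homogeneous Poisson process whose
  rate may change at protocol-segment boundaries (emulating how activity in
  the fluidically isolated "naïve" chamber shifts when the perfused chamber
  is stimulated),
* agonist-evoked transients at drug-segment onsets with amplitudes scaled
  by a Hill function of the applied concentration, attenuated by antagonist
  or TTX co-application factors,
* a terminal sustained KCl depolarisation step for responder cells, and
* calcein tracer pulse profiles in the perfused versus naïve chamber.

Every generator is a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .doseresponse import DoseResponseSet, hill_response
from .errors import DomainError, ValidationError
from .perfusion import DeviceGeometry, FlowSetup, simulate_pulse_profile
from .traces import Recording

__all__ = [
    "Segment",
    "Protocol",
    "NeuronModel",
    "GroundTruth",
    "CalceinAssay",
    "transient_kernel",
    "generate_recording",
    "generate_calcein_assay",
    "generate_dose_response_dataset",
    "generate_paired_antagonist_assay",
]

SegmentLabel = Literal["baseline", "drug", "wash", "kcl"]


class Segment(BaseModel):
    """One protocol segment: label, duration, and what is being perfused.

    ``spont_rate_per_min`` overrides the neuron's own spontaneous rate for
    this segment, which is how naïve-chamber activity shifts are emulated.
    """

    model_config = ConfigDict(frozen=True)

    label: SegmentLabel
    duration_s: float = Field(gt=0)
    compound: Optional[str] = None
    concentration_M: Optional[float] = Field(default=None, gt=0)
    spont_rate_per_min: Optional[float] = Field(default=None, ge=0)
    antagonist: bool = False
    ttx: bool = False


class Protocol(BaseModel):
    """Ordered segment schedule sampled at a fixed frame rate (2.0 Hz)."""

    model_config = ConfigDict(frozen=True)

    frame_rate: float = Field(default=2.0, gt=0)
    segments: tuple[Segment, ...]

    @model_validator(mode="after")
    def _check_kcl(self) -> "Protocol":
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        kcl_idx = [i for i, s in enumerate(self.segments) if s.label == "kcl"]
        if len(kcl_idx) > 1:
            raise ValueError("at most one KCl segment allowed")
        if kcl_idx and kcl_idx[0] != len(self.segments) - 1:
            raise ValueError("the KCl segment must be last")
        return self

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def segment_frames(self) -> list[int]:
        return [int(round(s.duration_s * self.frame_rate)) for s in self.segments]

    def frame_labels(self) -> np.ndarray:
        parts = [
            np.full(n, seg.label, dtype=object)
            for n, seg in zip(self.segment_frames(), self.segments)
        ]
        return np.concatenate(parts)

    def segment_durations(self) -> dict[str, float]:
        """Total duration (s) per segment label (summed over repeats)."""
        out: dict[str, float] = {}
        for s in self.segments:
            out[s.label] = out.get(s.label, 0.0) + s.duration_s
        return out


class NeuronModel(BaseModel):
    """Generative parameters of one simulated neuron.

    ``spont_amplitude`` is the peak height of spontaneous transients (a.u.,
    same scale as ``noise_sd``); ``resp_amplitude_max`` the saturating
    evoked-peak amplitude, scaled down the Hill curve at sub-saturating
    agonist concentrations and further attenuated by ``inhibition_factor``
    (antagonist co-application) or ``ttx_factor`` (TTX co-application).
    """

    model_config = ConfigDict(frozen=True)

    f0: float = Field(default=100.0, gt=0)
    noise_sd: float = Field(default=2.0, ge=0)
    spont_rate_per_min: float = Field(default=0.2, ge=0)
    spont_amplitude: float = Field(default=20.0, ge=0)
    resp_amplitude_max: float = Field(default=50.0, ge=0)
    hill_ec50_M: float = Field(default=4.7e-6, gt=0)
    hill_n: float = Field(default=1.2, gt=0)
    inhibition_factor: float = Field(default=1.0, ge=0, le=1)
    ttx_factor: float = Field(default=1.0, ge=0, le=1)
    is_kcl_responder: bool = True
    kcl_amplitude: Optional[float] = Field(default=None, gt=0)
    rise_tau_s: float = Field(default=0.3, gt=0)
    decay_tau_s: float = Field(default=2.0, gt=0)


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery testing."""

    event_times: dict[str, np.ndarray]  # neuron id → spontaneous event times (s)
    segment_rates: pd.DataFrame  # neuron × segment-index true rate (events/min)
    evoked_amplitudes: pd.DataFrame  # neuron × segment-index evoked peak (a.u.)
    kcl_responder: dict[str, bool] = field(default_factory=dict)


@dataclass
class CalceinAssay:
    """Paired tracer traces demonstrating fluidic isolation of the chambers."""

    times_s: np.ndarray
    perfused: np.ndarray
    naive: np.ndarray
    frame_rate: float = 2.0


def transient_kernel(
    rise_tau_s: float, decay_tau_s: float, amplitude: float, frame_rate: float
) -> np.ndarray:
    """Double-exponential calcium transient sampled at the frame rate.

    Shape (1 − e^(−t/τ_rise))·e^(−t/τ_decay), rescaled so the analytic peak
    equals ``amplitude``; the sampled peak matches within one frame of
    discretisation.  The kernel starts at 0 and covers at least five decay
    time constants.
    """
    if rise_tau_s <= 0 or decay_tau_s <= 0:
        raise DomainError("time constants must be positive")
    t_peak = rise_tau_s * np.log1p(decay_tau_s / rise_tau_s)
    t_end = t_peak + 5.0 * decay_tau_s
    n = int(np.ceil(t_end * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    if amplitude == 0:
        return np.zeros(n)
    shape = (1.0 - np.exp(-t / rise_tau_s)) * np.exp(-t / decay_tau_s)
    peak = (1.0 - np.exp(-t_peak / rise_tau_s)) * np.exp(-t_peak / decay_tau_s)
    return amplitude * shape / peak


def _add_kernel(trace: np.ndarray, kernel: np.ndarray, start: int) -> None:
    stop = min(start + kernel.size, trace.size)
    if stop > start >= 0:
        trace[start:stop] += kernel[: stop - start]


def generate_recording(
    protocol: Protocol, neurons: Sequence[NeuronModel], seed: int
) -> tuple[Recording, GroundTruth]:
    """Simulate a multi-neuron recording under a protocol, with ground truth.

    Per neuron the raw trace is f0 + Gaussian noise + Poisson-placed
    spontaneous kernels (segment-specific rate) + one Hill-scaled evoked
    kernel at each drug-segment onset + a sustained step over a final KCl
    segment for responders.  Bit-identical for identical inputs and seed.
    """
    if not neurons:
        raise ValidationError("need at least one neuron")
    rng = np.random.default_rng(seed)
    fps = protocol.frame_rate
    seg_frames = protocol.segment_frames()
    n_frames = sum(seg_frames)
    seg_starts = np.concatenate(([0], np.cumsum(seg_frames)[:-1]))
    labels = protocol.frame_labels()

    traces = np.empty((n_frames, len(neurons)))
    all_event_times: dict[str, np.ndarray] = {}
    rate_rows, amp_rows, kcl_flags = {}, {}, {}

    for j, nm in enumerate(neurons):
        nid = str(j)
        trace = np.full(n_frames, nm.f0)
        if nm.noise_sd > 0:
            trace += rng.normal(0.0, nm.noise_sd, n_frames)
        spont_kernel = transient_kernel(nm.rise_tau_s, nm.decay_tau_s, nm.spont_amplitude, fps)
        ev_times: list[float] = []
        rates, amps = {}, {}
        t_offset = 0.0
        for k, seg in enumerate(protocol.segments):
            rate = seg.spont_rate_per_min if seg.spont_rate_per_min is not None else nm.spont_rate_per_min
            rates[k] = rate
            count = rng.poisson(rate * seg.duration_s / 60.0)
            if count:
                times = np.sort(t_offset + rng.uniform(0.0, seg.duration_s, count))
                for t in times:
                    _add_kernel(trace, spont_kernel, int(round(t * fps)))
                ev_times.extend(times.tolist())
            amp = 0.0
            if seg.label == "drug" and nm.resp_amplitude_max > 0 and seg.concentration_M:
                amp = nm.resp_amplitude_max * hill_response(
                    seg.concentration_M, 1.0, nm.hill_ec50_M, nm.hill_n
                )
                if seg.antagonist:
                    amp *= nm.inhibition_factor
                if seg.ttx:
                    amp *= nm.ttx_factor
                evoked = transient_kernel(nm.rise_tau_s, nm.decay_tau_s, amp, fps)
                _add_kernel(trace, evoked, int(seg_starts[k]))
            amps[k] = amp
            if seg.label == "kcl" and nm.is_kcl_responder:
                step = nm.kcl_amplitude if nm.kcl_amplitude is not None else 10.0 * nm.noise_sd
                trace[seg_starts[k]:] += step
            t_offset += seg.duration_s
        traces[:, j] = trace
        all_event_times[nid] = np.asarray(ev_times)
        rate_rows[nid] = rates
        amp_rows[nid] = amps
        kcl_flags[nid] = nm.is_kcl_responder

    recording = Recording(
        frame_rate=fps,
        traces=traces,
        roi_ids=[str(j) for j in range(len(neurons))],
        segment_labels=labels,
    )
    truth = GroundTruth(
        event_times=all_event_times,
        segment_rates=pd.DataFrame.from_dict(rate_rows, orient="index"),
        evoked_amplitudes=pd.DataFrame.from_dict(amp_rows, orient="index"),
        kcl_responder=kcl_flags,
    )
    return recording, truth


def generate_calcein_assay(
    setup: FlowSetup,
    geometry: DeviceGeometry,
    pulses: Sequence[tuple[float, float]],
    seed: int,
    *,
    distance_mm: float = 4.75,
    duration_s: float | None = None,
    frame_rate: float = 2.0,
    noise_sd: float = 0.01,
) -> CalceinAssay:
    """Tracer pulse profiles in the perfused chamber and the isolated chamber.

    The perfused trace follows the well-mixed-well + plug-flow pulse model
    plus Gaussian noise; the naïve trace is baseline noise only, since the
    chambers are fluidically isolated.
    """
    rng = np.random.default_rng(seed)
    if duration_s is None:
        last = pulses[-1][0] if pulses else 0.0
        duration_s = last + 120.0
    n = int(round(duration_s * frame_rate))
    times = np.arange(n) / frame_rate
    profile = simulate_pulse_profile(list(pulses), times, setup, geometry, distance_mm)
    perfused = profile + rng.normal(0.0, noise_sd, n)
    naive = rng.normal(0.0, noise_sd, n)
    return CalceinAssay(times_s=times, perfused=perfused, naive=naive, frame_rate=frame_rate)


def generate_dose_response_dataset(
    concentrations_M: Sequence[float],
    hill: tuple[float, float, float],
    n_neurons_per_conc: int,
    noise_sd: float,
    seed: int,
    reference_concentration_M: float | None = None,
) -> DoseResponseSet:
    """Per-neuron peak table: peak(c) = Hill(c) + Gaussian noise.

    ``hill`` is (R_max, EC50 [M], n).  The reference concentration defaults
    to the highest dose, matching the study's normalisation to the 1 mM
    response.
    """
    conc = np.asarray(concentrations_M, dtype=float)
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive")
    if n_neurons_per_conc < 1:
        raise ValidationError("need at least one neuron per concentration")
    r_max, ec50, n = hill
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        mu = hill_response(c, r_max, ec50, n)
        peaks = mu + rng.normal(0.0, noise_sd, n_neurons_per_conc)
        for i, p in enumerate(peaks):
            rows.append({"concentration_M": c, "neuron": f"{c:.3e}_{i}", "peak": p})
    ref = reference_concentration_M if reference_concentration_M is not None else float(conc.max())
    return DoseResponseSet(points=pd.DataFrame(rows), reference_concentration_M=ref)


def generate_paired_antagonist_assay(
    n_neurons: int,
    attenuation: float,
    noise_sd: float,
    seed: int,
    control_amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired control / antagonist-co-application evoked peak cohorts.

    Control peaks are ``control_amplitude`` + noise; treated peaks are the
    same amplitude attenuated by ``attenuation`` + independent noise.
    Returns ``(control_peaks, treated_peaks)``.
    """
    if n_neurons < 1:
        raise ValidationError("need at least one neuron")
    if not 0 <= attenuation <= 1:
        raise DomainError("attenuation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    control = control_amplitude + rng.normal(0.0, noise_sd, n_neurons)
    treated = attenuation * control_amplitude + rng.normal(0.0, noise_sd, n_neurons)
    return control, treated
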