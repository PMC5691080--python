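"""Calcium-event detection and the events/neuron/minute (ENM) summary.

An event is a significant fluorescence increase exceeding ``k_sd`` standard
deviations above the median of the baseline frames of the filtered,
normalised trace.  The "moving window" of the counting rule is implemented
as a merge/refractory rule: after an event is registered at an upward
threshold crossing, any further crossing within ``window_s`` seconds is
merged into it, so at most one event is counted per window and consecutive
event times are at least ``window_s`` apart.  Per-segment counts normalised
by segment duration give the ENM rate per neuron; cohorts are summarised as
mean ± SEM and compared with paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .errors import DegenerateInputError, DomainError, ValidationError
from .traces import NormalisedTrace

__all__ = [
    "DetectorParams",
    "EventTrain",
    "ENMSummary",
    "SegmentComparison",
    "detection_threshold",
    "detect_events",
    "enm",
    "compare_segments",
]


class DetectorParams(BaseModel):
    """Detector configuration.

    ``k_sd`` — threshold multiplier over baseline spread (default 7);
    ``window_s`` — merge window in seconds (default 10);
    ``baseline_frames`` — frames defining the baseline statistics, the same
    frames used for F/F0 normalisation (default 24);
    ``filter_window`` — moving-average window applied upstream (default 11);
    ``spread_estimator`` — how the baseline SD is estimated:

    * ``"diff"`` (default): robust scale of the first differences of the
      full-window baseline frames (1.4826 × median absolute deviation),
      rescaled by √(filter_window/2).  For a boxcar-filtered white-noise
      baseline, consecutive first differences share no raw samples and are
      therefore independent, so this estimates the filtered-baseline noise
      SD with nearly one degree of freedom per frame; the median form keeps
      a calcium transient that happens to fall inside the baseline window
      from inflating the threshold.  The direct sample SD of the same
      frames has only ≈ baseline_frames/filter_window effective degrees of
      freedom (the smoothed frames are strongly correlated), which makes
      the 7·SD threshold collapse for a fraction of cells and floods them
      with false events.
    * ``"sample"``: the plain sample SD of the baseline frames.
    * ``"mad"``: 1.4826 × median absolute deviation of the baseline frames
      about their median.
    """

    model_config = ConfigDict(frozen=True)

    k_sd: float = Field(default=7.0, gt=0)
    window_s: float = Field(default=10.0, gt=0)
    baseline_frames: int = Field(default=24, ge=2)
    filter_window: int = Field(default=11, ge=1)
    spread_estimator: Literal["diff", "sample", "mad"] = "diff"


@dataclass
class EventTrain:
    """Detected events for one neuron: times (s), frames, segment labels."""

    neuron_id: str
    event_times: np.ndarray
    event_frames: np.ndarray
    event_segments: np.ndarray
    threshold: float
    window_s: float

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(self.event_times) < self.window_s - 1e-9):
            raise ValidationError("event times closer than the merge window")


@dataclass
class ENMSummary:
    """Per-neuron, per-segment event rates (events·neuron⁻¹·min⁻¹)."""

    rates: pd.DataFrame  # index: neuron id, columns: segment label
    segment_durations_s: dict[str, float] = field(default_factory=dict)

    @property
    def cohort_mean(self) -> pd.Series:
        return self.rates.mean(axis=0)

    @property
    def cohort_sem(self) -> pd.Series:
        return self.rates.sem(axis=0, ddof=1)


@dataclass
class SegmentComparison:
    """Paired contrast of per-neuron ENM between two segments."""

    segment_a: str
    segment_b: str
    mean_difference: float  # b − a
    n: int
    p_value: float
    degenerate: bool = False  # all paired differences identical → p undefined


def _baseline_spread(baseline: np.ndarray, params: DetectorParams) -> float:
    if params.spread_estimator == "mad":
        return 1.4826 * float(np.median(np.abs(baseline - np.median(baseline))))
    if params.spread_estimator == "sample":
        return float(baseline.std(ddof=1))
    # "diff": robust difference-based estimate of the filtered-baseline
    # noise SD.  Skip the leading shrinking-window frames, whose variance
    # differs from the full-window interior.
    interior = baseline[params.filter_window // 2 :]
    if interior.size < 3:  # too short for differencing; fall back
        return float(baseline.std(ddof=1))
    d = np.diff(interior)
    robust_sd_d = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    return robust_sd_d * np.sqrt(params.filter_window / 2.0)


def detection_threshold(trace: NormalisedTrace | np.ndarray, params: DetectorParams) -> float:
    """Event threshold = median(baseline) + k_sd × SD(baseline), in NFU.

    The baseline is the first ``baseline_frames`` frames of the filtered,
    normalised trace — the same frames used for F/F0 normalisation.
    """
    x = trace.values if isinstance(trace, NormalisedTrace) else np.asarray(trace, dtype=float)
    if x.size < params.baseline_frames:
        raise ValidationError("trace shorter than the baseline window")
    baseline = x[: params.baseline_frames]
    spread = _baseline_spread(baseline, params)
    if spread == 0:
        raise DegenerateInputError("baseline has zero spread; threshold undefined")
    return float(np.median(baseline) + params.k_sd * spread)


def detect_events(
    trace: NormalisedTrace | np.ndarray,
    params: DetectorParams,
    frame_rate: float,
    segment_labels: np.ndarray | None = None,
    neuron_id: str = "0",
) -> EventTrain:
    """Detect events as upward threshold crossings with a merge window.

    The event time is the first supra-threshold frame of each crossing; a
    crossing within ``window_s`` seconds of the previous event is merged
    into it.  A trace already above threshold at frame 0 registers an event
    at frame 0.
    """
    x = trace.values if isinstance(trace, NormalisedTrace) else np.asarray(trace, dtype=float)
    thr = detection_threshold(x, params)
    above = x >= thr
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    window_frames = int(round(params.window_s * frame_rate))
    accepted: list[int] = []
    for f in crossings:
        if not accepted or f - accepted[-1] >= window_frames:
            accepted.append(int(f))
    frames = np.asarray(accepted, dtype=int)
    if segment_labels is not None:
        segs = np.asarray(segment_labels, dtype=object)[frames] if frames.size else np.array([], dtype=object)
    else:
        segs = np.full(frames.size, "all", dtype=object)
    return EventTrain(
        neuron_id=neuron_id,
        event_times=frames / frame_rate,
        event_frames=frames,
        event_segments=segs,
        threshold=thr,
        window_s=params.window_s,
    )


def enm(trains: list[EventTrain], segment_durations_s: dict[str, float]) -> ENMSummary:
    """Events/neuron/minute per segment, with events assigned by onset time."""
    for seg, dur in segment_durations_s.items():
        if dur <= 0:
            raise DomainError(f"segment '{seg}' has non-positive duration")
    segments = list(segment_durations_s)
    rows = {}
    for train in trains:
        counts = {seg: 0 for seg in segments}
        for s in train.event_segments:
            if s in counts:
                counts[s] += 1
        rows[train.neuron_id] = {
            seg: counts[seg] / (segment_durations_s[seg] / 60.0) for seg in segments
        }
    rates = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    rates = rates.reindex(columns=segments)
    return ENMSummary(rates=rates, segment_durations_s=dict(segment_durations_s))


def compare_segments(summary: ENMSummary, segment_a: str, segment_b: str) -> SegmentComparison:
    """Paired two-sided t-test of per-neuron ENM between two segments."""
    for seg in (segment_a, segment_b):
        if seg not in summary.rates.columns:
            raise ValidationError(f"segment '{seg}' not present in summary")
    sub = summary.rates[[segment_a, segment_b]].dropna()
    if sub.empty:
        raise ValidationError("no neurons present in both segments")
    a = sub[segment_a].to_numpy()
    b = sub[segment_b].to_numpy()
    diff = b - a
    if np.allclose(diff, diff[0]):
        # zero-variance differences: the t statistic is undefined
        return SegmentComparison(
            segment_a=segment_a,
            segment_b=segment_b,
            mean_difference=float(diff.mean()),
            n=len(diff),
            p_value=float("nan"),
            degenerate=True,
        )
    res = stats.ttest_rel(b, a)
    return SegmentComparison(
        segment_a=segment_a,
        segment_b=segment_b,
        mean_difference=float(diff.mean()),
        n=len(diff),
        p_value=float(res.pvalue),
    )
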