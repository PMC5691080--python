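"""Fluorescence-trace containers and processing.

The analysis pipeline operates on time × ROI mean-fluorescence matrices
sampled at a fixed frame rate (2.0 Hz in the study protocol).  Per-ROI
traces from consecutive recordings of one assay are stitched together,
smoothed with a centred moving-average filter (window 11), and normalised
to the mean of the first 24 baseline frames (F/F0, "normalised fluorescent
units").  A terminal high-KCl depolarisation acts as a cell-inclusion
control: somata that do not show an immediate and sustained fluorescence
rise are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError, ValidationError

__all__ = [
    "Recording",
    "NormalisedTrace",
    "minmax_scale",
    "normalize_to_basal",
    "moving_average",
    "stitch_recordings",
    "extract_roi_traces",
    "kcl_inclusion_filter",
    "peak_magnitude",
]


@dataclass
class Recording:
    """A frame-timed multi-ROI fluorescence matrix with segment annotations.

    ``traces`` is frames × ROIs (raw fluorescence, a.u.); ``segment_labels``
    gives a per-frame protocol label (e.g. ``baseline``, ``drug``, ``kcl``);
    ``boundaries`` lists the frame indices at which stitched source
    recordings start (excluding 0). Frame i occurs at time i / frame_rate.
    """

    frame_rate: float
    traces: np.ndarray
    roi_ids: list[str]
    segment_labels: np.ndarray
    chamber: str = "perfused"
    boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=object)
        if self.frame_rate <= 0:
            raise ValidationError("frame rate must be positive")
        if self.traces.ndim != 2:
            raise ValidationError("traces must be a frames x ROIs matrix")
        if self.traces.shape[1] != len(self.roi_ids):
            raise ValidationError("trace columns must match roi_ids")
        if len(self.segment_labels) != self.traces.shape[0]:
            raise ValidationError("segment_labels length must equal frame count")
        if not np.all(np.isfinite(self.traces)):
            raise ValidationError("traces must be finite")

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times, "segment": self.segment_labels})
        for j, roi in enumerate(self.roi_ids):
            df[f"roi_{roi}"] = self.traces[:, j]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float, chamber: str = "perfused") -> "Recording":
        roi_cols = [c for c in df.columns if c.startswith("roi_")]
        if not roi_cols:
            raise ValidationError("no roi_<id> columns found")
        labels = (
            df["segment"].to_numpy()
            if "segment" in df.columns
            else np.full(len(df), "baseline", dtype=object)
        )
        return cls(
            frame_rate=frame_rate,
            traces=df[roi_cols].to_numpy(dtype=float),
            roi_ids=[c[len("roi_"):] for c in roi_cols],
            segment_labels=labels,
            chamber=chamber,
        )

    @classmethod
    def read_csv(cls, path, frame_rate: float | None = None, chamber: str = "perfused") -> "Recording":
        df = pd.read_csv(path)
        if frame_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if len(dt) == 0 or not np.allclose(dt, dt[0]):
                raise ValidationError("cannot infer frame rate from non-uniform time_s")
            frame_rate = 1.0 / dt[0]
        return cls.from_frame(df, frame_rate=frame_rate, chamber=chamber)


@dataclass
class NormalisedTrace:
    """A single trace in normalised fluorescent units (NFU = F/F0)."""

    values: np.ndarray
    baseline_frames: int
    provenance: str = "basal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalised values must be finite")


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Affine rescale of a trace to [0, 1]: f(x) = (x − min)/(max − min).

    Used for calcein perfusion profiles so recordings from different devices
    can be averaged.  A constant trace has no defined scaling and raises
    :class:`DegenerateInputError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples to min-max scale")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("constant trace: max equals min")
    return (x - lo) / (hi - lo)


def normalize_to_basal(trace: np.ndarray, n_baseline_frames: int = 24) -> NormalisedTrace:
    """Divide a trace by the mean of its first ``n_baseline_frames`` frames."""
    x = np.asarray(trace, dtype=float)
    if x.size <= n_baseline_frames:
        raise ValidationError(
            f"trace length {x.size} must exceed baseline window {n_baseline_frames}"
        )
    f0 = x[:n_baseline_frames].mean()
    if f0 <= 0:
        raise DomainError("baseline mean must be positive for F/F0 normalisation")
    return NormalisedTrace(values=x / f0, baseline_frames=n_baseline_frames)


def moving_average(trace: np.ndarray, window: int = 11) -> np.ndarray:
    """Centred moving average; edges use shrinking windows (no padding)."""
    x = np.asarray(trace, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be an odd positive integer")
    if window > x.size:
        raise ValidationError("window exceeds trace length")
    if window == 1:
        return x.copy()
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(x.size)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def stitch_recordings(recordings: list[Recording]) -> Recording:
    """Concatenate consecutive recordings of the same ROI set in time.

    Frame rates and ROI identities must match; the per-frame segment labels
    are preserved and the start index of every non-first part is recorded in
    ``boundaries``.
    """
    if not recordings:
        raise ValidationError("need at least one recording")
    first = recordings[0]
    for r in recordings[1:]:
        if r.roi_ids != first.roi_ids:
            raise ValidationError("ROI sets differ between recordings")
        if r.frame_rate != first.frame_rate:
            raise ValidationError("frame rates differ between recordings")
        if r.chamber != first.chamber:
            raise ValidationError("chamber labels differ between recordings")
    boundaries: list[int] = []
    offset = 0
    for r in recordings[:-1]:
        offset += r.n_frames
        boundaries.append(offset)
    return Recording(
        frame_rate=first.frame_rate,
        traces=np.vstack([r.traces for r in recordings]),
        roi_ids=list(first.roi_ids),
        segment_labels=np.concatenate([r.segment_labels for r in recordings]),
        chamber=first.chamber,
        boundaries=boundaries,
    )


def extract_roi_traces(
    stack: np.ndarray,
    masks: np.ndarray,
    frame_rate: float,
    segment_labels: np.ndarray | None = None,
    chamber: str = "perfused",
) -> Recording:
    """Mean pixel intensity per labelled ROI per frame of an image stack.

    ``stack`` is a (frames, height, width) array (e.g. read with tifffile);
    ``masks`` an integer label image (0 = background, ROIs numbered ≥ 1).
    """
    from scipy import ndimage

    stack = np.asarray(stack)
    masks = np.asarray(masks)
    if stack.ndim != 3:
        raise ValidationError("stack must be (frames, height, width)")
    if masks.shape != stack.shape[1:]:
        raise ValidationError("mask shape must match frame shape")
    labels = np.unique(masks)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValidationError("mask contains no ROI labels")
    traces = np.stack(
        [ndimage.mean(frame, labels=masks, index=labels) for frame in stack]
    )
    if segment_labels is None:
        segment_labels = np.full(stack.shape[0], "baseline", dtype=object)
    return Recording(
        frame_rate=frame_rate,
        traces=traces,
        roi_ids=[str(int(l)) for l in labels],
        segment_labels=segment_labels,
        chamber=chamber,
    )


def kcl_inclusion_filter(
    trace: NormalisedTrace | np.ndarray,
    kcl_onset_frame: int,
    frame_rate: float,
    k_kcl: float = 5.0,
    immediate_window_s: float = 10.0,
    sustain_fraction: float = 0.8,
) -> bool:
    """Terminal-KCl inclusion rule: immediate and sustained fluorescence rise.

    A cell is included iff the trace rises at least ``k_kcl`` baseline SDs
    above the pre-KCl median within ``immediate_window_s`` of onset, and
    stays above half that rise for at least ``sustain_fraction`` of the
    remaining frames.  Returns True for include, False for exclude.
    """
    x = trace.values if isinstance(trace, NormalisedTrace) else np.asarray(trace, dtype=float)
    n = x.size
    if kcl_onset_frame < 1 or kcl_onset_frame >= n:
        raise DomainError("KCl onset frame outside trace")
    pre = x[:kcl_onset_frame]
    post = x[kcl_onset_frame:]
    med = np.median(pre)
    sd = pre.std(ddof=1) if pre.size > 1 else 0.0
    if sd == 0:
        raise DegenerateInputError("pre-KCl baseline has zero SD")
    rise_level = med + k_kcl * sd
    w = max(1, int(round(immediate_window_s * frame_rate)))
    immediate = post[:w].max() >= rise_level
    sustain_level = med + 0.5 * k_kcl * sd
    sustained = np.mean(post >= sustain_level) >= sustain_fraction
    return bool(immediate and sustained)


def peak_magnitude(
    trace: NormalisedTrace | np.ndarray,
    drug_window: tuple[int, int],
    pre_window: tuple[int, int],
) -> float:
    """Evoked peak: max over the drug window minus pre-window median.

    Windows are half-open frame ranges ``(start, stop)``; they must be
    non-empty, in range and non-overlapping.  The pre-window median (rather
    than the mean) is used as the reference so that a spontaneous transient
    in the pre-window does not bias the peak.  The result may be negative.
    """
    x = trace.values if isinstance(trace, NormalisedTrace) else np.asarray(trace, dtype=float)
    (ds, de), (ps, pe) = drug_window, pre_window
    for s, e in ((ds, de), (ps, pe)):
        if not (0 <= s < e <= x.size):
            raise ValidationError(f"window ({s}, {e}) empty or outside trace")
    if max(ds, ps) < min(de, pe):
        raise ValidationError("drug and pre windows overlap")
    return float(x[ds:de].max() - np.median(x[ps:pe]))
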