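"""End-to-end orchestration: simulate → process → detect → summarise → fit.

``process_recording`` applies the fixed analysis order — stitch, filter,
normalise, (KCl inclusion), detect, ENM — to any :class:`Recording`;
``run_pipeline`` drives a complete synthetic experiment from an
:class:`ExperimentConfig` and writes a deterministic report bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import doseresponse as dr
from . import perfusion as pf
from .config import ExperimentConfig, provenance_block
from .events import DetectorParams, ENMSummary, EventTrain, detect_events, enm
from .synthetic import (
    GroundTruth,
    generate_dose_response_dataset,
    generate_recording,
)
from .traces import (
    NormalisedTrace,
    Recording,
    kcl_inclusion_filter,
    moving_average,
    normalize_to_basal,
)

__all__ = ["ProcessedRecording", "process_recording", "run_pipeline"]

log = logging.getLogger("neuroperf")


@dataclass
class ProcessedRecording:
    """Filtered+normalised traces with detection results for one recording."""

    recording: Recording
    normalised: np.ndarray  # frames × ROIs, NFU
    included: dict[str, bool]
    trains: list[EventTrain]  # included neurons only
    summary: ENMSummary


def process_recording(
    recording: Recording,
    detector: DetectorParams,
    kcl_params: dict | None = None,
) -> ProcessedRecording:
    """Filter, normalise, apply the KCl inclusion rule, detect events, ENM.

    Order is fixed: moving-average filter (window ``detector.filter_window``)
    then F/F0 normalisation to the first ``detector.baseline_frames`` frames,
    per trace.  If the recording has a ``kcl`` segment, cells failing the
    immediate-and-sustained KCl rule are excluded before event counting;
    otherwise all cells are included and a warning is logged.  ENM rates are
    computed over the non-KCl segments only: the terminal depolarisation is
    an inclusion control, not an activity readout, so event counting stops
    at the last frame whose smoothing window contains no post-KCl samples
    (the centred filter would otherwise smear the KCl step backwards and
    register a spurious event at the end of the preceding segment).
    """
    labels = recording.segment_labels
    kcl_frames = np.flatnonzero(labels == "kcl")
    has_kcl = kcl_frames.size > 0
    if not has_kcl:
        log.warning("no KCl segment: inclusion filter skipped, all neurons included")
    kcl_params = kcl_params or {}

    n_frames, n_roi = recording.traces.shape
    normalised = np.empty((n_frames, n_roi))
    included: dict[str, bool] = {}
    trains: list[EventTrain] = []

    count_end = n_frames
    if has_kcl:
        count_end = max(
            detector.baseline_frames, int(kcl_frames[0]) - detector.filter_window // 2
        )

    seg_durations: dict[str, float] = {}
    for lab in pd.unique(labels[:count_end]):
        if lab != "kcl":
            seg_durations[lab] = float(np.sum(labels[:count_end] == lab)) / recording.frame_rate

    for j, roi in enumerate(recording.roi_ids):
        filtered = moving_average(recording.traces[:, j], detector.filter_window)
        ntr = normalize_to_basal(filtered, detector.baseline_frames)
        normalised[:, j] = ntr.values
        ok = True
        if has_kcl:
            ok = kcl_inclusion_filter(
                ntr, int(kcl_frames[0]), recording.frame_rate, **kcl_params
            )
        included[roi] = ok
        if ok:
            counting = NormalisedTrace(
                values=ntr.values[:count_end], baseline_frames=ntr.baseline_frames
            )
            trains.append(
                detect_events(
                    counting, detector, recording.frame_rate,
                    segment_labels=labels[:count_end], neuron_id=roi,
                )
            )
    summary = enm(trains, seg_durations)
    return ProcessedRecording(
        recording=recording,
        normalised=normalised,
        included=included,
        trains=trains,
        summary=summary,
    )


def _perfusion_report(config: ExperimentConfig) -> dict:
    q_ch = pf.chamber_flow_rate(config.flow)
    hrt = pf.hydraulic_retention_time(
        config.flow.inlet_well_volume_ul, config.flow.q_injection_ul_min
    )
    return {
        "q_chamber_ul_min": q_ch,
        "hrt_s": hrt,
        "t_ex_s_at_L": pf.exchange_time(hrt, config.geometry, config.distance_mm, q_ch),
        "t_ex_s_full_length": pf.exchange_time(
            hrt, config.geometry, config.geometry.chamber_length_mm, q_ch
        ),
        "reynolds": pf.reynolds_number(config.geometry, q_ch, config.fluid),
        "peclet": pf.peclet_number(
            config.geometry, q_ch, config.fluid, config.geometry.chamber_length_mm
        ),
        "distance_mm": config.distance_mm,
    }


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment and write the report bundle.

    Writes ``traces.csv``, ``events.csv``, ``enm.json``, ``perfusion.json``,
    optionally ``hill_fit.json``, and ``report.json`` (which embeds the
    parameter-provenance block).  All randomness derives from
    ``config.seed`` via per-stage spawned seeds, so the report is
    byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_rec, seed_dr = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    log.info("stage=perfusion distance_mm=%s", config.distance_mm)
    perfusion = _perfusion_report(config)

    log.info("stage=simulate n_neurons=%d seed=%d", config.n_neurons, seed_rec)
    recording, truth = generate_recording(
        config.protocol, [config.neuron] * config.n_neurons, seed_rec
    )
    recording.write_csv(out / "traces.csv")

    log.info("stage=process_detect k_sd=%s window_s=%s", config.detector.k_sd, config.detector.window_s)
    processed = process_recording(recording, config.detector)
    events_df = pd.DataFrame(
        [
            {"neuron": tr.neuron_id, "time_s": t, "segment": s}
            for tr in processed.trains
            for t, s in zip(tr.event_times, tr.event_segments)
        ],
        columns=["neuron", "time_s", "segment"],
    )
    events_df.to_csv(out / "events.csv", index=False)

    enm_report = {
        "segment_durations_s": processed.summary.segment_durations_s,
        "cohort_mean": processed.summary.cohort_mean.to_dict(),
        "cohort_sem": processed.summary.cohort_sem.to_dict(),
        "n_included": int(sum(processed.included.values())),
        "n_total": len(processed.included),
        "true_rates_per_segment_index": truth.segment_rates.mean(axis=0).to_dict(),
    }
    (out / "enm.json").write_text(json.dumps(enm_report, indent=2, sort_keys=True))
    (out / "perfusion.json").write_text(json.dumps(perfusion, indent=2, sort_keys=True))

    report = {
        "perfusion": perfusion,
        "enm": enm_report,
        "provenance": provenance_block(config),
        "seed": config.seed,
    }

    if config.dose_response is not None:
        drc = config.dose_response
        log.info("stage=dose_response n_conc=%d seed=%d", len(drc.concentrations_M), seed_dr)
        dset = generate_dose_response_dataset(
            drc.concentrations_M,
            (drc.r_max, drc.ec50_M, drc.hill_n),
            drc.n_neurons_per_conc,
            drc.noise_sd,
            seed_dr,
        )
        fit = dr.fit_hill(dr.normalize_peaks(dset))
        fit_report = {
            "r_max": fit.r_max,
            "ec50_M": fit.ec50,
            "hill_n": fit.hill_n,
            "ec50_se_M": fit.ec50_se,
            "converged": fit.converged,
        }
        (out / "hill_fit.json").write_text(json.dumps(fit_report, indent=2, sort_keys=True))
        report["hill_fit"] = fit_report

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
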