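"""Event detection threshold, merge rule, ENM summary and recovery."""

import numpy as np
import pytest

from neuroperf import (
    DegenerateInputError,
    DetectorParams,
    DomainError,
    EventTrain,
    NeuronModel,
    Protocol,
    Segment,
    ValidationError,
    compare_segments,
    detect_events,
    detection_threshold,
    enm,
    generate_recording,
    moving_average,
    normalize_to_basal,
    process_recording,
    transient_kernel,
)


class TestDetectionThreshold:
    def test_flat_baseline_degenerate(self):
        with pytest.raises(DegenerateInputError):
            detection_threshold(np.ones(100), DetectorParams())

    def test_sample_sd_arithmetic(self):
        """median + k·SD with the plain sample-SD estimator."""
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.01, 24)
        x = np.concatenate([base, np.full(100, 1.0)])
        params = DetectorParams(spread_estimator="sample")
        expected = np.median(base) + 7.0 * base.std(ddof=1)
        assert detection_threshold(x, params) == pytest.approx(expected)

    def test_translation_equivariance(self, rng):
        x = 1.0 + rng.normal(0, 0.01, 200)
        p = DetectorParams()
        t0 = detection_threshold(x, p)
        t1 = detection_threshold(x + 0.5, p)
        assert t1 - t0 == pytest.approx(0.5, abs=1e-12)

    def test_diff_estimator_unbiased_for_filtered_noise(self, rng):
        """The default estimator recovers the filtered-noise SD, which the
        sample SD of correlated smoothed frames systematically misses."""
        p = DetectorParams()
        ests = []
        for _ in range(300):
            x = moving_average(rng.normal(1.0, 0.02, 200), 11)
            ests.append(detection_threshold(x, p) - np.median(x[:24]))
        true_sd = 0.02 / np.sqrt(11)
        assert np.median(ests) / 7.0 == pytest.approx(true_sd, rel=0.10)

    def test_mad_variant_available(self, rng):
        x = 1.0 + rng.normal(0, 0.01, 100)
        t = detection_threshold(x, DetectorParams(spread_estimator="mad"))
        base = x[:24]
        expected = np.median(base) + 7 * 1.4826 * np.median(np.abs(base - np.median(base)))
        assert t == pytest.approx(expected)


def _trace_with_events(event_times_s, fps=2.0, n_frames=600, amp=0.2, noise_sd=0.005, seed=0):
    """Normalised-scale trace: baseline 1.0, small noise, kernels at given times."""
    rng = np.random.default_rng(seed)
    x = 1.0 + rng.normal(0, noise_sd, n_frames)
    k = transient_kernel(0.3, 2.0, amp, fps)
    for t in event_times_s:
        i = int(round(t * fps))
        x[i:i + len(k)] += k[: max(0, n_frames - i)]
    return x


class TestDetectEvents:
    def test_flat_noisy_trace_no_events(self, rng):
        x = 1.0 + rng.normal(0, 0.005, 600)
        tr = detect_events(x, DetectorParams(), 2.0)
        assert len(tr.event_times) == 0

    def test_single_kernel_single_event(self):
        x = _trace_with_events([100.0])
        tr = detect_events(x, DetectorParams(), 2.0)
        assert len(tr.event_times) == 1
        assert tr.event_times[0] == pytest.approx(100.0, abs=3.0)

    def test_close_events_merged_distant_events_kept(self):
        """Two kernels 4 s apart count once; 30 s apart count twice."""
        close = detect_events(_trace_with_events([100.0, 104.0]), DetectorParams(), 2.0)
        assert len(close.event_times) == 1
        far = detect_events(_trace_with_events([100.0, 130.0]), DetectorParams(), 2.0)
        assert len(far.event_times) == 2

    def test_merge_rule_interval_invariant(self, rng):
        """All outputs respect the ≥ window_s inter-event interval."""
        for seed in range(20):
            times = np.sort(rng.uniform(15, 280, rng.integers(1, 15)))
            x = _trace_with_events(times, seed=seed)
            tr = detect_events(x, DetectorParams(), 2.0)
            if len(tr.event_times) > 1:
                assert np.all(np.diff(tr.event_times) >= tr.window_s - 1e-9)

    def test_affine_invariance_after_normalisation(self, rng):
        """Detection is unchanged when the raw trace is affinely rescaled
        before basal normalisation (gain changes cancel in F/F0)."""
        raw = 100.0 + rng.normal(0, 2.0, 600)
        k = transient_kernel(0.3, 2.0, 20.0, 2.0)
        raw[200:200 + len(k)] += k
        p = DetectorParams()

        def run(y):
            return detect_events(
                normalize_to_basal(moving_average(y, 11), 24), p, 2.0
            ).event_frames

        np.testing.assert_array_equal(run(raw), run(3.0 * raw))


class TestEnm:
    def _train(self, nid, times, segs):
        return EventTrain(
            neuron_id=nid,
            event_times=np.asarray(times, dtype=float),
            event_frames=(np.asarray(times) * 2).astype(int),
            event_segments=np.asarray(segs, dtype=object),
            threshold=1.05,
            window_s=10.0,
        )

    def test_rate_arithmetic(self):
        durations = {"baseline": 300.0}
        zero = enm([self._train("a", [], [])], durations)
        assert zero.rates.loc["a", "baseline"] == 0.0
        two = enm([self._train("a", [10.0, 50.0], ["baseline"] * 2)], durations)
        assert two.rates.loc["a", "baseline"] == pytest.approx(0.4)

    def test_identical_cohort_sem_zero(self):
        trains = [self._train(str(i), [10.0, 50.0], ["baseline"] * 2) for i in range(5)]
        s = enm(trains, {"baseline": 300.0})
        assert s.cohort_sem["baseline"] == 0.0
        assert s.cohort_mean["baseline"] == pytest.approx(0.4)

    def test_zero_duration_rejected(self):
        with pytest.raises(DomainError):
            enm([], {"baseline": 0.0})


class TestCompareSegments:
    def _summary(self, a_rates, b_rates):
        trains = []
        for i, (a, b) in enumerate(zip(a_rates, b_rates)):
            times = [10.0 + 20 * j for j in range(int(a * 5))] + [
                310.0 + 20 * j for j in range(int(b * 5))
            ]
            segs = ["baseline"] * int(a * 5) + ["drug"] * int(b * 5)
            trains.append(
                EventTrain(
                    neuron_id=str(i),
                    event_times=np.asarray(times),
                    event_frames=(np.asarray(times) * 2).astype(int),
                    event_segments=np.asarray(segs, dtype=object),
                    threshold=1.0,
                    window_s=10.0,
                )
            )
        return enm(trains, {"baseline": 300.0, "drug": 300.0})

    def test_identical_segments_degenerate(self):
        s = self._summary([0.4, 0.8, 1.2], [0.4, 0.8, 1.2])
        cmp = compare_segments(s, "baseline", "drug")
        assert cmp.mean_difference == pytest.approx(0.0)
        assert cmp.degenerate

    def test_constant_shift_recovered(self):
        s = self._summary([0.2, 0.4, 0.8, 1.0], [0.4, 0.6, 1.0, 1.2])
        cmp = compare_segments(s, "baseline", "drug")
        assert cmp.mean_difference == pytest.approx(0.2)
        assert cmp.n == 4

    def test_missing_segment_rejected(self):
        s = self._summary([0.4], [0.4])
        with pytest.raises(ValidationError):
            compare_segments(s, "baseline", "wash")

    def test_naive_chamber_rate_shift_recovered(self, naive_chamber_protocol, quiet_neuron):
        """Synthetic rates 0.16 vs 0.38 events/min over 222 neurons give a
        paired difference near 0.22 with a significant p-value."""
        rec, _ = generate_recording(naive_chamber_protocol, [quiet_neuron] * 222, seed=5)
        res = process_recording(rec, DetectorParams())
        cmp = compare_segments(res.summary, "baseline", "drug")
        sem = np.sqrt(
            res.summary.cohort_sem["baseline"] ** 2 + res.summary.cohort_sem["drug"] ** 2
        )
        assert cmp.mean_difference == pytest.approx(0.22, abs=2 * sem)
        assert cmp.p_value < 1e-6


class TestDetectorRecovery:
    def test_precision_and_recall_on_separated_events(self):
        """≥0.95 precision and recall for well-separated 10×SD transients."""
        fps, n_frames = 2.0, 1200
        rng = np.random.default_rng(99)
        tp = fp = fn = 0
        for _ in range(200):
            # renewal process with gaps > the merge window
            t, times = 20.0, []
            while True:
                t += 10.5 + rng.exponential(60.0)
                if t > 580.0:
                    break
                times.append(t)
            raw = 100.0 + rng.normal(0, 2.0, n_frames)
            k = transient_kernel(0.3, 2.0, 20.0, fps)
            for ev in times:
                i = int(round(ev * fps))
                raw[i:i + len(k)] += k[: max(0, n_frames - i)]
            tr = detect_events(
                normalize_to_basal(moving_average(raw, 11), 24), DetectorParams(), fps
            )
            det = list(tr.event_times)
            used = set()
            for ev in times:
                hit = [j for j, d in enumerate(det) if j not in used and -4 <= ev - d <= 12]
                if hit:
                    used.add(hit[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(det) - len(used)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_cohort_enm_matches_dead_time_oracle(self):
        """The recovered cohort rate equals, within 2 SEM, the ground-truth
        rate after applying the counting rule's own 10-s merge to the true
        event times (an independent oracle of the dead-time the rule
        imposes).  Neurons with a true transient inside the 24-frame
        baseline window are excluded: such a transient inflates the
        threshold by construction, which is the rule's documented failure
        mode, not a detector defect."""
        protocol = Protocol(
            frame_rate=2.0,
            segments=(Segment(label="baseline", duration_s=300.0, spont_rate_per_min=0.3),),
        )
        neuron = NeuronModel(f0=100.0, noise_sd=2.0, spont_amplitude=20.0, resp_amplitude_max=0.0)
        rec, truth = generate_recording(protocol, [neuron] * 220, seed=11)

        def merged_count(times, window=10.0):
            last, c = None, 0
            for t in sorted(times):
                if last is None or t - last >= window:
                    c, last = c + 1, t
            return c

        detected, oracle = [], []
        for j, roi in enumerate(rec.roi_ids):
            true_t = truth.event_times[roi]
            if len(true_t) and true_t.min() < 13.0:
                continue
            ntr = normalize_to_basal(moving_average(rec.traces[:, j], 11), 24)
            train = detect_events(ntr, DetectorParams(), rec.frame_rate)
            detected.append(len(train.event_times) / 5.0)
            oracle.append(merged_count(true_t) / 5.0)
        detected, oracle = np.asarray(detected), np.asarray(oracle)
        assert len(detected) >= 190
        sem = detected.std(ddof=1) / np.sqrt(len(detected))
        assert detected.mean() == pytest.approx(oracle.mean(), abs=2 * sem)
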