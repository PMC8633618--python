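"""EOG eye-movement detection and phasic/tonic/wake segment selection."""

import numpy as np
import pytest

from hepsleep.microstates import (
    SegmentationError,
    Segment,
    SegmentSet,
    classify_rem_segments,
    classify_window,
    detect_eye_movements,
    evaluate_against_truth,
    select_wake_segments,
)
from hepsleep.preprocess import bandpass_filter
from hepsleep.psg_io import Hypnogram

FS = 250.0


def _pulse(n, at_s, width_ms, amp_uv, fs=FS, neg_fraction=0.25):
    """A biphasic deflection: dominant lobe + small opposite lobe."""
    t = np.arange(n) / fs
    x = amp_uv * np.exp(-0.5 * ((t - at_s) / (width_ms / 4000.0)) ** 2)
    x -= neg_fraction * amp_uv * np.exp(
        -0.5 * ((t - at_s - width_ms / 1000.0) / (width_ms / 4000.0)) ** 2
    )
    return x


class TestEMDetection:
    def test_all_zero_signal_yields_no_events(self):
        assert detect_eye_movements(np.zeros(int(10 * FS)), FS) == []

    def test_single_qualifying_deflection_is_one_event(self):
        x = _pulse(int(10 * FS), 5.0, 300, 120.0)
        events = detect_eye_movements(x, FS)
        assert len(events) == 1
        assert events[0].peak_amplitude_uv >= 100.0
        assert events[0].duration_ms < 500.0
        assert events[0].onset_s == pytest.approx(5.0, abs=0.3)

    def test_subthreshold_amplitude_is_ignored(self):
        x = _pulse(int(10 * FS), 5.0, 300, 80.0)
        assert detect_eye_movements(x, FS) == []

    def test_overlong_deflection_is_rejected_by_duration_rule(self):
        # duration rule in isolation (prefiltered input): same amplitude,
        # half-peak width 600 ms vs 300 ms
        t = np.arange(int(10 * FS)) / FS
        slow = 150.0 * np.exp(
            -0.5 * ((t - 5.0) / (0.600 / 2.355)) ** 2
        )
        fast = 150.0 * np.exp(
            -0.5 * ((t - 5.0) / (0.300 / 2.355)) ** 2
        )
        assert detect_eye_movements(slow, FS, _prefiltered=True) == []
        assert len(detect_eye_movements(fast, FS, _prefiltered=True)) == 1

    def test_slow_800ms_deflection_yields_no_event(self):
        # through the full 0.5-30 Hz path an 800 ms 120 uV deflection
        # never qualifies (rejected on width and/or attenuated amplitude)
        x = _pulse(int(10 * FS), 5.0, 800, 120.0)
        assert detect_eye_movements(x, FS) == []

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(SegmentationError):
            detect_eye_movements(np.zeros(100), 50.0)

    def test_events_ordered_by_onset(self):
        n = int(20 * FS)
        x = _pulse(n, 12.0, 250, 150.0) + _pulse(n, 4.0, 250, 200.0)
        events = detect_eye_movements(x, FS)
        onsets = [e.onset_s for e in events]
        assert onsets == sorted(onsets)


class TestWindowClassification:
    def _events(self, x):
        f = bandpass_filter(x, FS, 0.5, 30.0)
        return f, detect_eye_movements(f, FS, _prefiltered=True)

    def test_two_close_ems_make_phasic(self):
        n = int(8 * FS)
        x = _pulse(n, 3.0, 300, 150.0) + _pulse(n, 3.9, 300, 150.0)
        f, ev = self._events(x)
        assert classify_window(f, FS, 2.0, ev) == "phasic"

    def test_quiet_window_is_tonic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, int(8 * FS))
        f, ev = self._events(x)
        assert classify_window(f, FS, 2.0, ev) == "tonic"

    def test_intermediate_deflection_is_unlabeled(self):
        # a single 60 uV slow deflection: too small for an EM, too big
        # for tonic quiescence
        x = _pulse(int(8 * FS), 4.0, 400, 60.0)
        f, ev = self._events(x)
        assert classify_window(f, FS, 2.0, ev) is None

    def test_distant_ems_do_not_make_phasic(self):
        n = int(8 * FS)
        x = _pulse(n, 2.5, 300, 150.0) + _pulse(n, 5.5, 300, 150.0)
        f, ev = self._events(x)
        assert classify_window(f, FS, 1.5, ev) != "phasic"


class TestSelection:
    def test_spacing_invariant_enforced_by_segmentset(self):
        with pytest.raises(SegmentationError, match="closer"):
            SegmentSet(
                [
                    Segment(onset_s=0.0, state="tonic"),
                    Segment(onset_s=10.0, state="tonic"),
                ]
            )

    def test_classification_on_synthetic_recording(self, small_psg):
        _, rec, truth = small_psg
        eog = rec.channel("EOG")
        segs = classify_rem_segments(eog, rec.fs, truth.hypnogram, seed=0)
        counts = segs.counts()
        assert counts.get("phasic", 0) > 0
        assert counts.get("tonic", 0) > 0
        ordered = sorted(segs, key=lambda s: s.onset_s)
        gaps = [
            b.onset_s - a.offset_s for a, b in zip(ordered, ordered[1:])
        ]
        assert min(gaps) >= 8.0 - 1e-9
        # every selected segment lies inside a REM epoch
        for s in segs:
            assert truth.hypnogram.stages[int(s.onset_s // 30)] == "REM"

    def test_cap_limits_per_state_counts(self, small_psg):
        _, rec, truth = small_psg
        segs = classify_rem_segments(
            rec.channel("EOG"), rec.fs, truth.hypnogram,
            cap_per_state=3, seed=0,
        )
        assert all(v <= 3 for v in segs.counts().values())

    def test_raising_amp_threshold_never_increases_phasic_count(
        self, small_psg
    ):
        _, rec, truth = small_psg
        eog = rec.channel("EOG")
        counts = []
        for thresh in (80.0, 100.0, 150.0, 260.0):
            segs = classify_rem_segments(
                eog, rec.fs, truth.hypnogram, amp_thresh_uv=thresh, seed=0
            )
            counts.append(segs.counts().get("phasic", 0))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_no_rem_yields_empty_set_with_warning(self):
        hyp = Hypnogram(["W"] * 4)
        with pytest.warns(UserWarning, match="no REM"):
            out = classify_rem_segments(np.zeros(int(120 * FS)), FS, hyp)
        assert len(out) == 0

    def test_ground_truth_fidelity_noise_free(self, noise_free_psg):
        _, rec, truth = noise_free_psg
        scores = evaluate_against_truth(
            rec.channel("EOG"), rec.fs, truth.true_segments
        )
        assert scores["f1_macro"] == 1.0

    def test_ground_truth_fidelity_default_noise(self, small_psg):
        _, rec, truth = small_psg
        scores = evaluate_against_truth(
            rec.channel("EOG"), rec.fs, truth.true_segments
        )
        assert scores["f1_macro"] >= 0.95


class TestWakeSelection:
    def test_prefers_pre_sleep_onset_wake(self, small_psg):
        _, rec, truth = small_psg
        segs = select_wake_segments(
            rec.channel("EOG"), rec.fs, truth.hypnogram, seed=0
        )
        assert len(segs) > 0
        stages = truth.hypnogram.stages
        first_sleep = next(
            i for i, s in enumerate(stages) if s != "W"
        )
        for s in segs:
            assert s.onset_s < first_sleep * 30.0

    def test_no_wake_epochs_warns_and_returns_empty(self):
        hyp = Hypnogram(["REM"] * 4)
        with pytest.warns(UserWarning, match="no wake"):
            out = select_wake_segments(np.zeros(int(120 * FS)), FS, hyp)
        assert len(out) == 0
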