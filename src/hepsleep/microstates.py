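"""REM microstate segmentation: phasic vs. tonic 4-s windows, plus wake.

Phasic REM is marked by bursts of rapid eye movements (EMs) on the bipolar
EOG channel; tonic REM by their absence.  The operational criteria:

* an EM is a biphasic EOG deflection of at least 100 uV (from the local
  baseline, on the 0.5-30 Hz band-passed channel) lasting less than 500 ms;
* a 4-s window is *phasic* when it contains at least two consecutive EMs
  (onsets no more than 1 s apart, as REM EM bursts stay below ~2 Hz);
* a 4-s window is *tonic* when the band-passed EOG never deflects more
  than 25 uV from the window median;
* windows meeting neither criterion stay unlabeled;
* selected segments must be at least 8 s apart edge-to-edge so that the
  microstates do not contaminate each other.

Wake segments (eyes closed, pre-sleep-onset preferred) are selected with
the same machinery.  Human visual artifact screening is replaced by an
automated veto: windows whose EEG RMS exceeds 5x the recording median RMS
are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .preprocess import bandpass_filter
from .psg_io import Hypnogram

SEGMENT_DURATION_S = 4.0
MIN_SEGMENT_GAP_S = 8.0
EM_AMP_THRESHOLD_UV = 100.0
EM_MAX_DURATION_MS = 500.0
TONIC_MAX_DEFLECTION_UV = 25.0
CONSECUTIVE_EM_GAP_S = 1.0


class SegmentationError(ValueError):
    pass


@dataclass
class EMEvent:
    """A single rapid-eye-movement deflection on the EOG channel."""

    onset_s: float
    duration_ms: float
    peak_amplitude_uv: float

    def __post_init__(self) -> None:
        if not self.duration_ms < EM_MAX_DURATION_MS:
            raise SegmentationError("a qualifying EM lasts < 500 ms")
        if self.peak_amplitude_uv < EM_AMP_THRESHOLD_UV:
            raise SegmentationError("a qualifying EM reaches >= 100 uV")


@dataclass
class Segment:
    onset_s: float
    state: str  # "phasic" | "tonic" | "wake"
    duration_s: float = SEGMENT_DURATION_S
    subject_id: str | None = None
    quality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in ("phasic", "tonic", "wake"):
            raise SegmentationError(f"unknown segment state {self.state!r}")
        if abs(self.duration_s - SEGMENT_DURATION_S) > 1e-9:
            raise SegmentationError("segments are exactly 4 s long")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SegmentSet:
    """Selected 4-s segments with the >= 8 s pairwise-gap guarantee."""

    segments: list[Segment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = sorted(self.segments, key=lambda s: s.onset_s)
        for a, b in zip(ordered, ordered[1:]):
            if b.onset_s - a.offset_s < MIN_SEGMENT_GAP_S - 1e-9:
                raise SegmentationError(
                    f"segments at {a.onset_s:.1f}s and {b.onset_s:.1f}s are "
                    f"closer than {MIN_SEGMENT_GAP_S} s edge-to-edge"
                )
        self.segments = ordered

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def by_state(self, state: str) -> "SegmentSet":
        return SegmentSet(
            [s for s in self.segments if s.state == state], dict(self.metadata)
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.segments:
            out[s.state] = out.get(s.state, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Eye-movement detection
# ---------------------------------------------------------------------------


def detect_eye_movements(
    eog: np.ndarray,
    fs: float,
    amp_thresh_uv: float = EM_AMP_THRESHOLD_UV,
    max_dur_ms: float = EM_MAX_DURATION_MS,
    _prefiltered: bool = False,
) -> list[EMEvent]:
    """Detect rapid eye movements on a single EOG channel.

    The channel is band-passed 0.5-30 Hz; a candidate is a contiguous
    excursion of |amplitude| above half the threshold (relative to the
    channel median) whose peak reaches ``amp_thresh_uv`` and whose
    above-half-peak width stays below ``max_dur_ms``.
    """
    eog = np.asarray(eog, dtype=float)
    if eog.ndim != 1:
        raise SegmentationError("EOG must be a single channel")
    if fs < 60:
        raise SegmentationError("fs too low for the 0.5-30 Hz EM band")
    if eog.size == 0:
        return []
    x = eog if _prefiltered else bandpass_filter(eog, fs, low=0.5, high=30.0)
    dev = np.abs(x - np.median(x))

    above = dev >= amp_thresh_uv / 2.0
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])  # inclusive

    events: list[EMEvent] = []
    for s, e in zip(run_starts, run_ends):
        seg = dev[s : e + 1]
        peak = float(seg.max())
        if peak < amp_thresh_uv:
            continue
        half = np.flatnonzero(seg >= peak / 2.0)
        width_ms = (half[-1] - half[0] + 1) * 1000.0 / fs
        if width_ms >= max_dur_ms:
            continue
        events.append(
            EMEvent(
                onset_s=s / fs,
                duration_ms=width_ms,
                peak_amplitude_uv=peak,
            )
        )
    events.sort(key=lambda ev: ev.onset_s)
    return events


def _has_consecutive_ems(
    events: list[EMEvent], onset_s: float, offset_s: float
) -> bool:
    inside = [ev for ev in events if onset_s <= ev.onset_s < offset_s]
    for a, b in zip(inside, inside[1:]):
        if b.onset_s - a.onset_s <= CONSECUTIVE_EM_GAP_S:
            return True
    return False


# ---------------------------------------------------------------------------
# Window classification and spacing-constrained selection
# ---------------------------------------------------------------------------


def classify_window(
    filtered_eog: np.ndarray,
    fs: float,
    onset_s: float,
    events: list[EMEvent],
    tonic_max_uv: float = TONIC_MAX_DEFLECTION_UV,
) -> str | None:
    """Label one 4-s window as phasic, tonic, or None (unlabeled)."""
    offset_s = onset_s + SEGMENT_DURATION_S
    if _has_consecutive_ems(events, onset_s, offset_s):
        return "phasic"
    lo = int(round(onset_s * fs))
    hi = int(round(offset_s * fs))
    win = filtered_eog[lo:hi]
    if win.size and np.max(np.abs(win - np.median(win))) < tonic_max_uv:
        return "tonic"
    return None


def _greedy_select(
    candidates: list[Segment],
    taken: list[Segment],
    rng: np.random.Generator | None = None,
    cap: int | None = None,
) -> list[Segment]:
    """Earliest-onset greedy selection under the 8-s edge-to-edge rule.

    ``taken`` are previously selected segments (other states) that also
    constrain spacing.  With a cap, the spacing-feasible pool is first
    collected and then sub-sampled with the seeded RNG.
    """
    chosen: list[Segment] = []
    occupied = list(taken)
    for seg in sorted(candidates, key=lambda s: s.onset_s):
        ok = all(
            seg.onset_s - o.offset_s >= MIN_SEGMENT_GAP_S - 1e-9
            or o.onset_s - seg.offset_s >= MIN_SEGMENT_GAP_S - 1e-9
            for o in occupied
        )
        if ok:
            chosen.append(seg)
            occupied.append(seg)
    if cap is not None and len(chosen) > cap:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = rng.choice(len(chosen), size=cap, replace=False)
        chosen = [chosen[i] for i in sorted(keep)]
    return chosen


def _artifact_free(
    eeg: np.ndarray | None, fs: float, onset_s: float, rms_factor: float = 5.0,
    median_rms: float | None = None,
) -> bool:
    if eeg is None or median_rms is None:
        return True
    lo = int(round(onset_s * fs))
    hi = lo + int(round(SEGMENT_DURATION_S * fs))
    win = eeg[:, lo:hi]
    if win.size == 0:
        return False
    rms = float(np.sqrt(np.mean(win**2)))
    return rms <= rms_factor * median_rms


def _window_rms_median(eeg: np.ndarray, fs: float) -> float:
    n_win = int(eeg.shape[1] // (SEGMENT_DURATION_S * fs))
    if n_win == 0:
        return float("inf")
    w = int(round(SEGMENT_DURATION_S * fs))
    vals = [
        float(np.sqrt(np.mean(eeg[:, i * w : (i + 1) * w] ** 2)))
        for i in range(n_win)
    ]
    return float(np.median(vals))


def classify_rem_segments(
    eog: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    tonic_max_uv: float = TONIC_MAX_DEFLECTION_UV,
    amp_thresh_uv: float = EM_AMP_THRESHOLD_UV,
    max_dur_ms: float = EM_MAX_DURATION_MS,
    eeg: np.ndarray | None = None,
    cap_per_state: int | None = None,
    min_total_s_per_state: float | None = None,
    stride_s: float = 1.0,
    seed: int | None = 0,
    subject_id: str | None = None,
) -> SegmentSet:
    """Classify and select phasic/tonic 4-s segments inside REM epochs.

    Candidate windows tile REM epochs on a ``stride_s`` grid; each is
    labeled by :func:`classify_window`; selection is greedy by onset under
    the 8-s spacing rule.  ``cap_per_state`` implements the fixed-count
    study mode (seeded random sub-sampling of the feasible pool);
    ``min_total_s_per_state`` implements the minimum-duration study mode
    (a warning is issued when unmet).
    """
    rem = hypnogram.stage_intervals("REM")
    if not rem:
        warnings.warn("no REM epochs in hypnogram; empty segment set",
                      stacklevel=2)
        return SegmentSet([], {"warning": "no REM epochs"})
    filtered = bandpass_filter(np.asarray(eog, dtype=float), fs, 0.5, 30.0)
    events = detect_eye_movements(
        filtered, fs, amp_thresh_uv, max_dur_ms, _prefiltered=True
    )
    median_rms = _window_rms_median(eeg, fs) if eeg is not None else None

    phasic_cand: list[Segment] = []
    tonic_cand: list[Segment] = []
    for lo_s, hi_s in rem:
        onset = lo_s
        while onset + SEGMENT_DURATION_S <= hi_s + 1e-9:
            if _artifact_free(eeg, fs, onset, median_rms=median_rms):
                label = classify_window(filtered, fs, onset, events, tonic_max_uv)
                if label == "phasic":
                    phasic_cand.append(
                        Segment(onset_s=onset, state="phasic",
                                subject_id=subject_id)
                    )
                elif label == "tonic":
                    tonic_cand.append(
                        Segment(onset_s=onset, state="tonic",
                                subject_id=subject_id)
                    )
            onset += stride_s

    rng = np.random.default_rng(seed)
    phasic = _greedy_select(phasic_cand, [], rng, cap_per_state)
    tonic = _greedy_select(tonic_cand, phasic, rng, cap_per_state)
    segs = phasic + tonic
    meta = {
        "amp_thresh_uv": amp_thresh_uv,
        "tonic_max_uv": tonic_max_uv,
        "max_dur_ms": max_dur_ms,
        "cap_per_state": cap_per_state,
        "seed": seed,
        "n_phasic": len(phasic),
        "n_tonic": len(tonic),
        "n_em_events": len(events),
    }
    if min_total_s_per_state is not None:
        for state, sel in (("phasic", phasic), ("tonic", tonic)):
            total = sum(s.duration_s for s in sel)
            if total < min_total_s_per_state:
                warnings.warn(
                    f"{state} segments total {total:.0f} s, below the "
                    f"required {min_total_s_per_state:.0f} s",
                    stacklevel=2,
                )
    return SegmentSet(segs, meta)


def select_wake_segments(
    eog: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    eeg: np.ndarray | None = None,
    cap: int | None = None,
    stride_s: float = 1.0,
    seed: int | None = 0,
    subject_id: str | None = None,
) -> SegmentSet:
    """Select eyes-closed wake 4-s segments, preferring pre-sleep-onset wake.

    Windows containing EM bursts are excluded (eyes-closed rest), artifact
    screening and 8-s spacing are identical to the REM selection.
    """
    stages = hypnogram.stages
    sleep_stages = {"N1", "N2", "N3", "REM"}
    first_sleep = next(
        (i for i, s in enumerate(stages) if s in sleep_stages), len(stages)
    )
    wake_epochs = hypnogram.epochs_of("W")
    if not wake_epochs:
        warnings.warn("no wake epochs in hypnogram; empty segment set",
                      stacklevel=2)
        return SegmentSet([], {"warning": "no wake epochs"})
    pre = [i for i in wake_epochs if i < first_sleep]
    post = [i for i in wake_epochs if i >= first_sleep]

    filtered = bandpass_filter(np.asarray(eog, dtype=float), fs, 0.5, 30.0)
    events = detect_eye_movements(filtered, fs, _prefiltered=True)
    median_rms = _window_rms_median(eeg, fs) if eeg is not None else None

    def windows(epochs: list[int]) -> list[Segment]:
        out = []
        L = hypnogram.epoch_length_s
        for i in epochs:
            onset = i * L
            while onset + SEGMENT_DURATION_S <= (i + 1) * L + 1e-9:
                if _artifact_free(eeg, fs, onset, median_rms=median_rms):
                    if not _has_consecutive_ems(
                        events, onset, onset + SEGMENT_DURATION_S
                    ):
                        out.append(
                            Segment(onset_s=onset, state="wake",
                                    subject_id=subject_id)
                        )
                onset += stride_s
        return out

    rng = np.random.default_rng(seed)
    selected = _greedy_select(windows(pre), [], rng, cap)
    if cap is None or len(selected) < (cap or 0):
        extra_cap = None if cap is None else cap - len(selected)
        if post and (cap is None and not selected or extra_cap):
            selected += _greedy_select(windows(post), selected, rng, extra_cap)
    meta = {"n_wake": len(selected), "pre_onset": bool(pre), "seed": seed}
    return SegmentSet(selected, meta)


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    eog: np.ndarray,
    fs: float,
    true_segments: SegmentSet,
    tonic_max_uv: float = TONIC_MAX_DEFLECTION_UV,
) -> dict[str, float]:
    """Label each ground-truth window with the automated classifier and
    score agreement.  Returns per-state precision/recall and macro F1."""
    filtered = bandpass_filter(np.asarray(eog, dtype=float), fs, 0.5, 30.0)
    events = detect_eye_movements(filtered, fs, _prefiltered=True)
    states = ("phasic", "tonic")
    tp = {s: 0 for s in states}
    fp = {s: 0 for s in states}
    fn = {s: 0 for s in states}
    for seg in true_segments:
        if seg.state not in states:
            continue
        pred = classify_window(filtered, fs, seg.onset_s, events, tonic_max_uv)
        if pred == seg.state:
            tp[seg.state] += 1
        else:
            fn[seg.state] += 1
            if pred in states:
                fp[pred] += 1
    out: dict[str, float] = {}
    f1s = []
    for s in states:
        prec = tp[s] / (tp[s] + fp[s]) if tp[s] + fp[s] else 0.0
        rec = tp[s] / (tp[s] + fn[s]) if tp[s] + fn[s] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[f"precision_{s}"] = prec
        out[f"recall_{s}"] = rec
        out[f"f1_{s}"] = f1
        f1s.append(f1)
    out["f1_macro"] = float(np.mean(f1s))
    return out
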