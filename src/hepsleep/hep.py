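"""R-peak-locked epoching and heartbeat-evoked-potential averaging.

Epochs span -200..+800 ms around each R-peak that falls inside a selected
segment (the epoch itself may extend into adjacent clean continuous data).
Baseline correction subtracts the -200..-50 ms pre-R mean — the window
stops at -50 ms to stay clear of the rising edge of the R wave.  Subjects
whose artifact-free trial count falls below 200 in any condition are
excluded from group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cardiac import RPeakSeries

EPOCH_WINDOW_MS = (-200.0, 800.0)
BASELINE_WINDOW_MS = (-200.0, -50.0)
MIN_TRIALS = 200


class EpochError(ValueError):
    pass


@dataclass
class EpochSet:
    """R-peak-locked trials: (n_trials, n_channels, n_times) in uV."""

    data: np.ndarray
    fs: float
    labels: list[str]
    condition: str
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS
    subject_id: str | None = None
    baseline_corrected: bool = False
    peak_samples: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise EpochError("epoch data must be trials x channels x time")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to the R-peak (time 0 = R sample)."""
        lo = -int(round(-self.window_ms[0] / 1000.0 * self.fs))
        n = self.data.shape[2]
        return (np.arange(n) + lo) * 1000.0 / self.fs


@dataclass
class HEPAverage:
    """Per-subject condition average: mean and SEM across trials."""

    mean: np.ndarray  # (n_channels, n_times)
    sem: np.ndarray
    n_trials: int
    condition: str
    times_ms: np.ndarray
    labels: list[str]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise EpochError("an average needs at least one trial")


def extract_epochs(
    recording,
    rpeaks: RPeakSeries,
    segments,
    condition: str,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    picks: list[int] | None = None,
    artifact_mask: np.ndarray | None = None,
    subject_id: str | None = None,
) -> EpochSet:
    """Cut one trial per R-peak lying inside a selected segment.

    Trial samples are ``[r + round(w0*fs), r + round(w1*fs))`` (half-open);
    trials running beyond the recording bounds or into artifact-flagged
    spans are dropped and counted in ``n_dropped``.
    """
    if abs(rpeaks.fs - recording.fs) > 1e-9:
        raise EpochError("recording and R-peak series must share fs")
    fs = recording.fs
    sig = recording.signals if picks is None else recording.signals[picks]
    labels = (
        list(recording.labels)
        if picks is None
        else [recording.labels[i] for i in picks]
    )
    lo_off = int(round(window_ms[0] / 1000.0 * fs))
    hi_off = int(round(window_ms[1] / 1000.0 * fs))
    n_samp = hi_off - lo_off

    times = rpeaks.times_s
    inside = np.zeros(times.size, dtype=bool)
    for seg in segments:
        inside |= (times >= seg.onset_s) & (times < seg.onset_s + seg.duration_s)
    eligible = rpeaks.peak_samples[inside]

    trials, kept_peaks, dropped = [], [], 0
    for r in eligible:
        a, b = r + lo_off, r + hi_off
        if a < 0 or b > recording.n_samples:
            dropped += 1
            continue
        if artifact_mask is not None and artifact_mask[a:b].any():
            dropped += 1
            continue
        trials.append(sig[:, a:b])
        kept_peaks.append(r)
    if not trials:
        warnings.warn(
            f"no eligible R-peaks for condition {condition!r}", stacklevel=2
        )
        data = np.empty((0, sig.shape[0], n_samp))
    else:
        data = np.stack(trials)
    return EpochSet(
        data=data,
        fs=fs,
        labels=labels,
        condition=condition,
        window_ms=window_ms,
        subject_id=subject_id,
        peak_samples=np.asarray(kept_peaks, dtype=np.int64),
        n_dropped=dropped,
    )


def baseline_correct(
    epochs: EpochSet, baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    if epochs.baseline_corrected:
        raise EpochError("epochs are already baseline-corrected")
    t = epochs.times_ms
    mask = (t >= baseline_ms[0]) & (t <= baseline_ms[1])
    if not mask.any():
        raise EpochError("baseline window contains no samples")
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        fs=epochs.fs,
        labels=list(epochs.labels),
        condition=epochs.condition,
        window_ms=epochs.window_ms,
        subject_id=epochs.subject_id,
        baseline_corrected=True,
        peak_samples=epochs.peak_samples.copy(),
        n_dropped=epochs.n_dropped,
    )


def average_hep(epochs: EpochSet) -> HEPAverage:
    """Arithmetic mean and SEM across trials."""
    if epochs.n_trials == 0:
        raise EpochError("cannot average zero trials")
    mean = epochs.data.mean(axis=0)
    if epochs.n_trials >= 2:
        sem = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_trials)
    else:
        sem = np.full_like(mean, np.nan)
    return HEPAverage(
        mean=mean,
        sem=sem,
        n_trials=epochs.n_trials,
        condition=epochs.condition,
        times_ms=epochs.times_ms,
        labels=list(epochs.labels),
        subject_id=epochs.subject_id,
    )


def screen_subjects(
    counts: dict[str, dict[str, int]], min_trials: int = MIN_TRIALS
) -> tuple[list[str], dict[str, str]]:
    """Exclude subjects with fewer than ``min_trials`` artifact-free trials
    in any condition (boundary inclusive: exactly ``min_trials`` passes).

    Returns ``(included_ids, {excluded_id: reason})``.
    """
    included, excluded = [], {}
    for sid in sorted(counts):
        short = {
            cond: n for cond, n in counts[sid].items() if n < min_trials
        }
        if short:
            reasons = ", ".join(
                f"{cond}: {n} < {min_trials}" for cond, n in short.items()
            )
            excluded[sid] = f"insufficient artifact-free trials ({reasons})"
        else:
            included.append(sid)
    return included, excluded
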