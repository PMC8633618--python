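"""R-peak detection and time-domain heart-rate variability.

The detector follows the classic energy-based recipe: band-pass the ECG to
the QRS band, differentiate, square, integrate over a short moving window,
then pick peaks of the energy envelope with an adaptive threshold and a
250 ms physiological refractory period.  Detected peaks are refined to the
local extremum of the raw ECG so that epoch time-locking is exact.

Heart rate is reported in beats per minute, and heart-rate variability as
SDNN (standard deviation of the inter-beat intervals, ms).  Because the
analysed data are non-contiguous 4-s segments, only IBIs whose both
endpoints fall inside selected segments enter segment-restricted summaries;
frequency-domain indices are deliberately out of scope.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

REFRACTORY_MS = 250.0


class CardiacError(ValueError):
    pass


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices at a given sampling rate."""

    peak_samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=np.int64)
        if self.peak_samples.ndim != 1:
            raise CardiacError("peak_samples must be 1-D")
        if np.any(np.diff(self.peak_samples) <= 0):
            raise CardiacError("peak samples must be strictly increasing")
        if self.fs <= 0:
            raise CardiacError("fs must be positive")

    def __len__(self) -> int:
        return len(self.peak_samples)

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_samples / self.fs

    @property
    def ibis_ms(self) -> np.ndarray:
        """Successive inter-beat intervals in milliseconds."""
        return np.diff(self.peak_samples) * 1000.0 / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Export peaks for manual review (sample_index, time_s)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_index", "time_s"])
            for p in self.peak_samples:
                w.writerow([int(p), p / self.fs])

    @classmethod
    def from_csv(cls, path: str | Path, fs: float) -> "RPeakSeries":
        peaks = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if i == 0 and row and row[0] == "sample_index":
                    continue
                if row:
                    peaks.append(int(row[0]))
        return cls(np.asarray(peaks), fs)


@dataclass
class CardiacSummary:
    """Heart rate and SDNN over a set of in-scope inter-beat intervals."""

    hr_bpm: float
    sdnn_ms: float
    n_rr: int
    normalization: str = "raw"  # "raw" (sample SD) or "per_sqrt_n"

    def __post_init__(self) -> None:
        if self.n_rr >= 2 and not self.hr_bpm > 0:
            raise CardiacError("hr_bpm must be positive with >= 2 intervals")
        if self.sdnn_ms < 0:
            raise CardiacError("sdnn_ms must be non-negative")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> RPeakSeries:
    """Detect R-peaks in a single-channel ECG (microvolts).

    Band-pass 5-30 Hz -> differentiate -> square -> moving-window
    integration (150 ms) -> block-adaptive threshold with a 250 ms
    refractory -> refinement to the raw-signal extremum within +-50 ms,
    with automatic polarity detection.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.ndim != 1:
        raise CardiacError("ECG must be a single channel")
    if fs < 100:
        raise CardiacError("R-peak detection requires fs >= 100 Hz")
    if ecg.size == 0 or np.ptp(ecg) < 1e-12:
        warnings.warn("flat ECG signal; no R-peaks detected", stacklevel=2)
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    sos = sps.butter(3, [5.0, 30.0], btype="band", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(0.150 * fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_MS / 1000.0 * fs))
    # block-adaptive threshold: half of each 10-s block's 98th percentile,
    # floored at 10% of the global 98th percentile to survive quiet blocks
    block = int(round(10 * fs))
    thresh = np.empty_like(envelope)
    global_ref = np.percentile(envelope, 98)
    for start in range(0, envelope.size, block):
        seg = envelope[start : start + block]
        thresh[start : start + block] = max(
            0.5 * np.percentile(seg, 98), 0.1 * global_ref
        )
    cand, _ = sps.find_peaks(envelope, distance=max(1, refractory))
    cand = cand[envelope[cand] >= thresh[cand]]
    if cand.size == 0:
        warnings.warn("no QRS-like activity found", stacklevel=2)
        return RPeakSeries(np.empty(0, dtype=np.int64), fs)

    # polarity: sign of the dominant raw excursion (about the median)
    # within +-50 ms of each candidate, majority vote across beats
    centered = ecg - np.median(ecg)
    half = int(round(0.050 * fs))
    votes = []
    for c in cand:
        lo, hi = max(0, c - half), min(ecg.size, c + half + 1)
        w = centered[lo:hi]
        votes.append(np.sign(w[np.argmax(np.abs(w))]))
    polarity = 1.0 if np.median(votes) >= 0 else -1.0
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(ecg.size, c + half + 1)
        refined.append(lo + int(np.argmax(polarity * centered[lo:hi])))
    peaks = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce refractory after refinement: keep the larger-envelope peak
    keep: list[int] = []
    for p in peaks:
        if keep and p - keep[-1] < refractory:
            if envelope[p] > envelope[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return RPeakSeries(np.asarray(keep, dtype=np.int64), fs)


def _in_scope_ibis_ms(rpeaks: RPeakSeries, segments=None) -> np.ndarray:
    """IBIs whose both endpoint peaks fall inside selected segments."""
    if segments is None:
        return rpeaks.ibis_ms
    times = rpeaks.times_s
    inside = np.zeros(times.size, dtype=bool)
    for seg in segments:
        inside |= (times >= seg.onset_s) & (times < seg.onset_s + seg.duration_s)
    both = inside[:-1] & inside[1:]
    return rpeaks.ibis_ms[both]


def heart_rate_bpm(rpeaks: RPeakSeries, segments=None) -> float:
    """Mean heart rate, 60000 / mean(IBI in ms), over in-scope intervals."""
    ibis = _in_scope_ibis_ms(rpeaks, segments)
    if ibis.size < 1:
        raise CardiacError("heart rate undefined with fewer than 2 in-scope peaks")
    return 60000.0 / float(np.mean(ibis))


def sdnn_ms(
    rpeaks: RPeakSeries, segments=None, normalized: bool = False
) -> CardiacSummary:
    """SDNN over in-scope IBIs (sample SD, n-1 denominator).

    ``normalized=True`` additionally divides by sqrt(n_rr); the mode used
    is always recorded in the returned summary because the two variants
    are not comparable.
    """
    ibis = _in_scope_ibis_ms(rpeaks, segments)
    if ibis.size < 2:
        raise CardiacError("SDNN undefined with fewer than 2 in-scope intervals")
    sd = float(np.std(ibis, ddof=1))
    mode = "raw"
    if normalized:
        sd = sd / np.sqrt(ibis.size)
        mode = "per_sqrt_n"
    return CardiacSummary(
        hr_bpm=60000.0 / float(np.mean(ibis)),
        sdnn_ms=sd,
        n_rr=int(ibis.size),
        normalization=mode,
    )
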