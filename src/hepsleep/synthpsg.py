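"""Synthetic polysomnography with known ground truth.

Every downstream stage (segmentation, R-peak detection, ICA cleaning,
epoching, cluster statistics, surrogate testing) is testable without real
recordings.  The generator emulates the study conditions:

* colored-noise (1/f) scalp EEG, with 10-14 Hz and 15-28 Hz band-limited
  activity elevated during tonic relative to phasic REM;
* an ECG channel with configurable mean heart rate (~60 bpm) and RR
  variability (SDNN ~55 ms, truncated-normal IBIs), QRS + T-wave
  morphology, and cardiac-field leakage into every EEG channel at <1% of
  the chest amplitude;
* a bipolar EOG channel whose rapid-eye-movement bursts (>= 2 biphasic
  deflections of >= 100 uV, each < 500 ms) are confined to phasic spans,
  with the EOG source leaking into frontal EEG channels (the target for
  ICA cleaning);
* an injectable heartbeat-locked EEG component (Gaussian bump, default
  center 600 ms post-R, sigma 40 ms, fronto-central topography) whose
  amplitude differs by state — the known effect the pipeline must recover.

The recording timeline is: eyes-closed wake blocks first (pre-sleep
onset), then REM with alternating phasic/tonic blocks; one ground-truth
4-s segment sits at the center of each block, which automatically honors
the 8-s spacing rule.

A cohort-level generator (:func:`synthesize_hep_cohort`) draws per-subject
condition *averages* directly from the same effect/noise model with the
residual noise scaled by 1/sqrt(n_trials); it is the scaled route used for
calibration studies that need hundreds of cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import truncnorm

from .cardiac import RPeakSeries
from .microstates import Segment, SegmentSet
from .montage import POSITIONS_1020, template_positions
from .psg_io import ContinuousRecording, Hypnogram

EEG_LABELS_19 = list(POSITIONS_1020)
EEG_LABELS_17 = [l for l in EEG_LABELS_19 if l not in ("Fp1", "Fp2")]

IBI_TRUNC_LO_MS = 250.0
IBI_TRUNC_HI_MS = 2000.0


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ECGMorphology:
    """QRS as a sum of narrow Gaussians plus a broader T wave (uV, ms)."""

    r_amp_uv: float = 1000.0
    r_sigma_ms: float = 8.0
    q_amp_uv: float = -120.0
    q_offset_ms: float = -30.0
    q_sigma_ms: float = 7.0
    s_amp_uv: float = -200.0
    s_offset_ms: float = 25.0
    s_sigma_ms: float = 7.0
    t_amp_uv: float = 300.0
    t_latency_ms: float = 300.0
    t_sigma_ms: float = 60.0


@dataclass
class HEPSpec:
    """Injected heartbeat-locked EEG component, per state."""

    amplitude_uv: dict = field(
        default_factory=lambda: {"phasic": 2.5, "tonic": 1.0, "wake": 1.0}
    )
    center_ms: float = 600.0
    sigma_ms: float = 40.0
    topo_center: tuple[float, float] = (0.0, 0.25)  # fronto-central
    topo_sigma: float = 0.7  # substantial weight over ~8 fronto-central sites


@dataclass
class EMSpec:
    """Eye-movement burst shape: >= 2 biphasic deflections per burst."""

    amplitude_uv: float = 200.0
    duration_ms: float = 250.0
    burst_size: int = 3
    within_burst_gap_s: float = 0.35
    burst_every_s: float = 4.0  # burst spacing inside phasic blocks


@dataclass
class BandPowerSpec:
    """Per-state RMS (uV) of band-limited 10-14 and 15-28 Hz activity."""

    alpha_high_uv: dict = field(
        default_factory=lambda: {"phasic": 2.0, "tonic": 6.0, "wake": 8.0}
    )
    beta_uv: dict = field(
        default_factory=lambda: {"phasic": 1.5, "tonic": 4.0, "wake": 2.0}
    )


@dataclass
class NoiseSpec:
    """Background noise levels (1/f^exponent colored noise, RMS in uV)."""

    exponent: float = 1.0
    eeg_rms_uv: float = 20.0
    eog_rms_uv: float = 5.0
    ecg_rms_uv: float = 5.0


@dataclass
class SynthConfig:
    """Full generative configuration for one synthetic recording."""

    fs: float = 512.0
    n_segments_per_state: int = 100
    block_s: float = 20.0
    eeg_labels: list[str] = field(default_factory=lambda: list(EEG_LABELS_19))
    mean_ibi_ms: float = 1000.0
    ibi_sd_ms: float = 55.0
    ecg_leak_fraction: float = 0.005
    eog_leak_gain: float = 0.3  # EOG-source gain at Fp1/Fp2, decays with distance
    hep_spec: HEPSpec = field(default_factory=HEPSpec)
    em_spec: EMSpec = field(default_factory=EMSpec)
    band_power_spec: BandPowerSpec = field(default_factory=BandPowerSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    ecg_morphology: ECGMorphology = field(default_factory=ECGMorphology)
    include_wake: bool = True  # False: REM-only recording (no wake blocks)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SynthError("fs must be positive")
        if self.n_segments_per_state < 1 or self.block_s < 12.0:
            raise SynthError(
                "need >= 1 block per state, blocks >= 12 s (4 s segment "
                "plus 8 s spacing)"
            )
        if self.mean_ibi_ms <= IBI_TRUNC_LO_MS:
            raise SynthError("mean IBI must exceed the 250 ms refractory")
        if not self.ecg_leak_fraction < 0.01:
            raise SynthError("cardiac-field leakage must stay below 1%")
        for w in self.hep_spec.amplitude_uv.values():
            if not np.isfinite(w):
                raise SynthError("HEP topography/amplitude must be finite")

    @property
    def channel_labels(self) -> list[str]:
        return list(self.eeg_labels) + ["EOG", "ECG"]

    @property
    def wake_duration_s(self) -> float:
        if not self.include_wake:
            return 0.0
        raw = self.n_segments_per_state * self.block_s
        return float(np.ceil(raw / 30.0) * 30.0)

    @property
    def rem_duration_s(self) -> float:
        raw = 2 * self.n_segments_per_state * self.block_s
        return float(np.ceil(raw / 30.0) * 30.0)

    @property
    def duration_s(self) -> float:
        return self.wake_duration_s + self.rem_duration_s


@dataclass
class GroundTruth:
    """Everything the generator injected, for oracle-style checks."""

    true_rpeaks: np.ndarray  # sample indices
    true_em_events: list[tuple[float, float, float]]  # (onset_s, dur_ms, uv)
    true_segments: SegmentSet
    state_intervals: list[tuple[float, float, str]]  # (onset, duration, state)
    injected_hep: HEPSpec
    hypnogram: Hypnogram
    ecg_leak_gains: np.ndarray
    eog_leak_gains: np.ndarray

    def state_at(self, t_s: float) -> str | None:
        for on, dur, state in self.state_intervals:
            if on <= t_s < on + dur:
                return state
        return None


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def generate_rr_series(
    mean_ibi_ms: float,
    ibi_sd_ms: float,
    duration_s: float,
    seed: int | None = None,
    fs: float = 512.0,
) -> RPeakSeries:
    """Draw R-peak times with truncated-normal IBIs (250..2000 ms).

    The truncation keeps every interval physiologic; with ``ibi_sd_ms=0``
    the series is strictly periodic.  Identical seeds give identical
    series.
    """
    if duration_s <= 0 or mean_ibi_ms <= 0:
        raise SynthError("duration and mean IBI must be positive")
    if mean_ibi_ms <= IBI_TRUNC_LO_MS:
        raise SynthError("mean IBI must exceed the 250 ms refractory")
    if ibi_sd_ms < 0:
        raise SynthError("IBI standard deviation must be non-negative")
    rng = np.random.default_rng(seed)
    n_max = int(duration_s * 1000.0 / IBI_TRUNC_LO_MS) + 2
    if ibi_sd_ms == 0:
        ibis = np.full(n_max, mean_ibi_ms)
    else:
        a = (IBI_TRUNC_LO_MS - mean_ibi_ms) / ibi_sd_ms
        b = (IBI_TRUNC_HI_MS - mean_ibi_ms) / ibi_sd_ms
        ibis = truncnorm.rvs(
            a, b, loc=mean_ibi_ms, scale=ibi_sd_ms, size=n_max,
            random_state=rng,
        )
    times_s = np.cumsum(ibis) / 1000.0
    times_s = times_s[times_s <= duration_s]
    samples = np.round(times_s * fs).astype(np.int64)
    samples = samples[samples < int(duration_s * fs)]
    samples = np.unique(samples)
    return RPeakSeries(samples, fs)


def synthesize_ecg(
    rpeaks: RPeakSeries,
    fs: float | None = None,
    morphology: ECGMorphology | None = None,
    n_samples: int | None = None,
) -> np.ndarray:
    """Render a noise-free ECG (uV) from R-peak times.

    Each beat is a QRS complex (sum of narrow Gaussians: Q, R, S) plus a
    broader T-wave Gaussian at a configurable post-R latency.  The R-peak
    sample is the global per-beat maximum by construction.
    """
    m = morphology or ECGMorphology()
    fs = rpeaks.fs if fs is None else fs
    if len(rpeaks) == 0:
        raise SynthError("need at least one R-peak")
    ibis = rpeaks.ibis_ms
    template_span_ms = m.t_latency_ms + 2 * m.t_sigma_ms
    if ibis.size and ibis.min() < template_span_ms:
        raise SynthError(
            f"shortest IBI {ibis.min():.0f} ms is shorter than the "
            f"QRS+T template ({template_span_ms:.0f} ms)"
        )
    n = n_samples if n_samples is not None else int(rpeaks.peak_samples[-1]
                                                   + fs)
    ecg = np.zeros(n)
    half_ms = m.t_latency_ms + 4 * m.t_sigma_ms
    lo = int(round(-(abs(m.q_offset_ms) + 4 * m.q_sigma_ms) / 1000 * fs))
    hi = int(round(half_ms / 1000 * fs))
    rel_ms = np.arange(lo, hi + 1) * 1000.0 / fs

    def gauss(amp, mu, sig):
        return amp * np.exp(-0.5 * ((rel_ms - mu) / sig) ** 2)

    template = (
        gauss(m.q_amp_uv, m.q_offset_ms, m.q_sigma_ms)
        + gauss(m.r_amp_uv, 0.0, m.r_sigma_ms)
        + gauss(m.s_amp_uv, m.s_offset_ms, m.s_sigma_ms)
        + gauss(m.t_amp_uv, m.t_latency_ms, m.t_sigma_ms)
    )
    for r in rpeaks.peak_samples:
        a, b = r + lo, r + hi + 1
        ta, tb = max(0, -a), (b - a) - max(0, b - n)
        a, b = max(a, 0), min(b, n)
        if a < b:
            ecg[a:b] += template[ta:tb]
    return ecg


def colored_noise(
    n: int, rms_uv: float, exponent: float, rng: np.random.Generator,
    size: int | tuple = 1,
) -> np.ndarray:
    """1/f^exponent Gaussian noise, RMS-normalized, shape (size, n)."""
    n_ch = size if isinstance(size, int) else int(np.prod(size))
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms * rms_uv


def _band_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator,
    n_ch: int,
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (n_ch, n)."""
    white = rng.standard_normal((n_ch, n))
    sos = sps.butter(4, band, btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _em_burst_waveform(fs: float, spec: EMSpec) -> np.ndarray:
    """One burst: ``burst_size`` alternating-sign biphasic deflections."""
    dur = spec.duration_ms / 1000.0
    t_defl = np.arange(int(round(dur * fs))) / fs
    # biphasic: one sine cycle, peak amplitude = spec.amplitude_uv
    defl = spec.amplitude_uv * np.sin(2 * np.pi * t_defl / dur)
    gap = int(round(spec.within_burst_gap_s * fs))
    parts = []
    for k in range(spec.burst_size):
        parts.append(defl * (-1) ** k)
        if k < spec.burst_size - 1:
            parts.append(np.zeros(max(0, gap - defl.size)))
    return np.concatenate(parts)


def hep_topography(labels: list[str], spec: HEPSpec) -> np.ndarray:
    """Per-channel weights of the injected component (Gaussian on the
    template scalp around the fronto-central focus)."""
    pos = template_positions(labels)
    d = np.linalg.norm(pos - np.asarray(spec.topo_center), axis=1)
    return np.exp(-0.5 * (d / spec.topo_sigma) ** 2)


# ---------------------------------------------------------------------------
# Full recording synthesis
# ---------------------------------------------------------------------------


def _state_layout(config: SynthConfig):
    """Block plan: wake blocks, then alternating phasic/tonic REM blocks."""
    blocks: list[tuple[float, float, str]] = []
    if config.include_wake:
        t = 0.0
        for _ in range(config.n_segments_per_state):
            blocks.append((t, config.block_s, "wake"))
            t += config.block_s
    t = config.wake_duration_s
    for k in range(2 * config.n_segments_per_state):
        state = "phasic" if k % 2 == 0 else "tonic"
        blocks.append((t, config.block_s, state))
        t += config.block_s
    return blocks


def synthesize_recording(
    config: SynthConfig,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Generate one synthetic polysomnography recording plus ground truth.

    Deterministic in ``config`` (including its seed).
    """
    labels = config.channel_labels
    if "ECG" not in labels or "EOG" not in labels:
        raise SynthError("channel list must include an EOG and an ECG channel")
    fs = config.fs
    n = int(round(config.duration_s * fs))
    n_eeg = len(config.eeg_labels)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    blocks = _state_layout(config)

    # --- cardiac ---
    rpeaks = generate_rr_series(
        config.mean_ibi_ms, config.ibi_sd_ms, config.duration_s,
        seed=rng.integers(2**31), fs=fs,
    )
    ecg_clean = synthesize_ecg(
        rpeaks, fs, config.ecg_morphology, n_samples=n
    )
    ecg = ecg_clean + colored_noise(
        n, config.noise_spec.ecg_rms_uv, 0.5, rng
    )[0]

    # --- EOG: noise + EM bursts in phasic blocks only ---
    eog = colored_noise(n, config.noise_spec.eog_rms_uv,
                        config.noise_spec.exponent, rng)[0]
    em_source = np.zeros(n)
    em_events: list[tuple[float, float, float]] = []
    burst = _em_burst_waveform(fs, config.em_spec)
    burst_span_s = burst.size / fs
    for on, dur, state in blocks:
        if state != "phasic":
            continue
        start = on + config.em_spec.burst_every_s / 2.0
        while start + burst_span_s < on + dur - 0.2:
            i0 = int(round(start * fs))
            em_source[i0 : i0 + burst.size] += burst
            dur_ms = config.em_spec.duration_ms
            gap = config.em_spec.within_burst_gap_s
            for k in range(config.em_spec.burst_size):
                em_events.append(
                    (start + k * gap, dur_ms, config.em_spec.amplitude_uv)
                )
            start += config.em_spec.burst_every_s
    eog = eog + em_source

    # --- EEG ---
    eeg = colored_noise(
        n, config.noise_spec.eeg_rms_uv, config.noise_spec.exponent, rng,
        size=n_eeg,
    )
    # state-dependent band-limited activity (shared spatial pattern would be
    # unrealistically coherent; draw independent band noise per channel);
    # the two bands are generated sequentially to bound peak memory
    bp = config.band_power_spec
    for band, amp_map in (
        ((10.0, 14.0), bp.alpha_high_uv),
        ((15.0, 28.0), bp.beta_uv),
    ):
        env = np.zeros(n)
        for on, dur, state in blocks:
            i0, i1 = int(round(on * fs)), int(round((on + dur) * fs))
            env[i0:i1] = amp_map.get(state, 0.0)
        if env.any():
            band_x = _band_noise(n, fs, band, rng, n_eeg)
            band_x *= env[None, :]
            eeg += band_x
            del band_x

    # cardiac-field leakage: per-channel gains bounded by ecg_leak_fraction
    leak_gains = config.ecg_leak_fraction * rng.uniform(0.3, 1.0, n_eeg)
    leak_gains *= rng.choice([-1.0, 1.0], size=n_eeg)
    eeg += leak_gains[:, None] * ecg_clean[None, :]

    # EOG-source leakage into frontal EEG, decaying with distance from
    # the frontopolar sites (gives ICA a recoverable source)
    pos = template_positions(config.eeg_labels)
    fp = np.asarray([POSITIONS_1020["Fp1"], POSITIONS_1020["Fp2"]])
    d = np.min(
        np.linalg.norm(pos[:, None, :] - fp[None, :, :], axis=-1), axis=1
    )
    eog_gains = config.eog_leak_gain * np.exp(-d / 0.3)
    eeg += eog_gains[:, None] * em_source[None, :]

    # injected heartbeat-locked component
    spec = config.hep_spec
    topo = hep_topography(config.eeg_labels, spec)
    k_lo = int(round((spec.center_ms - 4 * spec.sigma_ms) / 1000 * fs))
    k_hi = int(round((spec.center_ms + 4 * spec.sigma_ms) / 1000 * fs))
    rel_ms = np.arange(k_lo, k_hi + 1) * 1000.0 / fs
    kernel = np.exp(-0.5 * ((rel_ms - spec.center_ms) / spec.sigma_ms) ** 2)
    block_onsets = np.asarray([b[0] for b in blocks])
    block_states = [b[2] for b in blocks]
    for r in rpeaks.peak_samples:
        t_r = r / fs
        j = int(np.searchsorted(block_onsets, t_r, side="right")) - 1
        if j < 0:
            continue
        on, dur, state = blocks[j]
        if not on <= t_r < on + dur:
            continue
        amp = spec.amplitude_uv.get(state, 0.0)
        if amp == 0.0:
            continue
        a, b = r + k_lo, r + k_hi + 1
        ta, tb = max(0, -a), (b - a) - max(0, b - n)
        a, b = max(a, 0), min(b, n)
        if a < b:
            eeg[:, a:b] += amp * topo[:, None] * kernel[ta:tb][None, :]

    signals = np.vstack([eeg, eog[None, :], ecg[None, :]])
    recording = ContinuousRecording(
        signals=signals,
        fs=fs,
        labels=labels,
        channel_types=["EEG"] * n_eeg + ["EOG", "ECG"],
    )

    # ground truth
    segs = [
        Segment(onset_s=on + (dur - 4.0) / 2.0, state=state)
        for on, dur, state in blocks
    ]
    true_segments = SegmentSet(segs, {"source": "generator"})
    n_wake_epochs = int(round(config.wake_duration_s / 30.0))
    n_rem_epochs = int(round(config.rem_duration_s / 30.0))
    hyp = Hypnogram(["W"] * n_wake_epochs + ["REM"] * n_rem_epochs)
    truth = GroundTruth(
        true_rpeaks=rpeaks.peak_samples.copy(),
        true_em_events=em_events,
        true_segments=true_segments,
        state_intervals=blocks,
        injected_hep=spec,
        hypnogram=hyp,
        ecg_leak_gains=leak_gains,
        eog_leak_gains=eog_gains,
    )
    return recording, truth


def synthesize_cohort(
    n_subjects: int, config: SynthConfig, seed: int | None = None
):
    """Yield ``(subject_id, recording, ground_truth)`` for a cohort.

    Per-subject seeds are spawned deterministically from ``seed`` (falling
    back to ``config.seed``).
    """
    import copy

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    for i, child in enumerate(root.spawn(n_subjects)):
        cfg = copy.deepcopy(config)
        cfg.seed = int(child.generate_state(1)[0] % (2**31))
        yield f"S{i + 1:02d}", *synthesize_recording(cfg)


# ---------------------------------------------------------------------------
# Cohort-level generator (subject condition averages)
# ---------------------------------------------------------------------------


def synthesize_hep_cohort(
    n_subjects: int = 12,
    labels: list[str] | None = None,
    fs: float = 256.0,
    effect_uv: float = 0.0,
    n_trials: int = 300,
    noise_rms_uv: float = 20.0,
    between_subject_sd_uv: float = 0.5,
    hep_spec: HEPSpec | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-subject condition-average pairs (A, B) directly.

    Models the sampling distribution of a subject's trial average: 1/f
    residual noise with RMS ``noise_rms_uv / sqrt(n_trials)`` per channel,
    plus — in condition A only — the heartbeat-locked bump with amplitude
    ``effect_uv`` (jittered across subjects by ``between_subject_sd_uv``)
    under the fronto-central topography.  ``effect_uv=0`` gives an exact
    null cohort.  Averages are baseline-corrected over -200..-50 ms like
    the pipeline's.

    Returns ``(a, b, times_ms)`` with shapes (n_subjects, n_ch, n_times).
    """
    labels = list(EEG_LABELS_19) if labels is None else labels
    spec = hep_spec or HEPSpec()
    rng = np.random.default_rng(seed)
    n_ch = len(labels)
    lo = int(round(-0.2 * fs))
    hi = int(round(0.8 * fs))
    times_ms = np.arange(lo, hi) * 1000.0 / fs
    n_t = times_ms.size
    resid_rms = noise_rms_uv / np.sqrt(n_trials)
    topo = hep_topography(labels, spec)
    kernel = np.exp(-0.5 * ((times_ms - spec.center_ms) / spec.sigma_ms) ** 2)

    a = colored_noise(n_t, resid_rms, 1.0, rng, size=n_subjects * n_ch)
    b = colored_noise(n_t, resid_rms, 1.0, rng, size=n_subjects * n_ch)
    a = a.reshape(n_subjects, n_ch, n_t)
    b = b.reshape(n_subjects, n_ch, n_t)
    if effect_uv != 0.0 or between_subject_sd_uv > 0.0:
        amps = rng.normal(effect_uv, between_subject_sd_uv, n_subjects)
        a += amps[:, None, None] * topo[None, :, None] * kernel[None, None, :]
    base = (times_ms >= -200.0) & (times_ms <= -50.0)
    a -= a[:, :, base].mean(axis=2, keepdims=True)
    b -= b[:, :, base].mean(axis=2, keepdims=True)
    return a, b, times_ms
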