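"""EEG preprocessing: zero-phase band-pass filtering and ICA-based removal
of rapid-eye-movement components.

Filtering uses a fourth-order Butterworth band-pass applied forward and
backward (two-pass, hence zero phase).  Eye-movement artifact components
are estimated by ICA on the EEG concatenated across the selected phasic,
tonic and wake segments, flagged by the correlation of their time course
with the EOG channel, and subtracted from the continuous EEG.  Cardiac
artifacts are deliberately *not* removed by ICA: ICA cleaning can remove
genuine heartbeat-evoked signal, so cardiac-field confounds are handled
statistically downstream (see :mod:`hepsleep.confounds`).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA


class PreprocessError(ValueError):
    pass


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 0.5, high: float = 35.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (two-pass, DC removed).

    Works on the last axis; accepts 1-D or (channels, samples) input.
    """
    if not (0 < low < high < fs / 2):
        raise PreprocessError(
            f"infeasible band {low}-{high} Hz at fs={fs} Hz"
        )
    sos = sps.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


@dataclass
class ICADecomposition:
    """Fitted ICA with the eye-movement components flagged for removal."""

    unmixing: np.ndarray  # (n_comp, n_ch)
    mixing: np.ndarray  # (n_ch, n_comp)
    mean: np.ndarray  # (n_ch,)
    removed: list[int]
    eog_correlations: np.ndarray  # (n_comp,)

    def __post_init__(self) -> None:
        if len(self.removed) > 4:
            raise PreprocessError("at most four components may be removed")

    def sources(self, eeg: np.ndarray) -> np.ndarray:
        """Component time courses for (n_ch, n_samples) EEG."""
        return self.unmixing @ (eeg - self.mean[:, None])

    def clean(self, eeg: np.ndarray) -> np.ndarray:
        """Reconstruct EEG with the flagged components subtracted."""
        if not self.removed:
            return eeg.copy()
        s = self.sources(eeg)
        contrib = self.mixing[:, self.removed] @ s[self.removed]
        return eeg - contrib


def _concatenate_segments(x: np.ndarray, fs: float, segments) -> np.ndarray:
    parts = []
    for seg in segments:
        lo = int(round(seg.onset_s * fs))
        hi = lo + int(round(seg.duration_s * fs))
        parts.append(x[..., lo:hi])
    return np.concatenate(parts, axis=-1)


def remove_em_components(
    recording,
    segments,
    corr_thresh: float = 0.4,
    max_remove: int = 4,
    seed: int | None = 0,
    n_components: int | None = None,
    max_iter: int = 800,
    tol: float = 1e-3,
):
    """Fit ICA on segment-concatenated EEG and remove EM components.

    Components are ranked by the absolute Pearson correlation of their
    time course with the (band-passed) EOG channel over the same
    concatenated spans; those above ``corr_thresh`` are flagged, at most
    ``max_remove`` (the top ones by |r|) are removed.  The cleaned EEG is
    reconstructed over the *whole* continuous recording; EOG and ECG
    channels are untouched.

    The decomposition is fit in a PCA-reduced space (default
    ``min(n_eeg, 12)`` components): background EEG is close to Gaussian,
    and fixed-point ICA converges poorly on a full-rank near-Gaussian
    subspace, while the strongly non-Gaussian eye-movement sources live
    in the leading components.  On non-convergence the fit is retried
    with a smaller dimension and a fresh seed before raising.

    Returns ``(cleaned_recording, ICADecomposition)``.
    """
    from .psg_io import ContinuousRecording

    eeg_idx = recording.picks("EEG")
    eog_idx = recording.picks("EOG")
    if len(eeg_idx) < 2:
        raise PreprocessError("ICA needs at least two EEG channels")
    if not eog_idx:
        raise PreprocessError("no EOG channel to correlate components with")
    if len(segments) == 0:
        raise PreprocessError("no segments to concatenate for ICA")

    fs = recording.fs
    eeg = recording.signals[eeg_idx]
    eog = recording.signals[eog_idx[0]]
    eeg_cat = _concatenate_segments(eeg, fs, segments)
    eog_cat = _concatenate_segments(eog, fs, segments)

    base = min(len(eeg_idx), 12) if n_components is None else n_components
    base_seed = 0 if seed is None else int(seed)
    ica = sources = None
    attempts = []
    for k, n_comp in enumerate(dict.fromkeys(
        [base, max(4, base - 2), max(4, base - 4)]
    )):
        cand = FastICA(
            n_components=n_comp,
            whiten="unit-variance",
            random_state=base_seed + k,
            max_iter=max_iter,
            tol=tol,
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            out = cand.fit_transform(eeg_cat.T).T  # (n_comp, n_samples)
        attempts.append((n_comp, cand.n_iter_))
        if cand.n_iter_ < max_iter:
            ica, sources = cand, out
            break
    if ica is None:
        raise PreprocessError(
            "ICA did not converge; attempts (n_components, iterations): "
            f"{attempts} with max_iter={max_iter}, tol={tol}"
        )
    n_comp = sources.shape[0]

    ec = eog_cat - eog_cat.mean()
    denom_e = np.sqrt((ec**2).sum())
    corrs = np.zeros(n_comp)
    if denom_e > 0:
        for k in range(n_comp):
            sk = sources[k] - sources[k].mean()
            denom_s = np.sqrt((sk**2).sum())
            if denom_s > 0:
                corrs[k] = float((sk @ ec) / (denom_s * denom_e))

    flagged = np.flatnonzero(np.abs(corrs) > corr_thresh)
    flagged = flagged[np.argsort(-np.abs(corrs[flagged]))][:max_remove]
    decomp = ICADecomposition(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        mean=ica.mean_,
        removed=[int(k) for k in flagged],
        eog_correlations=corrs,
    )

    cleaned = recording.signals.copy()
    cleaned[eeg_idx] = decomp.clean(eeg)
    out = ContinuousRecording(
        signals=cleaned,
        fs=fs,
        labels=list(recording.labels),
        channel_types=list(recording.channel_types),
        start_time=recording.start_time,
    )
    return out, decomp
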