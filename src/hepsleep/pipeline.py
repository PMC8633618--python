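"""End-to-end study orchestration: recordings in, statistics report out.

:class:`HEPStudy` is the top-level model object.  It is built from a list
of subjects (each a continuous polysomnography recording plus a 30-s-epoch
hypnogram), or synthesized from a :class:`~hepsleep.synthpsg.SynthConfig`;
``fit()`` executes the study in the canonical order:

1. REM microstate segmentation (phasic / tonic) and wake segment selection;
2. 0.5-35 Hz band-pass filtering and ICA removal of eye-movement components;
3. R-peak detection, per-condition epoching (-200..+800 ms), baseline
   correction (-200..-50 ms), trial-count screening (< 200 excludes);
4. paired cluster-based permutation contrasts (phasic-tonic, phasic-wake,
   tonic-wake) in the 350-650 ms window;
5. ECG confound suite on the winning phasic-tonic cluster's window;
6. the surrogate-heartbeat specificity test.

The returned :class:`StudyResults` carries every stage's output and a
``summary()`` table; two runs with the same config and inputs produce
identical results (all randomness flows from the config seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import confounds as cf
from .cardiac import detect_r_peaks, heart_rate_bpm, sdnn_ms
from .hep import (
    MIN_TRIALS,
    average_hep,
    baseline_correct,
    extract_epochs,
    screen_subjects,
)
from .microstates import classify_rem_segments, select_wake_segments
from .permstats import (
    ClusterPermutationTest,
    bh_fdr,
    pointwise_permutation_test,
)
from .preprocess import bandpass_filter, remove_em_components
from .psg_io import ContinuousRecording, Hypnogram
from .surrogate import SubjectData, surrogate_specificity_test
from .synthpsg import SynthConfig, synthesize_cohort


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Study-level knobs: mode, analysis window, permutation counts, seeds."""

    study_mode: str = "study1"  # "study1": 100-segment cap; "study2": >=6 min
    window_ms: tuple[float, float] = (350.0, 650.0)
    n_permutations: int = 5000
    n_surrogates: int = 100
    min_trials: int = MIN_TRIALS
    alpha: float = 0.05
    min_neighbors: int = 2
    cap_per_state: int | None = None
    min_total_s_per_state: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_mode not in ("study1", "study2"):
            raise PipelineError(f"unknown study mode {self.study_mode!r}")
        lo, hi = self.window_ms
        if not lo < hi:
            raise PipelineError(f"empty analysis window {self.window_ms}")
        if lo < -200.0 or hi > 800.0:
            raise PipelineError("analysis window outside the epoch span")
        if self.cap_per_state is None and self.study_mode == "study1":
            self.cap_per_state = 100
        if self.min_total_s_per_state is None and self.study_mode == "study2":
            self.min_total_s_per_state = 360.0


@dataclass
class SubjectInput:
    subject_id: str
    recording: ContinuousRecording
    hypnogram: Hypnogram


@dataclass
class SubjectOutput:
    """Per-subject bookkeeping: counts and cardiac summaries."""

    subject_id: str
    n_segments: dict[str, int]
    n_trials: dict[str, int]
    n_dropped: dict[str, int]
    removed_components: list[int]
    hr_bpm: dict[str, float]
    sdnn_ms: dict[str, float]


@dataclass
class StudyResults:
    """Everything the study computed, machine- and human-readable."""

    config: PipelineConfig
    subjects: list[SubjectOutput]
    included: list[str]
    excluded: dict[str, str]
    cluster_results: dict  # contrast name -> ClusterPermutationResults
    confound_report: dict | None
    surrogate_null: object | None
    log: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Heartbeat-evoked potential study",
            f"  mode: {self.config.study_mode}   "
            f"window: {self.config.window_ms[0]:.0f}-"
            f"{self.config.window_ms[1]:.0f} ms   seed: {self.config.seed}",
            f"  subjects: {len(self.subjects)} "
            f"({len(self.included)} included, {len(self.excluded)} excluded)",
        ]
        for name, res in self.cluster_results.items():
            lines.append(f"-- contrast {name}:")
            lines.extend("  " + ln for ln in res.summary().splitlines()[1:])
        if self.confound_report:
            ecg = self.confound_report["ecg_window_comparison"]
            an = self.confound_report["rm_ancova"]
            rr = self.confound_report["contrast_correlation"]
            lines.append(
                f"-- ECG confounds: {ecg['test']} statistic="
                f"{ecg['statistic']:.3f} p={ecg['p_value']:.3f}; "
                f"ANCOVA condition F{an['df']}={an['f_condition']:.2f} "
                f"p={an['p_condition']:.3f} eta_p2={an['partial_eta_sq']:.2f}; "
                f"HEP-ECG contrast r={rr['r']:.2f} p={rr['p']:.2f}; "
                f"pointwise: {self.confound_report['n_uncorrected_sig']} "
                f"uncorrected / {self.confound_report['n_fdr_sig']} "
                "FDR-significant time points"
            )
        if self.surrogate_null is not None:
            s = self.surrogate_null
            lines.append(
                f"-- surrogate specificity: original mass "
                f"{s.original_mass:.1f} vs {s.n_surrogates} surrogates, "
                f"exceeded by {s.exceedance_count}; "
                + ("PASS (heartbeat-locked)" if s.passed else "FAIL")
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "config": {
                "study_mode": self.config.study_mode,
                "window_ms": list(self.config.window_ms),
                "n_permutations": self.config.n_permutations,
                "n_surrogates": self.config.n_surrogates,
                "min_trials": self.config.min_trials,
                "seed": self.config.seed,
            },
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "n_segments": s.n_segments,
                    "n_trials": s.n_trials,
                    "n_dropped": s.n_dropped,
                    "removed_components": s.removed_components,
                    "hr_bpm": s.hr_bpm,
                    "sdnn_ms": s.sdnn_ms,
                }
                for s in self.subjects
            ],
            "included": self.included,
            "excluded": self.excluded,
            "contrasts": {
                k: v.to_dict() for k, v in self.cluster_results.items()
            },
            "confounds": self.confound_report,
            "surrogate": (
                self.surrogate_null.to_dict()
                if self.surrogate_null is not None
                else None
            ),
            "log": self.log,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


class HEPStudy:
    """The end-to-end heartbeat-evoked-potential study as a model object.

    Parameters
    ----------
    subjects : list of SubjectInput
        Continuous recordings (EEG + EOG + ECG) with hypnograms.
    config : PipelineConfig
    """

    def __init__(self, subjects: list[SubjectInput], config: PipelineConfig
                 | None = None):
        if not subjects:
            raise PipelineError("no subjects")
        self.subjects = subjects
        self.config = config or PipelineConfig()

    @classmethod
    def from_synthetic(
        cls,
        synth_config: SynthConfig,
        n_subjects: int = 12,
        config: PipelineConfig | None = None,
    ) -> "HEPStudy":
        """Build a cohort by synthesizing ``n_subjects`` recordings."""
        subs = []
        truths = {}
        for sid, rec, truth in synthesize_cohort(
            n_subjects, synth_config, seed=synth_config.seed
        ):
            subs.append(SubjectInput(sid, rec, truth.hypnogram))
            truths[sid] = truth
        study = cls(subs, config)
        study.ground_truths = truths
        return study

    # -- stages ------------------------------------------------------------

    def _process_subject(self, sub: SubjectInput, seed: int, log: list[str]):
        cfg = self.config
        rec, hyp = sub.recording, sub.hypnogram
        fs = rec.fs
        eeg_idx = rec.picks("EEG")
        eog_idx = rec.picks("EOG")
        ecg_idx = rec.picks("ECG")
        if not eog_idx or not ecg_idx:
            raise PipelineError(
                f"{sub.subject_id}: recording lacks EOG or ECG channel"
            )
        eog = rec.signals[eog_idx[0]]
        eeg = rec.signals[eeg_idx]

        segments = classify_rem_segments(
            eog, fs, hyp, eeg=eeg,
            cap_per_state=cfg.cap_per_state,
            min_total_s_per_state=cfg.min_total_s_per_state,
            seed=seed, subject_id=sub.subject_id,
        )
        wake = select_wake_segments(
            eog, fs, hyp, eeg=eeg, cap=cfg.cap_per_state,
            seed=seed + 1, subject_id=sub.subject_id,
        )

        filtered = rec.signals.copy()
        filtered[eeg_idx] = bandpass_filter(eeg, fs, 0.5, 35.0)
        frec = ContinuousRecording(
            signals=filtered, fs=fs, labels=list(rec.labels),
            channel_types=list(rec.channel_types),
            start_time=rec.start_time,
        )
        all_segs = list(segments) + list(wake)
        cleaned, decomp = remove_em_components(
            frec, all_segs, seed=seed,
        )
        rpeaks = detect_r_peaks(rec.signals[ecg_idx[0]], fs)

        epochs, ecg_epochs, counts, dropped = {}, {}, {}, {}
        hr, sdnn = {}, {}
        for cond, segset in (
            ("phasic", segments.by_state("phasic")),
            ("tonic", segments.by_state("tonic")),
            ("wake", wake),
        ):
            ep = extract_epochs(
                cleaned, rpeaks, segset, cond, picks=eeg_idx,
                subject_id=sub.subject_id,
            )
            eep = extract_epochs(
                cleaned, rpeaks, segset, cond, picks=ecg_idx,
                subject_id=sub.subject_id,
            )
            counts[cond] = ep.n_trials
            dropped[cond] = ep.n_dropped
            epochs[cond] = baseline_correct(ep) if ep.n_trials else ep
            ecg_epochs[cond] = baseline_correct(eep) if eep.n_trials else eep
            try:
                hr[cond] = heart_rate_bpm(rpeaks, segset)
                sdnn[cond] = sdnn_ms(rpeaks, segset).sdnn_ms
            except Exception:
                hr[cond] = float("nan")
                sdnn[cond] = float("nan")
        log.append(
            f"{sub.subject_id}: segments {segments.counts()} wake "
            f"{len(wake)}; trials {counts}; dropped {dropped}; ICA removed "
            f"{decomp.removed}"
        )
        out = SubjectOutput(
            subject_id=sub.subject_id,
            n_segments={**segments.counts(), "wake": len(wake)},
            n_trials=counts,
            n_dropped=dropped,
            removed_components=decomp.removed,
            hr_bpm=hr,
            sdnn_ms=sdnn,
        )
        # surrogates need all three states; spacing was already enforced
        # within each selection, so the container keeps them per state
        sdata = SubjectData(
            subject_id=sub.subject_id,
            recording=cleaned,
            rpeaks=rpeaks,
            segments=_MultiStateSegments(segments, wake),
        )
        return out, sdata, epochs, ecg_epochs

    def fit(self) -> StudyResults:
        """Run the full study and return the results object."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        log: list[str] = []
        per_subject: list[SubjectOutput] = []
        sdatas: dict[str, SubjectData] = {}
        avgs: dict[str, dict[str, object]] = {"phasic": {}, "tonic": {},
                                              "wake": {}}
        ecg_avgs: dict[str, dict[str, object]] = {"phasic": {}, "tonic": {},
                                                  "wake": {}}
        counts: dict[str, dict[str, int]] = {}
        for sub in self.subjects:
            seed = int(rng.integers(2**31))
            try:
                out, sdata, epochs, ecg_epochs = self._process_subject(
                    sub, seed, log
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage failure for subject {sub.subject_id}: {exc}"
                ) from exc
            per_subject.append(out)
            sdatas[sub.subject_id] = sdata
            counts[sub.subject_id] = out.n_trials
            for cond in ("phasic", "tonic", "wake"):
                if epochs[cond].n_trials:
                    avgs[cond][sub.subject_id] = average_hep(epochs[cond])
                    ecg_avgs[cond][sub.subject_id] = average_hep(
                        ecg_epochs[cond]
                    )

        included, excluded = screen_subjects(counts, cfg.min_trials)
        included = [
            s for s in included
            if all(s in avgs[c] for c in ("phasic", "tonic", "wake"))
        ]
        log.append(f"included {len(included)} subjects; excluded {excluded}")
        if len(included) < 3:
            raise PipelineError(
                "fewer than 3 subjects survive trial screening"
            )

        ref = avgs["phasic"][included[0]]
        labels, times_ms = ref.labels, ref.times_ms

        def stack(cond: str) -> np.ndarray:
            return np.stack([avgs[cond][s].mean for s in included])

        cluster_results = {}
        for name, (ca, cb) in {
            "phasic_vs_tonic": ("phasic", "tonic"),
            "phasic_vs_wake": ("phasic", "wake"),
            "tonic_vs_wake": ("tonic", "wake"),
        }.items():
            model = ClusterPermutationTest(
                stack(ca), stack(cb), labels=labels, times_ms=times_ms,
                window_ms=cfg.window_ms, alpha=cfg.alpha,
                min_neighbors=cfg.min_neighbors,
            )
            cluster_results[name] = model.fit(
                n_permutations=cfg.n_permutations,
                seed=int(rng.integers(2**31)),
            )

        main = cluster_results["phasic_vs_tonic"]
        confound_report = None
        if main.clusters:
            top = main.clusters[0]
            win = main.cluster_window_ms(top)
            chans = main.cluster_channels(top)
            hep_a = np.array([
                cf.window_mean_amplitude(avgs["phasic"][s], win, chans)
                for s in included
            ])
            hep_b = np.array([
                cf.window_mean_amplitude(avgs["tonic"][s], win, chans)
                for s in included
            ])
            ecg_a = np.array([
                cf.window_mean_amplitude(ecg_avgs["phasic"][s], win)
                for s in included
            ])
            ecg_b = np.array([
                cf.window_mean_amplitude(ecg_avgs["tonic"][s], win)
                for s in included
            ])
            cmp_res = cf.compare_conditions_scalar(ecg_a, ecg_b)
            ancova = cf.rm_ancova_condition(hep_a, hep_b, ecg_a - ecg_b)
            try:
                corr = cf.pearson_contrast_correlation(
                    hep_a - hep_b, ecg_a - ecg_b
                )
            except cf.ConfoundError:
                corr = {"r": float("nan"), "p": float("nan"),
                        "n": len(included)}
            ecg_wave_a = np.stack(
                [ecg_avgs["phasic"][s].mean[0] for s in included]
            )
            ecg_wave_b = np.stack(
                [ecg_avgs["tonic"][s].mean[0] for s in included]
            )
            t_pt, p_pt = pointwise_permutation_test(
                ecg_wave_a, ecg_wave_b,
                n_permutations=cfg.n_permutations,
                seed=int(rng.integers(2**31)),
            )
            fdr_mask = bh_fdr(p_pt, q=0.05)
            confound_report = {
                "cluster_window_ms": list(win),
                "cluster_channels": chans,
                "ecg_window_comparison": {
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "effect_size": cmp_res.effect_size,
                },
                "rm_ancova": {
                    "f_condition": ancova.f_condition,
                    "df": list(ancova.df),
                    "p_condition": ancova.p_condition,
                    "partial_eta_sq": ancova.partial_eta_sq,
                    "f_covariate": ancova.f_covariate,
                    "p_covariate": ancova.p_covariate,
                },
                "contrast_correlation": corr,
                "n_uncorrected_sig": int((p_pt < 0.05).sum()),
                "n_fdr_sig": int(fdr_mask.sum()),
            }

        surrogate_null = None
        if cfg.n_surrogates > 0 and main.clusters:
            surrogate_null = surrogate_specificity_test(
                [sdatas[s] for s in included],
                original_mass=main.max_mass,
                n_surrogates=cfg.n_surrogates,
                seed=int(rng.integers(2**31)),
                window_ms=cfg.window_ms,
                alpha=cfg.alpha,
                min_neighbors=cfg.min_neighbors,
            )

        return StudyResults(
            config=cfg,
            subjects=per_subject,
            included=included,
            excluded=excluded,
            cluster_results=cluster_results,
            confound_report=confound_report,
            surrogate_null=surrogate_null,
            log=log,
        )


class _MultiStateSegments:
    """Segments from independent selections (REM and wake), queryable by
    state without re-validating cross-selection spacing."""

    def __init__(self, rem_segments, wake_segments):
        self._rem = rem_segments
        self._wake = wake_segments

    def by_state(self, state: str):
        if state == "wake":
            return self._wake
        return self._rem.by_state(state)

    def __iter__(self):
        yield from self._rem
        yield from self._wake

    def __len__(self):
        return len(self._rem) + len(self._wake)


def run_pipeline(
    synth_config: SynthConfig | None = None,
    subjects: list[SubjectInput] | None = None,
    n_subjects: int = 12,
    config: PipelineConfig | None = None,
) -> StudyResults:
    """One-call study runner (synthetic cohort or provided subjects)."""
    if (synth_config is None) == (subjects is None):
        raise PipelineError(
            "provide exactly one input source (synth_config or subjects)"
        )
    if synth_config is not None:
        study = HEPStudy.from_synthetic(
            synth_config, n_subjects=n_subjects, config=config
        )
    else:
        study = HEPStudy(subjects, config)
    return study.fit()
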