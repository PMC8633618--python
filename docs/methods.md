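# Methods

This note documents the models, parameter choices, numerical decisions and
limitations behind `hepsleep`.

## The measurement problem

A heartbeat-evoked potential (HEP) is the scalp EEG average time-locked to
the ECG R-peak.  Comparing HEPs between phasic and tonic REM microstates
raises three methodological hazards this package is built around:

1. **Mass univariate testing** over channels × time inflates family-wise
   error; handled with cluster-based permutation inference.
2. **Cardiac-field artifact** — volume-conducted ECG (strongest around
   the T wave) contaminates scalp channels at < 1% of the chest
   amplitude; handled with a battery of ECG confound controls rather
   than ICA (which can delete genuine HEP signal).
3. **State-dependent background oscillations** — phasic and tonic REM
   differ in ongoing high-alpha (10–14 Hz) and beta (15–28 Hz) power, so
   an apparent "HEP difference" could be unlocked background activity;
   handled with the surrogate-heartbeat specificity test.

## Microstate segmentation

Eye movements are detected on the 0.5–30 Hz band-passed bipolar EOG as
contiguous excursions (relative to the channel median) whose peak reaches
100 μV and whose width above half-peak stays below 500 ms.  A 4-s window
is phasic when it holds at least two *consecutive* eye movements; the
unstated inter-movement gap is operationalized as onsets ≤ 1 s apart,
since REM eye-movement bursts do not exceed ~2 Hz.  A window is tonic
when the band-passed EOG never deviates more than 25 μV from the window
median (band-passed rather than raw, for symmetry with detection).
Windows between the two criteria stay unlabeled.  Candidates tile REM
epochs on a 1-s stride; selection is greedy by onset under an 8-s
edge-to-edge gap (the stricter reading of the spacing rule), with a
seeded random sub-sample when a per-state cap (study-1 mode: 100) is
set.  Human visual artifact screening is replaced by an automated veto:
windows whose EEG RMS exceeds 5× the recording's median 4-s-window RMS
are dropped.  Wake segments (eyes closed, pre-sleep-onset preferred) are
selected with identical machinery.

## Cardiac analysis

R-peak detection is the classic energy recipe: band-pass 5–30 Hz,
differentiate, square, 150 ms moving-window integrate, block-adaptive
threshold (half of each 10-s block's 98th percentile, floored at 10% of
the global level), 250 ms refractory, polarity by majority vote over the
dominant raw excursion near each candidate, and refinement to the raw
extremum within ±50 ms.  A review CSV export allows manual override,
replacing the semi-automatic marking workflow with a reproducible one.

SDNN is the sample standard deviation (n−1) of inter-beat intervals whose
both endpoints fall in selected segments.  Because the normalization "by
the available number of RR intervals" admits more than one reading, both
the raw SDNN (default) and an SDNN/√n variant are provided and the mode
is always recorded in the output; neither is asserted to be the original
computation.  Frequency-domain HRV is out of scope: 4-s non-contiguous
segments cannot support it.

## Preprocessing

EEG is band-passed 0.5–35 Hz with a fourth-order Butterworth applied
forward and backward (zero phase).  ICA is fit on the EEG concatenated
across all selected segments; components are flagged when the absolute
correlation of their time course with the EOG exceeds 0.4 (conservative,
configurable), at most four are removed, and the cleaned EEG is
reconstructed over the whole recording.  The decomposition uses seeded
FastICA in a PCA-reduced space (12 components by default): background
EEG is close to Gaussian, where fixed-point ICA is ill-posed, while
eye-movement sources are strongly non-Gaussian and live in the leading
subspace.  Non-convergence after a retry ladder (smaller dimension,
fresh seed) raises an error carrying the iteration diagnostics.

## HEP construction

Epochs span −200..+800 ms around each R-peak inside a selected segment
(half-open sample window, `round` at non-integer fs·ms products; the
R-peak is the time-0 sample).  Epochs may extend past the 4-s segment
into adjacent clean data — the trial is anchored to the beat, not the
segment — but artifact-flagged spans veto.  Baseline is the −200..−50 ms
mean, stopping early to avoid the rising R edge; ECG epochs are treated
identically to EEG epochs (a deliberate symmetry choice).  Subjects with
fewer than 200 artifact-free trials in any condition are excluded
(boundary inclusive at 200).

## Cluster-based permutation inference

Paired t statistics are computed at every (channel, time) sample
(df = n−1; zero-variance samples get t = 0 and are counted as
degenerate).  Samples exceeding the two-tailed critical value at
α = 0.05 are clustered by connectivity: adjacent time points on the same
channel, or spatially neighboring channels at the same time point.
Spatial neighborhoods come from schematic 2-D 10–20 template positions
with a distance threshold of 0.62 (unit head radius), giving a median of
four neighbors on the 19-channel montage; T3/T4/T5/T6 naming is native,
modern aliases accepted.  The "at least two neighboring channels" rule
is implemented as a single-pass pruning step — a suprathreshold sample
survives only if ≥ 2 of its spatial neighbors are suprathreshold at the
same time point (configurable to 0 = off).  Cluster mass is the sum of
member t values (t_maxsum).  The null distribution records, for each of
5,000 per-subject random condition exchanges (sign flips of the
difference maps — the standard paired scheme), the maximum |mass| over
both signs; cluster p = (1 + #{null ≥ |mass|}) / (1 + n_perm), the +1
guarding against p = 0.  Positive and negative clusters are both tested
against the same max-|mass| null; the `significant()` accessor defaults
to 0.025 per tail, with raw p always reported.  The analysis window
defaults to 350–650 ms post-R, where cardiac-field contamination from
the R and T waves is unlikely.  Permutation t maps are computed in
vectorized batches (only the sign-weighted sums vary across flips; the
sum of squares is flip-invariant), which makes 1,000-permutation runs on
a 19 × ~80 grid take well under a second.

The ECG pointwise test compares the observed per-time-point paired t
against the sign-flip null *at that time point*, two-tailed, with
Benjamini–Hochberg FDR (via statsmodels) available for correction.

## Surrogate specificity

Surrogate R-peaks preserve, per condition, the per-segment beat count
and the pooled in-segment IBI multiset: the multiset is permuted across
segments and each segment's train is re-anchored at a uniform random
offset (an IBI-resampling variant is available behind a flag).  A train
that does not fit its segment falls back to that segment's own shuffled
intervals.  Surrogates are drawn per participant per replicate (the
stronger null).  Each replicate re-epochs, re-averages and re-forms
clusters in the analysis window; only the maximum |mass| is needed, so
no inner permutation loop runs.  The verdict: with N surrogates the
original mass must exceed the `round(0.05·N)` largest surrogate masses
(the top-5 rule at N = 100).  An original mass of zero therefore always
fails.

## ECG confound suite

Within the winning cluster's window: (1) the subject-wise mean ECG
amplitude is compared between conditions with a paired t, or the exact
signed-rank test when Shapiro–Wilk (α = 0.05, on differences) rejects
normality — Cohen's d or rank-biserial r reported accordingly, zero
differences dropped per Wilcoxon's convention; (2) a repeated-measures
ANCOVA regresses HEP amplitude on condition with the centered
phasic−tonic ECG contrast as covariate.  With two within-subject levels
this reduces exactly to OLS of the difference scores on the centered
covariate: the intercept test is the adjusted condition effect,
F(1, n−2); the slope test is the covariate effect; with a constant
covariate the model falls back to the paired t (F(1, n−1) = t²).
Partial η² = F/(F + df_err).  (3) Pearson correlation between HEP and
ECG contrasts.

## The synthetic generator

The generator emulates the study conditions so that every stage has a
ground-truth oracle.  Fixed choices (units μV, ms):

| quantity | default | rationale |
|---|---|---|
| EEG background | 1/f, 20 μV RMS | desynchronized REM EEG amplitude |
| EOG baseline noise | 1/f, 5 μV RMS | quiet bipolar EOG between bursts |
| band power (10–14 Hz) | tonic 6 / phasic 2 / wake 8 μV RMS | tonic > phasic; eyes-closed wake alpha strongest |
| band power (15–28 Hz) | tonic 4 / phasic 1.5 / wake 2 μV RMS | tonic > phasic |
| IBI model | truncated normal, mean 1000, SD 55, bounds 250–2000 ms | ~60 bpm, SDNN in the 50–62 ms range; simplest two-moment model |
| ECG morphology | Q −120/R 1000/S −200 Gaussians + T 300 μV at +300 ms (σ 60) | chest-lead scale; T wave present so T-window confounds are exercisable |
| cardiac-field leakage | 0.5% per channel (< 1% bound) | reported artifact attenuation at the scalp |
| EM bursts | 3 biphasic deflections, 200 μV, 250 ms, 350 ms apart, every 4 s in phasic blocks | satisfies the ≥ 2 × ≥ 100 μV × < 500 ms phasic criterion |
| EOG→EEG mixing | gain 0.3 at Fp1/Fp2, exponential decay (space constant 0.3) | recoverable ICA source |
| injected HEP | Gaussian bump, center 600 ms, σ 40 ms; amplitudes phasic 2.5 / tonic 1.0 / wake 1.0 | straddles the late-window effect; phasic−tonic difference +1.5 μV |
| HEP topography | Gaussian on the template scalp at (0, 0.25), σ 0.7 | substantial weight over ~8 fronto-central sites, matching the spatial extent such effects show |

The timeline is blocks of 20 s — wake first (eyes closed, pre-sleep),
then alternating phasic/tonic REM — with one ground-truth 4-s segment
centered per block (which automatically satisfies the 8-s rule) and a
30-s-epoch hypnogram to match.  Per-subject cohort seeds are spawned
deterministically from a root seed; identical configs give bit-identical
recordings.

What the generator does **not** model: sleep spindles and K-complexes,
respiration and movement artifacts, realistic PQRST beyond QRS+T,
non-stationary heart-rate drift, electrode pops, or volume-conduction
correlation structure between EEG channels (channels are independent
noise plus shared sources).  Passing tests therefore demonstrate the
*statistical machinery* under controlled conditions — calibration,
power, specificity — not robustness to every artifact class of real
polysomnography.

A cohort-level shortcut, `synthesize_hep_cohort`, draws per-subject
condition *averages* directly: 1/f residual noise scaled by
RMS/√n_trials (default 300 trials, matching the per-subject trial counts
such studies report) plus the injected bump with a 0.5 μV
between-subject amplitude SD.  Calibration studies that need hundreds of
cohorts use this route; the full recording path is exercised end-to-end
in the pipeline and surrogate tests.

## Problem sizes in the test and acceptance runs

Chosen as the package's own desk-scale defaults: calibration uses 200
null cohorts (n = 12, 19 channels, 256 Hz cohort averages, 1,000
permutations); effect recovery 20 cohorts of the same shape; surrogate
controls 10 + 10 cohorts (n = 8 subjects, 30 segments/state, 128 Hz, 25
surrogates — the pass rule scales to "beat the single largest mass");
the end-to-end study n = 12 subjects at 60 segments/state and 128 Hz
with 1,000 permutations and 25 surrogates.  The surrogate positive
control injects a 3 μV locked difference: the control probes event
locking, not minimal detectable amplitude, so it is run in a clearly
powered regime.  Exhaustive-enumeration checks use n = 6 subjects (64
sign flips) on a 5-channel chain.

## Known limitations

* The sign-flip null assumes symmetric difference distributions under
  H0; heavy asymmetry at tiny n would distort calibration.
* Single-pass neighbor pruning (the two-neighbor rule) is one reading of
  the cluster-extent requirement; the toggle `min_neighbors=0` recovers
  plain connectivity clustering.
* EDF support is the plain 16-bit dialect with equal per-channel rates
  and 1-s records; EDF+ TAL annotations, BDF and discontinuous records
  are not parsed (annotations travel in CSV/JSON sidecars).
* The ANCOVA is exact only for the two-level within-subject design; it
  does not generalize to more conditions.
* Wilcoxon p values are exact for n ≤ 25 non-zero differences and
  asymptotic beyond.
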