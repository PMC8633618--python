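"""Cardiac-artifact confound controls for HEP condition differences.

A scalp HEP difference between phasic and tonic REM could in principle be
volume-conducted ECG rather than cortical signal.  The controls implemented
here mirror the standard defence: (1) compare the *ECG channel's* average
amplitude between conditions inside the significant cluster's window
(paired t, or exact Wilcoxon signed-rank when the differences are
non-normal by Shapiro-Wilk); (2) a repeated-measures ANCOVA asking whether
the condition effect on HEP amplitude survives controlling for the
phasic-tonic ECG amplitude contrast; (3) the Pearson correlation between
HEP contrasts and ECG contrasts; and (4) a full-range pointwise permutation
test on the ECG waveforms with uncorrected and FDR-corrected p values
(see :func:`hepsleep.permstats.pointwise_permutation_test`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .hep import HEPAverage


class ConfoundError(ValueError):
    pass


def window_mean_amplitude(
    average: HEPAverage,
    window_ms: tuple[float, float],
    channels: list[str] | None = None,
) -> float:
    """Mean amplitude over a channel x time submatrix of a subject average.

    ``channels=None`` uses all channels of the average (the single-channel
    case for ECG averages).
    """
    t = average.times_ms
    mask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not mask.any():
        raise ConfoundError(f"window {window_ms} contains no samples")
    if channels is None:
        rows = np.arange(len(average.labels))
    else:
        if not channels:
            raise ConfoundError("empty channel set")
        rows = np.asarray([average.labels.index(c) for c in channels])
    return float(average.mean[np.ix_(rows, np.flatnonzero(mask))].mean())


@dataclass
class PairedComparison:
    """Outcome of a paired two-condition comparison on scalars."""

    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    effect_size: float  # Cohen's d (t) or rank-biserial r (Wilcoxon)
    shapiro_p: float
    n: int


def compare_conditions_scalar(
    x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05
) -> PairedComparison:
    """Paired t or exact Wilcoxon signed-rank, gated by Shapiro-Wilk.

    The normality gate runs on the paired differences; with normal
    differences a paired t is used (Cohen's d effect size), otherwise the
    signed-rank test with its exact null for n <= 25 (rank-biserial
    effect size).  Zero differences are dropped per Wilcoxon's original
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ConfoundError("need paired 1-D vectors with n >= 3")
    d = x - y
    if np.allclose(d, 0.0):
        return PairedComparison("degenerate", 0.0, 1.0, 0.0, 1.0, x.size)
    if np.ptp(d) == 0:  # constant nonzero differences: SW undefined
        sw_p = 0.0
    else:
        sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= normality_alpha:
        t_stat, p = stats.ttest_rel(x, y)
        d_cohen = float(np.mean(d) / np.std(d, ddof=1))
        return PairedComparison(
            "paired_t", float(t_stat), float(p), d_cohen, sw_p, x.size
        )
    nz = d[d != 0]
    method = "exact" if nz.size <= 25 else "auto"
    res = stats.wilcoxon(nz, method=method)
    n = nz.size
    total = n * (n + 1) / 2.0
    w_plus = float(stats.rankdata(np.abs(nz))[nz > 0].sum())
    rb = 2.0 * w_plus / total - 1.0  # rank-biserial correlation
    return PairedComparison(
        "wilcoxon", float(res.statistic), float(res.pvalue), rb, sw_p, x.size
    )


@dataclass
class RMAncovaResult:
    """Condition main effect adjusted for a subject-level covariate."""

    f_condition: float
    df: tuple[int, int]
    p_condition: float
    partial_eta_sq: float
    f_covariate: float | None
    p_covariate: float | None
    covariate_defined: bool


def rm_ancova_condition(
    hep_a: np.ndarray, hep_b: np.ndarray, ecg_contrast: np.ndarray
) -> RMAncovaResult:
    """Repeated-measures ANCOVA for a two-level within-subject factor with
    a subject-level covariate.

    With two conditions the model reduces exactly to a regression of the
    within-subject differences d_i = a_i - b_i on the centered covariate:
    the intercept test is the covariate-adjusted condition main effect,
    F(1, n-2); the slope test is the covariate (condition x covariate)
    effect.  With a constant covariate the covariate effect is undefined
    and the condition test falls back to the paired t (F(1, n-1) = t^2).
    """
    a = np.asarray(hep_a, dtype=float)
    b = np.asarray(hep_b, dtype=float)
    cov = np.asarray(ecg_contrast, dtype=float)
    if not (a.shape == b.shape == cov.shape) or a.ndim != 1:
        raise ConfoundError("equal-length 1-D vectors required")
    n = a.size
    if n < 4:
        raise ConfoundError("need at least 4 subjects")
    d = a - b
    if np.allclose(d, 0.0):
        # identical conditions: no effect, nothing for the covariate
        return RMAncovaResult(
            f_condition=0.0,
            df=(1, n - 2 if np.ptp(cov) > 0 else n - 1),
            p_condition=1.0,
            partial_eta_sq=0.0,
            f_covariate=0.0 if np.ptp(cov) > 0 else None,
            p_covariate=1.0 if np.ptp(cov) > 0 else None,
            covariate_defined=bool(np.ptp(cov) > 0),
        )
    if np.ptp(cov) == 0:
        t_stat, p = stats.ttest_rel(a, b)
        f = float(t_stat**2)
        return RMAncovaResult(
            f_condition=f,
            df=(1, n - 1),
            p_condition=float(p),
            partial_eta_sq=f / (f + (n - 1)),
            f_covariate=None,
            p_covariate=None,
            covariate_defined=False,
        )
    xc = cov - cov.mean()
    X = sm.add_constant(xc)
    fit = sm.OLS(d, X).fit()
    t_int = fit.tvalues[0]
    t_slope = fit.tvalues[1]
    f_cond = float(t_int**2)
    f_cov = float(t_slope**2)
    dfe = n - 2
    return RMAncovaResult(
        f_condition=f_cond,
        df=(1, dfe),
        p_condition=float(fit.pvalues[0]),
        partial_eta_sq=f_cond / (f_cond + dfe),
        f_covariate=f_cov,
        p_covariate=float(fit.pvalues[1]),
        covariate_defined=True,
    )


def pearson_contrast_correlation(
    hep_contrast: np.ndarray, ecg_contrast: np.ndarray
) -> dict[str, float]:
    """Pearson r (two-tailed p) between HEP and ECG condition contrasts."""
    x = np.asarray(hep_contrast, dtype=float)
    y = np.asarray(ecg_contrast, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ConfoundError("need 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfoundError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": x.size}
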