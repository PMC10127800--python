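"""Trace-level summary statistics for evoked dopamine transients.

Three quantities summarise a stimulated FSCV trace: the evoked peak
amplitude above pre-stimulus baseline, the clearance half-time t½ (time
from the peak until the signal first falls to half the evoked amplitude),
and the coefficient of determination R² of a model fit.  Group contrasts
of these metrics use Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import FSCVRecording, StimulusProtocol, ValidationError

__all__ = [
    "TraceMetrics",
    "MetricUndefinedError",
    "peak_amplitude",
    "clearance_half_time",
    "trace_metrics",
    "r_squared",
    "welch_t",
]


class MetricUndefinedError(ValueError):
    """The requested metric is not defined for this trace."""


@dataclass(frozen=True)
class TraceMetrics:
    """Summary of a single evoked transient (amplitudes in μM, times in s)."""

    peak_amplitude: float
    peak_time: float
    t_half: float
    baseline: float


def _baseline(rec: FSCVRecording, protocol: StimulusProtocol) -> float:
    pre = rec.signal[rec.time < protocol.onset]
    if pre.size == 0:
        raise MetricUndefinedError(
            "baseline undefined: no samples before stimulus onset"
        )
    return float(pre.mean())


def peak_amplitude(
    rec: FSCVRecording, protocol: StimulusProtocol
) -> tuple[float, float]:
    """Evoked peak amplitude above baseline and its time.

    Baseline is the mean of all pre-onset samples; the peak is the maximum
    of ``signal − baseline`` at or after onset, earliest sample on ties.
    """
    base = _baseline(rec, protocol)
    post = rec.time >= protocol.onset
    if not post.any():
        raise MetricUndefinedError("no samples at or after stimulus onset")
    seg = rec.signal[post] - base
    i = int(np.argmax(seg))  # argmax returns the first maximiser
    return float(seg[i]), float(rec.time[post][i])


def clearance_half_time(rec: FSCVRecording, protocol: StimulusProtocol) -> float:
    """Time from the evoked peak until the signal first falls to half-peak.

    The crossing level is ``baseline + 0.5 · amplitude``; the crossing time
    is linearly interpolated between the two samples bracketing the first
    downward crossing after the peak.  Raises
    :class:`MetricUndefinedError` if the trace never decays that far.
    """
    base = _baseline(rec, protocol)
    amp, t_peak = peak_amplitude(rec, protocol)
    if amp <= 0:
        raise MetricUndefinedError("half-time undefined: no positive evoked peak")
    level = base + 0.5 * amp
    after = rec.time > t_peak
    t = rec.time[after]
    y = rec.signal[after]
    below = np.flatnonzero(y <= level)
    if below.size == 0:
        raise MetricUndefinedError(
            "half-time undefined: signal never decays to half-peak within the recording"
        )
    j = int(below[0])
    if j == 0:
        t_prev, y_prev = t_peak, base + amp
    else:
        t_prev, y_prev = t[j - 1], y[j - 1]
    if y[j] == y_prev:  # flat segment sitting exactly on the level
        t_cross = t[j]
    else:
        t_cross = t_prev + (y_prev - level) * (t[j] - t_prev) / (y_prev - y[j])
    return float(t_cross - t_peak)


def trace_metrics(rec: FSCVRecording, protocol: StimulusProtocol) -> TraceMetrics:
    """Bundle baseline, peak and t½ for one recording."""
    base = _baseline(rec, protocol)
    amp, t_peak = peak_amplitude(rec, protocol)
    t_half = clearance_half_time(rec, protocol)
    return TraceMetrics(
        peak_amplitude=amp, peak_time=t_peak, t_half=t_half, baseline=base
    )


def r_squared(observed: FSCVRecording, predicted: FSCVRecording) -> float:
    """Coefficient of determination of ``predicted`` against ``observed``.

    ``1 − SS_res/SS_tot`` with ``SS_tot`` about the observed mean; requires
    identical time grids and a non-constant observed signal.
    """
    if observed.time.shape != predicted.time.shape or not np.allclose(
        observed.time, predicted.time, rtol=0, atol=1e-9
    ):
        raise ValidationError("observed and predicted recordings must share a time grid")
    resid = observed.signal - predicted.signal
    ss_res = float(resid @ resid)
    centred = observed.signal - observed.signal.mean()
    ss_tot = float(centred @ centred)
    if ss_tot == 0.0:
        raise MetricUndefinedError("R² undefined for a constant observed signal")
    return 1.0 - ss_res / ss_tot


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom
    and a two-sided p-value.  Requires >= 2 values per group and nonzero
    variance in at least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValidationError("Welch test undefined: both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
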