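"""Amplitude, slope and onset/offset features of peri-ripple mean traces.

Conventions: the baseline is the mean over (-200, 0) ms; the amplitude is
the maximum over (0, 200] ms minus the baseline; onset and offset are the
half-maximum crossings of the trace derivative flanking the derivative
maximum within (-200, 200) ms, with sub-sample linear interpolation.
Deactivation traces (voltage dips) are inverted before feature extraction
so every quantity is reported as a positive-going activation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TraceFeatureSet", "trace_features", "compare_onsets"]


@dataclass
class TraceFeatureSet:
    baseline: float
    amplitude: float
    onset: float
    offset: float
    slope: float
    pre_event_amplitude: float
    polarity: str

    def __post_init__(self):
        if self.onset > self.offset:
            raise ValueError("onset must not exceed offset")


def _interp_crossing(lags, d, i_from, i_to, level):
    """Linear-interpolated time where d crosses ``level`` between samples."""
    d0, d1 = d[i_from], d[i_to]
    if d1 == d0:
        return lags[i_to]
    frac = (level - d0) / (d1 - d0)
    return lags[i_from] + frac * (lags[i_to] - lags[i_from])


def trace_features(
    trace: np.ndarray,
    lags: np.ndarray,
    polarity: str = "activation",
    deriv_smooth: int = 3,
    search_window: tuple[float, float] = (-0.2, 0.2),
) -> TraceFeatureSet:
    """Extract amplitude, slope, onset/offset from a peri-event mean trace.

    Parameters
    ----------
    trace, lags : ndarray
        The mean peri-event trace and its lag grid (s); the grid must
        cover ``search_window``.
    polarity : {"activation", "deactivation"}
        Deactivation traces are multiplied by -1 before analysis.
    deriv_smooth : int
        Moving-average width (samples) applied to the first-difference
        derivative before the half-maximum search; stabilizes crossings
        on noisy means.

    Raises
    ------
    ValueError
        For flat traces, or when the derivative maximum sits at the edge
        of the search window so a flanking crossing is undefined.
    """
    trace = np.asarray(trace, float)
    lags = np.asarray(lags, float)
    if polarity not in ("activation", "deactivation"):
        raise ValueError("polarity must be 'activation' or 'deactivation'")
    if trace.std() == 0:
        raise ValueError("flat trace: features undefined")
    if lags[0] > search_window[0] or lags[-1] < search_window[1]:
        raise ValueError("lag grid does not cover the search window")

    y = -trace if polarity == "deactivation" else trace
    pre = (lags >= -0.2) & (lags < 0)
    post = (lags > 0) & (lags <= 0.2)
    baseline = float(y[pre].mean())
    amplitude = float(y[post].max() - baseline)

    d = np.gradient(y, lags)
    if deriv_smooth > 1:
        kernel = np.ones(deriv_smooth) / deriv_smooth
        d = np.convolve(d, kernel, mode="same")

    sel = np.flatnonzero((lags >= search_window[0]) & (lags <= search_window[1]))
    imax = sel[int(np.argmax(d[sel]))]
    if imax == sel[0] or imax == sel[-1]:
        raise ValueError("derivative maximum at the search-window edge")
    half = d[imax] / 2.0

    i = imax
    while i > 0 and d[i] >= half:
        i -= 1
    if d[i] >= half:
        raise ValueError("onset half-max crossing not found")
    onset = _interp_crossing(lags, d, i, i + 1, half)

    j = imax
    while j < lags.size - 1 and d[j] >= half:
        j += 1
    if d[j] >= half:
        raise ValueError("offset half-max crossing not found")
    offset = _interp_crossing(lags, d, j - 1, j, half)

    y_on = np.interp(onset, lags, y)
    y_off = np.interp(offset, lags, y)
    slope = float((y_off - y_on) / (offset - onset))
    between = (lags >= onset) & (lags <= offset)
    pre_event_amplitude = float(trace[between].mean()) if between.any() else float(
        np.interp((onset + offset) / 2, lags, trace)
    )
    return TraceFeatureSet(
        baseline=baseline,
        amplitude=amplitude,
        onset=float(onset),
        offset=float(offset),
        slope=slope,
        pre_event_amplitude=pre_event_amplitude,
        polarity=polarity,
    )


def compare_onsets(values_a, values_b, test: str = "ttest") -> dict:
    """Two-group comparison of onset times (or any scalar feature).

    ``test`` is ``"ttest"`` (two-sample, two-sided) or ``"ranksum"``
    (Wilcoxon rank-sum).  Returns group means, their difference and the
    p-value.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if test == "ttest":
        res = stats.ttest_ind(a, b)
    elif test == "ranksum":
        res = stats.ranksums(a, b)
    else:
        raise ValueError("test must be 'ttest' or 'ranksum'")
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "test": test,
    }
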