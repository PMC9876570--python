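"""Neuron-resolved calcium analysis.

Covers the neuron-level arm of the pipeline: neuropil subtraction,
non-negative AR(1) deconvolution, k-means clustering of peri-ripple mean
traces with correlation distance (plus silhouette / Calinski-Harabasz
model selection), and the circular-jitter shuffle test for per-neuron
ripple modulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumTraceSet",
    "ClusterAssignment",
    "ModulationTestResult",
    "neuropil_correct",
    "deconvolve",
    "cluster_peri_ripple",
    "select_cluster_number",
    "modulation_test",
]


@dataclass
class CalciumTraceSet:
    """N x T dF/F traces at ``rate`` Hz, with optional neuropil traces."""

    traces: np.ndarray
    rate: float = 19.6
    neuropil: np.ndarray | None = None

    def __post_init__(self):
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.neuropil is not None:
            self.neuropil = np.atleast_2d(np.asarray(self.neuropil, float))
            if self.neuropil.shape != self.traces.shape:
                raise ValueError("neuropil shape mismatch")


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k; 0 marks dropped zero-variance neurons)."""

    labels: np.ndarray
    k: int
    criterion_curves: dict


@dataclass
class ModulationTestResult:
    """Per-neuron shuffle-test outcome.

    ``statistic`` is the squared difference between the true peri-event
    average and the shuffle-mean over the test window; ``percentile`` its
    rank among shuffle statistics; ``direction`` is 'up'/'down' for
    significant neurons and '' otherwise.
    """

    statistic: np.ndarray
    percentile: np.ndarray
    significant: np.ndarray
    direction: np.ndarray


def neuropil_correct(
    traces: np.ndarray, neuropil: np.ndarray, coefficient: float = 0.7
) -> np.ndarray:
    """Subtract the scaled neuropil contamination: trace - 0.7 * neuropil."""
    traces = np.asarray(traces, float)
    neuropil = np.asarray(neuropil, float)
    if traces.shape != neuropil.shape:
        raise ValueError("trace/neuropil shape mismatch")
    return traces - coefficient * neuropil


def _oasis_ar1(y: np.ndarray, g: float) -> np.ndarray:
    """Non-negative AR(1) deconvolution (pool-adjacent-violators).

    Solves min ||c - y||^2 subject to s_t = c_t - g c_{t-1} >= 0 and
    returns s.  This is the lambda = 0 variant of the online active-set
    method for sparse calcium deconvolution.
    """
    # pools: [value, weight, start, length]
    pools: list[list] = []
    for t, yt in enumerate(y):
        pools.append([float(yt), 1.0, t, 1])
        while len(pools) > 1 and pools[-1][0] < g ** pools[-2][3] * pools[-2][0]:
            v2, w2, _, l2 = pools.pop()
            v1, w1, t1, l1 = pools[-1]
            decay = g**l1
            wnew = w1 + decay**2 * w2
            vnew = (w1 * v1 + decay * w2 * v2) / wnew
            pools[-1] = [vnew, wnew, t1, l1 + l2]
    c = np.zeros_like(y)
    for v, _, t, l in pools:
        v = max(v, 0.0)
        c[t : t + l] = v * g ** np.arange(l)
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - g * c[:-1]
    return np.clip(s, 0.0, None)


def deconvolve(
    traces: np.ndarray, rate: float, decay_s: float = 1.0
) -> np.ndarray:
    """Non-negative activity traces under an AR(1) indicator kernel.

    The AR coefficient is g = exp(-1 / (rate * decay_s)); the output has
    the input shape, is >= 0 everywhere, and re-convolving it with the
    AR(1) kernel reproduces the trace up to the noise floor.
    """
    if decay_s <= 0:
        raise ValueError("decay_s must be > 0")
    traces = np.atleast_2d(np.asarray(traces, float))
    if not np.all(np.isfinite(traces)):
        raise ValueError("non-finite input")
    g = float(np.exp(-1.0 / (rate * decay_s)))
    out = np.stack([_oasis_ar1(row, g) for row in traces])
    return out if np.asarray(traces).ndim > 1 else out[0]


def _prep_for_clustering(mean_traces: np.ndarray):
    """Z-score rows and scale to unit norm so that squared Euclidean
    distance is proportional to (1 - correlation)."""
    x = np.asarray(mean_traces, float)
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance traces", int((~keep).sum()))
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    return z, keep


def cluster_peri_ripple(
    mean_traces: np.ndarray,
    lags: np.ndarray,
    k: int = 2,
    seed: int | None = None,
    n_replicates: int = 10,
    max_iter: int = 1000,
) -> ClusterAssignment:
    """K-means clustering of peri-ripple mean traces, correlation distance.

    Each neuron's mean trace (typically over -500..+500 ms) is z-scored
    and unit-normalized, making Euclidean k-means equivalent to k-means
    under correlation distance.  Labels are renumbered so that cluster 1
    has the largest mean z-value over (0, 200] ms (the "activated"
    cluster).  Zero-variance traces are dropped (label 0).
    """
    x, keep = _prep_for_clustering(mean_traces)
    if x.shape[0] < k:
        raise ValueError("fewer valid traces than clusters")
    km = KMeans(n_clusters=k, n_init=n_replicates, max_iter=max_iter, random_state=seed)
    raw = km.fit_predict(x)
    lags = np.asarray(lags, float)
    # the slow indicator smears pre-ripple calcium into the early post
    # window, so the activated cluster is identified by its post-minus-pre
    # contrast rather than the post-window mean alone
    post, pre = lags > 0, lags < 0
    contrast = [
        x[raw == c][:, post].mean() - x[raw == c][:, pre].mean()
        if (raw == c).any()
        else -np.inf
        for c in range(k)
    ]
    order = np.argsort([-v for v in contrast])
    remap = {int(c): rank + 1 for rank, c in enumerate(order)}
    labels = np.zeros(np.asarray(mean_traces).shape[0], dtype=int)
    labels[keep] = [remap[int(c)] for c in raw]
    return ClusterAssignment(labels=labels, k=k, criterion_curves={})


def select_cluster_number(
    mean_traces: np.ndarray,
    lags: np.ndarray,
    k_range=range(2, 9),
    seed: int | None = None,
) -> tuple[int, dict]:
    """Pick the cluster count by silhouette and Calinski-Harabasz criteria.

    Both criteria are evaluated on the z-scored unit-norm traces for every
    k in ``k_range`` (silhouette under correlation distance).  If the two
    argmaxes disagree the silhouette winner is returned and the conflict
    logged.  Returns ``(k_star, criterion_curves)``.
    """
    x, _ = _prep_for_clustering(mean_traces)
    k_range = list(k_range)
    if x.shape[0] <= max(k_range):
        raise ValueError("need more traces than the largest candidate k")
    sil, ch = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, max_iter=1000, random_state=seed)
        labels = km.fit_predict(x)
        sil[k] = float(silhouette_score(x, labels, metric="correlation"))
        ch[k] = float(calinski_harabasz_score(x, labels))
    k_sil = max(sil, key=sil.get)
    k_ch = max(ch, key=ch.get)
    if k_sil != k_ch:
        logger.warning(
            "criterion disagreement: silhouette -> %d, Calinski-Harabasz -> %d; "
            "using silhouette",
            k_sil,
            k_ch,
        )
    return k_sil, {"silhouette": sil, "calinski_harabasz": ch}


def modulation_test(
    activity: np.ndarray,
    rate: float,
    centers: np.ndarray,
    n_shuffle: int = 1000,
    window: tuple[float, float] = (0.0, 0.2),
    baseline_window: tuple[float, float] = (-0.4, 0.0),
    jitter_max: float = 1.0,
    seed: int | None = None,
) -> ModulationTestResult:
    """Circular-jitter shuffle test for per-neuron ripple modulation.

    For each neuron the peri-event chunks (+-``jitter_max`` s around each
    ripple center) are averaged into the true average.  Each of
    ``n_shuffle`` surrogates circularly shifts every chunk independently
    by a uniform amount up to ``jitter_max`` and re-averages.  The
    statistic is the sum over the ``window`` lags of the squared
    difference between an average and the mean of the shuffled averages;
    a neuron is significant when its true statistic exceeds the 95th
    percentile of the shuffle statistics.  Direction compares the mean of
    the true average over ``window`` with its median over
    ``baseline_window``.
    """
    activity = np.atleast_2d(np.asarray(activity, float))
    centers = np.asarray(centers, float)
    if centers.size < 10:
        raise ValueError("need >= 10 events for the shuffle test")
    half = int(round(jitter_max * rate))
    n_l = 2 * half + 1
    lags = np.arange(-half, half + 1) / rate
    win = (lags > window[0]) & (lags <= window[1])
    base = (lags >= baseline_window[0]) & (lags < baseline_window[1])
    if not win.any():
        raise ValueError("test window outside the lag grid")

    idx = np.round(centers * rate).astype(int)
    ok = (idx - half >= 0) & (idx + half < activity.shape[1])
    idx = idx[ok]
    r = idx.size
    if r < 10:
        raise ValueError("fewer than 10 events fit inside the recording")
    offsets = np.arange(-half, half + 1)

    rng = np.random.default_rng(seed)
    n_neurons = activity.shape[0]
    stat = np.empty(n_neurons)
    pct = np.empty(n_neurons)
    sig = np.empty(n_neurons, dtype=bool)
    direction = np.empty(n_neurons, dtype=object)

    # one jitter realization set per neuron keeps shuffles independent
    for i in range(n_neurons):
        chunks = activity[i][idx[:, None] + offsets[None, :]]  # (R, L)
        true_avg = chunks.mean(axis=0)
        shifts = rng.integers(-half, half + 1, size=(n_shuffle, r))
        cols = (np.arange(n_l)[None, None, :] - shifts[:, :, None]) % n_l
        shuf_avgs = chunks[np.arange(r)[None, :, None], cols].mean(axis=1)  # (S, L)
        shuf_mean = shuf_avgs.mean(axis=0)
        stat[i] = np.sum((true_avg[win] - shuf_mean[win]) ** 2)
        shuf_stats = np.sum((shuf_avgs[:, win] - shuf_mean[win]) ** 2, axis=1)
        pct[i] = 100.0 * np.mean(stat[i] > shuf_stats)
        sig[i] = stat[i] > np.percentile(shuf_stats, 95.0)
        if sig[i]:
            up = true_avg[win].mean() > np.median(true_avg[base])
            direction[i] = "up" if up else "down"
        else:
            direction[i] = ""
    return ModulationTestResult(
        statistic=stat, percentile=pct, significant=sig, direction=direction
    )
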