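"""SVD decomposition of concatenated peri-ripple stacks.

Chunks of the imaging stack around individual ripples are concatenated
along time and the (time) x (pixels) unfolding is factorized by a thin
SVD.  The left singular vectors are temporal modes, the right ones
spatial modes.  No per-pixel mean is removed, so the dominant global
event-locked response is absorbed by component 1; components 2..K carry
the spatially specific remainder (in particular the aRSC-confined
negative modulation).  Each component's sign is fixed so that its spatial
mode has non-negative mean, resolving the SVD sign ambiguity
deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .peri_event import PeriEventEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "SVDDecomposition",
    "ComponentReconstruction",
    "decompose_concatenated",
    "component_peri_event_average",
    "reconstruct_subset",
    "deep_layer_estimate",
]


@dataclass
class SVDDecomposition:
    """Thin SVD of concatenated peri-ripple frames.

    ``temporal_modes`` (K, R*L) are the left singular vectors transposed;
    ``spatial_modes`` (K, H, W) the right ones; ``singular_values`` the
    retained K values (descending).  ``all_singular_values`` keeps the
    full spectrum so variance fractions refer to total energy.
    Components are 1-based in the public API.
    """

    spatial_modes: np.ndarray
    singular_values: np.ndarray
    temporal_modes: np.ndarray
    all_singular_values: np.ndarray
    n_events: int
    n_lags: int
    lags: np.ndarray

    @property
    def k(self) -> int:
        return self.singular_values.size

    def chunk_span(self, event: int) -> slice:
        """Time span of one event's chunk inside the concatenated axis."""
        if not 0 <= event < self.n_events:
            raise IndexError("unknown event")
        return slice(event * self.n_lags, (event + 1) * self.n_lags)


@dataclass
class ComponentReconstruction:
    component_set: tuple
    region_trace: np.ndarray  # (L,) peri-event mean of the region trace
    event_traces: np.ndarray  # (R, L) per-event region traces
    variance_explained: float
    lags: np.ndarray


def decompose_concatenated(chunks: PeriEventEnsemble, k: int = 100) -> SVDDecomposition:
    """Thin SVD of the concatenated peri-ripple stack.

    ``chunks.values`` must be (R, L, H, W); the unfolding is
    (R*L) x (H*W).  ``k`` components are retained (k <= min(R*L, pixels)).
    """
    v = np.asarray(chunks.values, np.float64)
    if v.ndim != 4:
        raise ValueError("chunks must be an R x L x H x W ensemble")
    r, l, h, w = v.shape
    x = v.reshape(r * l, h * w)
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k={k} exceeds the rank bound {min(x.shape)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    sign = np.where(vt[:k].mean(axis=1) < 0, -1.0, 1.0)
    temporal = (u[:, :k] * sign).T
    spatial = (vt[:k] * sign[:, None]).reshape(k, h, w)
    return SVDDecomposition(
        spatial_modes=spatial,
        singular_values=s[:k],
        temporal_modes=temporal,
        all_singular_values=s,
        n_events=r,
        n_lags=l,
        lags=np.asarray(chunks.lags),
    )


def component_peri_event_average(dec: SVDDecomposition, component: int):
    """Re-chunk one component's temporal mode and average across events.

    ``component`` is 1-based.  Returns ``(lags, mean, sem)``.
    """
    if not 1 <= component <= dec.k:
        raise ValueError(f"unknown component {component}")
    mode = dec.temporal_modes[component - 1].reshape(dec.n_events, dec.n_lags)
    mean = mode.mean(axis=0)
    sem = (
        mode.std(axis=0, ddof=1) / np.sqrt(dec.n_events)
        if dec.n_events > 1
        else np.zeros_like(mean)
    )
    return dec.lags, mean, sem


def reconstruct_subset(
    dec: SVDDecomposition,
    component_set,
    masks: dict,
    label: str,
) -> ComponentReconstruction:
    """Partial reconstruction from a subset of components, as a region trace.

    Reconstructs sum_{k in set} u_k s_k v_k^T, extracts the frame-wise
    mean over the ``label`` mask, and re-chunks it into per-event peri-
    ripple traces.  ``variance_explained`` is the subset's share of the
    total squared Frobenius energy.  Region traces are additive over
    disjoint component sets (linearity).
    """
    comps = tuple(sorted(set(int(c) for c in component_set)))
    if not comps:
        raise ValueError("component set is empty")
    if comps[0] < 1 or comps[-1] > dec.k:
        raise ValueError("component set outside 1..K")
    if label not in masks:
        raise KeyError(f"unknown region label {label!r}")
    mask = masks[label]
    h, w = dec.spatial_modes.shape[1:]
    if mask.shape != (h, w):
        raise ValueError("mask shape mismatch")

    idx = np.array(comps) - 1
    # region trace of the reconstruction: only mask pixels are needed
    spatial_region = dec.spatial_modes.reshape(dec.k, h * w)[:, mask.ravel()].mean(
        axis=1
    )  # (K,)
    concat_trace = (
        dec.temporal_modes[idx].T * dec.singular_values[idx]
    ) @ spatial_region[idx]
    event_traces = concat_trace.reshape(dec.n_events, dec.n_lags)
    var = float(
        np.sum(dec.singular_values[idx] ** 2) / np.sum(dec.all_singular_values**2)
    )
    return ComponentReconstruction(
        component_set=comps,
        region_trace=event_traces.mean(axis=0),
        event_traces=event_traces,
        variance_explained=var,
        lags=dec.lags,
    )


def reconstruct_frames(dec: SVDDecomposition, component_set) -> np.ndarray:
    """Full (R, L, H, W) reconstruction from a component subset."""
    comps = tuple(sorted(set(int(c) for c in component_set)))
    if not comps or comps[0] < 1 or comps[-1] > dec.k:
        raise ValueError("invalid component set")
    idx = np.array(comps) - 1
    h, w = dec.spatial_modes.shape[1:]
    x = (dec.temporal_modes[idx].T * dec.singular_values[idx]) @ dec.spatial_modes[
        idx
    ].reshape(idx.size, h * w)
    return x.reshape(dec.n_events, dec.n_lags, h, w)


def deep_layer_estimate(
    emx_trace: np.ndarray, ras_trace: np.ndarray, alpha: float = 0.5
) -> np.ndarray:
    """Deep-layer glutamate estimate: EMX - alpha * Ras.

    The pan-layer (EMX) signal mixes superficial and deep contributions;
    subtracting a scaled superficial-only (Ras) signal isolates an
    estimate of the deep-layer component.  Both traces must share a lag
    grid (same length).
    """
    emx = np.asarray(emx_trace, float)
    ras = np.asarray(ras_trace, float)
    if emx.shape != ras.shape:
        raise ValueError("lag grid mismatch between EMX and Ras traces")
    return emx - alpha * ras
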