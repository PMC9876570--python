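"""Wide-field imaging preprocessing: denoising, dF/F, filtering, regions.

Stacks are T x H x W arrays with a sampling rate and a modality tag.
Baselines use a piecewise-linear local-regression detrend (sliding linear
fits blended with triangular weights), the convention of the classic
``locdetrend`` routine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ImagingStack",
    "validate_masks",
    "lowrank_denoise",
    "local_linear_trend",
    "compute_dff",
    "bandpass_stack",
    "ratiometric_voltage",
    "extract_region_trace",
]

MODALITIES = ("glutamate", "voltage_acceptor", "voltage_donor", "voltage_ratio", "calcium")


@dataclass
class ImagingStack:
    """A fluorescence movie: frames (T, H, W), rate (Hz), modality tag."""

    frames: np.ndarray
    rate: float
    modality: str = "glutamate"
    time0: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self):
        return self.frames.shape

    def with_frames(self, frames: np.ndarray) -> "ImagingStack":
        return ImagingStack(frames, self.rate, self.modality, self.time0)


def validate_masks(masks: dict, shape: tuple[int, int]) -> None:
    if not masks:
        raise ValueError("mask set is empty")
    for label, m in masks.items():
        if m.shape != shape:
            raise ValueError(f"mask {label!r} shape {m.shape} != stack {shape}")
        if not m.any():
            raise ValueError(f"mask {label!r} is empty")


def lowrank_denoise(stack: ImagingStack, n_components: int = 100) -> ImagingStack:
    """Keep the top-``n_components`` SVD components of the T x (H*W) unfolding."""
    t, h, w = stack.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(t, h * w):
        raise ValueError("n_components exceeds min(T, pixels)")
    x = stack.frames.reshape(t, h * w).astype(np.float64)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components]
    return stack.with_frames(recon.reshape(t, h, w))


def local_linear_trend(
    x: np.ndarray, rate: float, window_s: float = 30.0, overlap: float = 0.5
) -> np.ndarray:
    """Piecewise-linear local-regression trend along axis 0.

    Fits a first-degree polynomial in sliding windows (50% overlap by
    default) and blends them with triangular weights.  ``x`` may be (T,)
    or (T, P); the trend has the same shape.
    """
    x2 = np.atleast_2d(np.asarray(x, float).T).T  # (T, P)
    n = x2.shape[0]
    w = min(n, max(4, int(round(window_s * rate))))
    step = max(1, int(round(w * (1.0 - overlap))))
    trend = np.zeros_like(x2)
    weight = np.zeros(n)
    tri = np.bartlett(w + 2)[1:-1]  # strictly positive triangular weights
    tloc = np.arange(w, dtype=float)
    design = np.column_stack([np.ones(w), tloc])
    starts = list(range(0, max(1, n - w + 1), step))
    if starts[-1] != n - w:
        starts.append(n - w)
    for i0 in starts:
        seg = x2[i0 : i0 + w]
        coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
        fit = design @ coef
        trend[i0 : i0 + w] += tri[:, None] * fit
        weight[i0 : i0 + w] += tri
    trend /= weight[:, None]
    return trend.reshape(np.asarray(x).shape)


def compute_dff(stack: ImagingStack, baseline_window_s: float = 30.0) -> ImagingStack:
    """Per-pixel dF/F0 with a time-varying local-regression baseline.

    Raises if the fitted baseline F0 is not strictly positive anywhere
    (a sign of badly scaled input).
    """
    t, h, w = stack.shape
    x = stack.frames.reshape(t, h * w).astype(np.float64)
    f0 = local_linear_trend(x, stack.rate, window_s=baseline_window_s)
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; input is not raw positive fluorescence")
    dff = (x - f0) / f0
    return stack.with_frames(dff.reshape(t, h, w))


def bandpass_stack(
    stack: ImagingStack, band: tuple[float, float] = (0.5, 6.0)
) -> ImagingStack:
    """Zero-phase FIR band-pass applied per pixel along time."""
    if band[1] >= stack.rate / 2:
        raise ValueError("band above Nyquist")
    t = stack.shape[0]
    numtaps = int(round(3.0 * stack.rate / band[0]))
    numtaps = min(numtaps | 1, (t // 4) | 1)
    if numtaps < 5:
        raise ValueError("stack too short for the requested band")
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=stack.rate)
    flat = stack.frames.reshape(t, -1).astype(np.float64)
    out = sps.filtfilt(taps, [1.0], flat, axis=0)
    return stack.with_frames(out.reshape(stack.shape))


def ratiometric_voltage(
    acceptor: ImagingStack, donor: ImagingStack, window_s: float = 30.0
) -> ImagingStack:
    """Trend-equalized FRET ratio for dual-emission voltage imaging.

    Each channel is divided by its own slow local-regression trend; the
    output is equalized-acceptor / equalized-donor - 1.  Common-mode
    (same-sign, equal-fraction) fluctuations such as hemodynamic artifacts
    cancel to first order, while anti-phase FRET fluctuations add.
    """
    if acceptor.shape != donor.shape or acceptor.rate != donor.rate:
        raise ValueError("acceptor/donor shape or rate mismatch")
    t = acceptor.shape[0]
    out = np.empty((t, acceptor.shape[1] * acceptor.shape[2]))
    a = acceptor.frames.reshape(t, -1).astype(np.float64)
    d = donor.frames.reshape(t, -1).astype(np.float64)
    ta = local_linear_trend(a, acceptor.rate, window_s=window_s)
    td = local_linear_trend(d, donor.rate, window_s=window_s)
    if np.any(ta <= 0) or np.any(td <= 0):
        raise ValueError("non-positive channel trend")
    out = (a / ta) / (d / td) - 1.0
    return ImagingStack(
        out.reshape(acceptor.shape), acceptor.rate, "voltage_ratio", acceptor.time0
    )


def extract_region_trace(
    stack: ImagingStack | np.ndarray, masks: dict, label: str
) -> np.ndarray:
    """Frame-wise mean over the pixels of one region mask."""
    frames = stack.frames if isinstance(stack, ImagingStack) else np.asarray(stack)
    if label not in masks:
        raise KeyError(f"unknown region label {label!r}")
    validate_masks({label: masks[label]}, frames.shape[-2:])
    return frames[..., masks[label]].mean(axis=-1)
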