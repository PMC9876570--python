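"""Synthetic recording sessions with known ground truth.

Every downstream stage of the pipeline (ripple detection, peri-event
statistics, SVD multiplexing, modulation testing) is validated against
sessions produced here, so the generator encodes the statistical structure
of the modelled recordings explicitly:

* CA1 LFP: 1/f background with embedded ripple-band (110-250 Hz) Gabor
  bursts riding on a 50 ms half-cosine sharp-wave trough, plus a >300 Hz
  "spiking" component whose variance rises during ripples (drives MUA).
* Neck EMG: baseline noise with rectangular high-variance movement bouts
  that follow a fraction of ripples.
* Wide-field stacks: sums of spatial-mode x temporal-mode components --
  one global, positively ripple-modulated; one confined to the aRSC mask,
  negatively modulated -- plus common-mode slow drift and pixel noise.
  The negative component's per-event amplitude shares a latent factor with
  the per-event MUA burst gain, creating genuine ripple-to-ripple "noise"
  covariability between the two.
* Calcium populations: inhomogeneous-Poisson spike trains with up-, down-
  or un-modulated peri-ripple rate kernels, convolved with a 1 s
  single-exponential indicator kernel.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import SynthConfig

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "generate_ripple_times",
    "generate_lfp",
    "generate_emg",
    "default_masks",
    "generate_widefield_stack",
    "generate_calcium_population",
    "generate_session",
]

#: minimum spacing between consecutive ripple centers (s); keeps the
#: peri-event windows of neighbouring events from overlapping heavily
RIPPLE_REFRACTORY_S = 0.5

#: margin kept free of events at both recording edges (s) so that
#: +-1 s alignment windows and detector edge trimming always fit
EDGE_MARGIN_S = 1.5

#: sharp-wave trough width (s): half-cosine so the "largest trough"
#: centering used by the detector is well defined
SHARPWAVE_WIDTH_S = 0.05

#: calcium indicator decay time constant (s), GCaMP6s-like
INDICATOR_DECAY_S = 1.0


@dataclass
class GroundTruth:
    """Implanted structure of one synthetic session.

    ``ripple_times`` are the event centers (s, strictly increasing).
    ``event_latents`` is the per-event standard-normal factor shared
    between the MUA burst gain and the negative wide-field component
    amplitude.  Spatial modes have unit L2 norm; ``neuron_labels``
    partition the population into ``up`` / ``down`` / ``none``.
    """

    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_latents: np.ndarray = field(default_factory=lambda: np.empty(0))
    mua_gains: np.ndarray = field(default_factory=lambda: np.empty(0))
    mua_suppressions: np.ndarray = field(default_factory=lambda: np.empty(0))
    emg_bout_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    emg_followed: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    component_spatial_modes: list = field(default_factory=list)
    component_temporal_kernels: list = field(default_factory=list)
    component_event_amplitudes: np.ndarray | None = None
    component_lags: np.ndarray | None = None
    neuron_labels: np.ndarray | None = None
    neuron_rate_kernels: np.ndarray | None = None
    neuron_kernel_lags: np.ndarray | None = None
    spike_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.ripple_times, float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("ripple_times must be strictly increasing")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    """Independent, reproducible RNG stream per generation stage."""
    return np.random.default_rng(np.random.SeedSequence([stream, cfg.rng_seed]))


def generate_ripple_times(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw ripple centers and durations.

    Centers follow a renewal process (exponential gaps plus a refractory
    period) with mean rate ``cfg.ripple_rate_per_min``; durations are
    uniform on 30-100 ms.
    """
    rate_hz = cfg.ripple_rate_per_min / 60.0
    usable = cfg.duration_s - 2 * EDGE_MARGIN_S
    if rate_hz == 0:
        return np.empty(0), np.empty(0)
    if usable <= 1.0 / rate_hz:
        raise ValueError(
            f"duration_s={cfg.duration_s} too short to host ripples at "
            f"{cfg.ripple_rate_per_min}/min with {EDGE_MARGIN_S} s edge margins"
        )
    mean_gap = 1.0 / rate_hz
    if mean_gap <= RIPPLE_REFRACTORY_S:
        raise ValueError("ripple_rate_per_min too high for the refractory period")
    rng = _rng(cfg, 1)
    times = []
    t = EDGE_MARGIN_S + rng.exponential(mean_gap - RIPPLE_REFRACTORY_S)
    limit = cfg.duration_s - EDGE_MARGIN_S
    while t < limit:
        times.append(t)
        t += RIPPLE_REFRACTORY_S + rng.exponential(mean_gap - RIPPLE_REFRACTORY_S)
    times = np.asarray(times)
    durations = rng.uniform(0.030, 0.100, size=times.size)
    return times, durations


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f (power ~ 1/f) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _band_envelope(x: np.ndarray, rate: float, band=(110.0, 250.0)) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return np.abs(sps.hilbert(sps.sosfiltfilt(sos, x)))


def _gabor_band_gain(duration: float, fc: float, rate: float) -> float:
    """Peak band-envelope of a unit-amplitude Gabor of the given duration.

    Brief bursts spread spectrally and are attenuated by the ripple-band
    filter; dividing by this gain keeps the envelope z-score at the event
    center equal to the requested SNR for every duration.
    """
    sigma = duration / 6.0
    t = np.arange(-0.5, 0.5, 1.0 / rate)
    gabor = np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * fc * t)
    return float(_band_envelope(gabor, rate).max())


def generate_lfp(cfg: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize the CA1 LFP and the session ground truth.

    Returns
    -------
    samples : ndarray
        LFP at ``cfg.lfp_rate`` (arbitrary microvolt-like units).
    truth : GroundTruth
        Ripple times/durations, per-event latents and MUA gains.

    Notes
    -----
    Each ripple is a Gaussian-windowed sinusoid (Gabor atom) at
    ``cfg.ripple_band_center`` whose envelope peak is calibrated so that
    the ripple-band Hilbert-envelope z-score of the event center equals
    ``cfg.ripple_snr`` relative to the background statistics.  The Gabor
    phase puts the deepest trough of the band-filtered trace at the event
    center.  A >300 Hz noise component with ripple-locked variance bursts
    provides the substrate for MUA extraction.
    """
    n = int(round(cfg.duration_s * cfg.lfp_rate))
    rng = _rng(cfg, 2)
    background = _pink_noise(n, rng) * cfg.noise_sd["lfp"]

    times, durations = generate_ripple_times(cfg)
    truth = GroundTruth(ripple_times=times, ripple_durations=durations)

    t = np.arange(n) / cfg.lfp_rate
    lfp = background.copy()

    # spiking (>300 Hz) component: variance rises during ripples; steep
    # roll-off keeps it out of the 110-250 Hz detection band
    hp_sos = sps.butter(8, 350.0, btype="highpass", fs=cfg.lfp_rate, output="sos")
    spiking = sps.sosfilt(hp_sos, rng.standard_normal(n))
    spiking /= spiking.std()
    mua_envelope = np.ones(n)

    if times.size:
        env = _band_envelope(background, cfg.lfp_rate)
        target = env.mean() + cfg.ripple_snr * env.std()
        sos_band = sps.butter(
            4, (110.0, 250.0), btype="bandpass", fs=cfg.lfp_rate, output="sos"
        )
        bg_band = sps.sosfiltfilt(sos_band, background)
        latents = rng.standard_normal(times.size)
        # burst gain varies independently of the common-source latent
        mua_gains = np.clip(2.0 * (1.0 + 0.4 * rng.standard_normal(times.size)), 0.3, None)
        truth.event_latents = latents
        truth.mua_gains = mua_gains
        # common-source coupling: the same per-event latent deepens both
        # the post-ripple MUA suppression and the aRSC imaging dip,
        # implanting positive ripple-to-ripple noise correlation
        mua_suppressions = np.clip(0.5 + 0.25 * latents, 0.0, 0.95)
        truth.mua_suppressions = mua_suppressions
        sw_amp = 3.0 * cfg.noise_sd["lfp"]
        for c, d, g, sup in zip(times, durations, mua_gains, mua_suppressions):
            sigma = d / 6.0
            amp = target / _gabor_band_gain(d, cfg.ripple_band_center, cfg.lfp_rate)
            sel = slice(
                max(0, int((c - d) * cfg.lfp_rate)),
                min(n, int((c + d) * cfg.lfp_rate) + 1),
            )
            tau = t[sel] - c
            gabor = np.exp(-(tau**2) / (2 * sigma**2))
            # the ripple replaces (rather than rides on) the local band
            # noise, so the realized band z at the center hits the target
            gate = np.exp(-(tau**2) / (2 * (1.5 * sigma) ** 2))
            lfp[sel] -= gate * bg_band[sel]
            lfp[sel] += -amp * gabor * np.cos(2 * np.pi * cfg.ripple_band_center * tau)
            # sharp-wave: half-cosine trough, width 50 ms
            sw = np.where(
                np.abs(tau) < SHARPWAVE_WIDTH_S / 2,
                -sw_amp * np.cos(np.pi * tau / SHARPWAVE_WIDTH_S),
                0.0,
            )
            lfp[sel] += sw
            mua_envelope[sel] += g * np.exp(-(tau**2) / (2 * (d / 4.0) ** 2))
            wide = slice(
                max(0, int((c - 0.1) * cfg.lfp_rate)),
                min(n, int((c + 0.5) * cfg.lfp_rate) + 1),
            )
            tau_w = t[wide] - c
            mua_envelope[wide] -= sup * np.exp(-((tau_w - 0.075) ** 2) / (2 * 0.045**2))
        np.clip(mua_envelope, 0.05, None, out=mua_envelope)

    lfp += 0.3 * cfg.noise_sd["lfp"] * spiking * mua_envelope
    return lfp, truth


def generate_emg(cfg: SynthConfig, truth: GroundTruth) -> np.ndarray:
    """Neck-EMG signal: baseline noise plus post-ripple movement bouts.

    With probability ``cfg.emg_follow_prob`` each ripple is followed
    (50-300 ms later) by a 300 ms rectangular bout during which the noise
    SD is multiplied by 6.  Bout onsets are recorded in
    ``truth.emg_bout_times``; ``truth.emg_followed`` flags which ripples
    got one.  The modelled animal rests on a stationary platform, so no
    spontaneous bouts are added.
    """
    n = int(round(cfg.duration_s * cfg.lfp_rate))
    rng = _rng(cfg, 3)
    emg = rng.standard_normal(n) * cfg.noise_sd["emg"]
    bouts = []
    followed = np.zeros(truth.ripple_times.size, dtype=bool)
    for i, c in enumerate(truth.ripple_times):
        if rng.uniform() < cfg.emg_follow_prob:
            start = c + rng.uniform(0.05, 0.30)
            i0 = int(start * cfg.lfp_rate)
            i1 = min(n, i0 + int(0.3 * cfg.lfp_rate))
            if i0 < n:
                emg[i0:i1] *= 6.0
                bouts.append(start)
                followed[i] = True
    truth.emg_bout_times = np.asarray(bouts)
    truth.emg_followed = followed
    return emg


def default_masks(shape: tuple[int, int] = (32, 32)) -> dict[str, np.ndarray]:
    """Schematic cortical region masks on a coarse imaging grid.

    Rectangular, mutually disjoint stand-ins for the regions of interest:
    aRSC posterior-medial, with sensory regions (V1, FLS1, BC, Aud, V2M)
    around it.  Not anatomically accurate; sized relative to ``shape``.
    """
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("mask grid must be at least 16x16")

    def box(r0, r1, c0, c1):
        m = np.zeros(shape, dtype=bool)
        m[int(r0 * h) : int(r1 * h), int(c0 * w) : int(c1 * w)] = True
        return m

    return {
        "aRSC": box(0.62, 0.94, 0.38, 0.62),
        "V1": box(0.62, 0.94, 0.06, 0.28),
        "FLS1": box(0.12, 0.38, 0.12, 0.38),
        "BC": box(0.12, 0.38, 0.62, 0.88),
        "Aud": box(0.44, 0.56, 0.72, 0.94),
        "V2M": box(0.44, 0.56, 0.06, 0.28),
    }


def _unit(mode: np.ndarray) -> np.ndarray:
    return mode / np.linalg.norm(mode)


def _peri_kernels(modality: str, lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Temporal kernels (mode units) of the two implanted components.

    Component 1 (global, positive): post-ripple alpha-function bump.  For
    voltage the positive global modulation peaks slightly before the
    ripple (pre-ripple depolarization).  Component 2 (aRSC-confined,
    negative): post-ripple Gaussian dip; the voltage flavour adds a
    pre-ripple rise so the net aRSC kernel is rise-then-dip.
    """
    if modality == "voltage":
        k1 = 1.5 * np.exp(-((lags + 0.10) ** 2) / (2 * 0.08**2))
        k2 = 0.8 * np.exp(-((lags + 0.15) ** 2) / (2 * 0.07**2)) - 1.2 * np.exp(
            -((lags - 0.10) ** 2) / (2 * 0.05**2)
        )
    else:  # glutamate-like
        tau = 0.15
        k1 = np.where(lags > 0, (lags / tau) * np.exp(1 - lags / tau), 0.0) * 1.5
        k2 = -1.2 * np.exp(-((lags - 0.08) ** 2) / (2 * 0.04**2))
    return k1, k2


def generate_widefield_stack(
    cfg: SynthConfig,
    masks: dict[str, np.ndarray],
    truth: GroundTruth,
    modality: str = "glutamate",
    n_components: int = 2,
    drift_amplitude: float = 0.004,
) -> np.ndarray:
    """Build a T x H x W wide-field stack from implanted components.

    stack = sum_k a_k(x) b_k(t) + common-mode drift + i.i.d. pixel noise.

    Component 1 is spatially global (smooth, all-positive unit-norm map)
    with a positive post-ripple kernel; component 2 is confined to the
    ``aRSC`` mask with a negative post-ripple kernel.  Per-event amplitudes
    of component 2 are coupled to ``truth.event_latents`` (the same factor
    scaling the MUA bursts), implanting MUA <-> aRSC noise correlation.
    Spatial modes / kernels / amplitudes are recorded in ``truth``.
    """
    if "aRSC" not in masks:
        raise ValueError("masks must include an 'aRSC' label")
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise ValueError("all masks must share one shape")
    h, w = shapes.pop()
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    n_frames = int(round(cfg.duration_s * cfg.stack_rate))
    rng = _rng(cfg, 4 if modality != "voltage" else 5)

    from scipy.ndimage import gaussian_filter

    yy, xx = np.mgrid[0:h, 0:w]
    global_mode = 0.5 + np.exp(
        -(((yy - h / 2) ** 2 + (xx - w / 2) ** 2)) / (2 * (0.6 * h) ** 2)
    )
    # mild fixed topography so the global map is not featureless
    global_mode *= 1.0 + 0.35 * np.sin(2 * np.pi * yy / h) * np.cos(np.pi * xx / w)
    arsc_mode = gaussian_filter(masks["aRSC"].astype(float), 1.0) * masks["aRSC"]
    arsc_mode = _unit(arsc_mode)
    # near-orthogonal implants are recoverable by the SVD stage; a small
    # retained overlap (0.08) keeps the global mode positive inside aRSC
    global_mode = _unit(global_mode)
    overlap = global_mode.ravel() @ arsc_mode.ravel()
    global_mode = _unit(global_mode - (overlap - 0.08) * arsc_mode)

    half = int(round(1.0 * cfg.stack_rate))
    lags = np.arange(-half, half + 1) / cfg.stack_rate
    k1, k2 = _peri_kernels(modality, lags)
    k2 = k2 - (k2 @ k1) / (k1 @ k1) * k1  # temporal orthogonality

    n_events = truth.ripple_times.size
    amps = np.ones((n_events, 2))
    if n_events:
        amps[:, 0] = 1.0 + 0.1 * _rng(cfg, 6).standard_normal(n_events)
        if truth.event_latents.size:
            amps[:, 1] = np.clip(1.0 + 0.5 * truth.event_latents, 0.2, None)

    stack = np.zeros((n_frames, h, w), dtype=np.float64)
    modes = [global_mode, arsc_mode][:n_components]
    kernels = [k1, k2][:n_components]
    for r, c in enumerate(truth.ripple_times):
        i0 = int(round(c * cfg.stack_rate)) - half
        lo, hi = max(i0, 0), min(i0 + lags.size, n_frames)
        if hi <= lo:
            continue
        ksel = slice(lo - i0, lo - i0 + (hi - lo))
        for k, (mode, kern) in enumerate(zip(modes, kernels)):
            stack[lo:hi] += amps[r, k] * kern[ksel, None, None] * mode[None, :, :]

    if drift_amplitude:
        tt = np.arange(n_frames) / cfg.stack_rate
        drift = drift_amplitude * (
            np.sin(2 * np.pi * 0.03 * tt) + 0.5 * np.sin(2 * np.pi * 0.011 * tt + 1.0)
        )
        stack += drift[:, None, None]

    if cfg.noise_sd["widefield"]:
        stack += cfg.noise_sd["widefield"] * rng.standard_normal(stack.shape)

    truth.component_spatial_modes = modes
    truth.component_temporal_kernels = kernels
    truth.component_event_amplitudes = amps[:, :n_components]
    truth.component_lags = lags
    return stack


def _rate_profile(label: str, lags: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative peri-ripple rate profile, lightly smoothed."""
    prof = np.ones_like(lags)
    post = (lags > 0) & (lags <= 0.2)
    pre = (lags >= -0.5) & (lags <= 0)
    if label == "up":
        prof[post] = gain
        prof[pre] = 0.5
    elif label == "down":
        prof[post] = 1.0 / gain
        prof[pre] = 1.5
    return np.clip(prof, 0.05, None)


def generate_calcium_population(
    cfg: SynthConfig,
    truth: GroundTruth,
    n_neurons: int = 200,
    fractions: tuple[float, float, float] = (0.4, 0.4, 0.2),
    baseline_rate_hz: float = 0.5,
    rate_gain: float = 3.0,
) -> np.ndarray:
    """Simulate a population of peri-ripple-modulated calcium traces.

    Each neuron fires an inhomogeneous-Poisson spike train whose rate is
    ``baseline_rate_hz`` times a label-specific peri-ripple profile:
    ``up`` neurons gain x``rate_gain`` in (0, 200] ms with mild pre-ripple
    suppression, ``down`` neurons mirror that, ``none`` neurons are flat.
    Spike counts (stored in ``truth.spike_counts``) are convolved with a
    1 s single-exponential indicator kernel and Gaussian noise is added.

    Returns the N x T dF/F-like trace array at ``cfg.calcium_rate``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if baseline_rate_hz < 0 or rate_gain <= 0:
        raise ValueError("rates and gains must be positive")
    rng = _rng(cfg, 7)
    n_t = int(round(cfg.duration_s * cfg.calcium_rate))
    dt = 1.0 / cfg.calcium_rate

    n_up = int(round(fractions[0] * n_neurons))
    n_down = int(round(fractions[1] * n_neurons))
    labels = np.array(
        ["up"] * n_up + ["down"] * n_down + ["none"] * (n_neurons - n_up - n_down)
    )

    half = int(round(1.0 * cfg.calcium_rate))
    lags = np.arange(-half, half + 1) * dt
    profiles = {
        lab: _rate_profile(lab, lags, rate_gain) for lab in ("up", "down", "none")
    }

    # session-long rate modulation per label (shared shape, per-neuron draws)
    centers_idx = np.round(truth.ripple_times * cfg.calcium_rate).astype(int)
    modulation = {}
    for lab, prof in profiles.items():
        m = np.zeros(n_t)
        for ci in centers_idx:
            i0 = ci - half
            lo, hi = max(i0, 0), min(i0 + lags.size, n_t)
            if hi > lo:
                m[lo:hi] += prof[lo - i0 : lo - i0 + (hi - lo)] - 1.0
        modulation[lab] = np.clip(1.0 + m, 0.0, None)

    kernel_len = int(round(5 * INDICATOR_DECAY_S * cfg.calcium_rate))
    kernel = np.exp(-np.arange(kernel_len) * dt / INDICATOR_DECAY_S)

    traces = np.empty((n_neurons, n_t))
    counts = np.empty((n_neurons, n_t), dtype=np.int64)
    for i, lab in enumerate(labels):
        lam = baseline_rate_hz * modulation[lab] * dt
        c = rng.poisson(lam)
        counts[i] = c
        f = np.convolve(c.astype(float), kernel)[:n_t]
        traces[i] = f + cfg.noise_sd["calcium"] * rng.standard_normal(n_t)

    truth.neuron_labels = labels
    truth.neuron_rate_kernels = np.array(
        [baseline_rate_hz * profiles[lab] for lab in labels]
    )
    truth.neuron_kernel_lags = lags
    truth.spike_counts = counts
    return traces


def generate_session(
    cfg: SynthConfig,
    modality: str = "glutamate",
    n_neurons: int = 200,
    fractions: tuple[float, float, float] = (0.4, 0.4, 0.2),
    mask_shape: tuple[int, int] = (32, 32),
):
    """Generate a complete session: LFP, EMG, wide-field stack, calcium.

    Returns a dict with keys ``lfp``, ``emg``, ``stack``, ``masks``,
    ``calcium``, ``truth``, ``config``.
    """
    lfp, truth = generate_lfp(cfg)
    emg = generate_emg(cfg, truth)
    masks = default_masks(mask_shape)
    stack = generate_widefield_stack(cfg, masks, truth, modality=modality)
    calcium = generate_calcium_population(
        cfg, truth, n_neurons=n_neurons, fractions=fractions
    )
    logger.info(
        "synthetic session: %d ripples, %d EMG bouts, %d neurons",
        truth.ripple_times.size,
        truth.emg_bout_times.size,
        n_neurons,
    )
    return {
        "lfp": lfp,
        "emg": emg,
        "stack": stack,
        "masks": masks,
        "calcium": calcium,
        "truth": truth,
        "config": cfg,
    }
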