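"""Configuration dataclasses shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass
class SynthConfig:
    """Parameters of a synthetic recording session.

    The defaults describe a quiet head-fixed mouse resting on a platform:
    a ~2-minute epoch of CA1 LFP sampled at 1 kHz with awake sharp-wave
    ripples at ~10 events/min, wide-field imaging at 100 Hz, and two-photon
    calcium traces at 19.6 Hz.

    Attributes
    ----------
    duration_s : float
        Session length in seconds.
    lfp_rate, stack_rate, calcium_rate : float
        Sampling rates (Hz) of the electrophysiology, wide-field stack and
        calcium traces respectively.
    ripple_rate_per_min : float
        Mean ripple rate (events per minute).
    ripple_band_center : float
        Carrier frequency of the ripple oscillation, within 110-250 Hz.
    ripple_snr : float
        Target z-score of ripple-band power at each event center, measured
        against the power distribution of the background LFP.
    emg_follow_prob : float
        Probability that a movement (EMG) bout follows a ripple; default is
        the mean ripple-exclusion fraction observed in awake mice.
    noise_sd : dict
        Additive-noise scales per modality: ``lfp`` (background LFP SD, in
        the arbitrary microvolt-like unit of the signal), ``emg`` (baseline
        EMG SD), ``widefield`` (per-pixel dF/F SD per frame; the coarse
        32x32 grid corresponds to heavy spatial binning, hence the small
        value), ``calcium`` (dF/F SD per sample).
    rng_seed : int
        Master seed; identical configs produce bit-identical sessions.
    """

    duration_s: float = 120.0
    lfp_rate: float = 1000.0
    stack_rate: float = 100.0
    calcium_rate: float = 19.6
    ripple_rate_per_min: float = 10.0
    ripple_band_center: float = 160.0
    ripple_snr: float = 8.0
    emg_follow_prob: float = 0.2847
    noise_sd: dict = field(
        default_factory=lambda: {
            "lfp": 1.0,
            "emg": 1.0,
            "widefield": 0.005,
            "calcium": 0.1,
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "lfp_rate", "stack_rate", "calcium_rate"):
            _positive(name, getattr(self, name))
        if self.ripple_rate_per_min < 0:
            raise ValueError("ripple_rate_per_min must be >= 0")
        if not 110.0 <= self.ripple_band_center <= 250.0:
            raise ValueError("ripple_band_center must lie in [110, 250] Hz")
        if not 0.0 <= self.emg_follow_prob <= 1.0:
            raise ValueError("emg_follow_prob must be a probability")
        if self.ripple_snr < 0:
            raise ValueError("ripple_snr must be >= 0")
        for key, value in self.noise_sd.items():
            if value < 0:
                raise ValueError(f"noise_sd[{key!r}] must be >= 0")


@dataclass
class DetectionParams:
    """Ripple-detector settings.

    ``detect_k`` and ``duration_threshold`` are per-recording knobs (they
    were hand-tuned per animal in the experiments this pipeline models);
    the remaining values are fixed by the detection procedure itself:
    110-250 Hz band, 8 ms power smoothing, boundary threshold at 75% of the
    detection threshold, and concatenation of events whose centers are less
    than 50 ms apart.
    """

    band: tuple = (110.0, 250.0)
    smooth_window: float = 0.008
    detect_k: float = 4.0
    boundary_frac: float = 0.75
    duration_threshold: float = 0.013
    merge_gap: float = 0.050
    emg_exclusion_halfwidth: float = 0.5
    edge_margin: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.boundary_frac < 1.0:
            raise ValueError("boundary_frac must be in (0, 1)")
        if self.merge_gap <= 0:
            raise ValueError("merge_gap must be > 0")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")
        if self.duration_threshold < 0:
            raise ValueError("duration_threshold must be >= 0")
        if self.emg_exclusion_halfwidth < 0:
            raise ValueError("emg_exclusion_halfwidth must be >= 0")
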