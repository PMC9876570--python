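"""Self-contained evaluation runs for every pipeline stage.

Each function simulates its inputs with the synthetic generator (or a
direct construction), executes the stage under test, and measures the
outcome against the generator's ground truth or a closed form.  The
functions are consumed by the acceptance script and the acceptance test
suite; all randomness is derived from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .calcium import deconvolve, modulation_test, select_cluster_number
from .config import SynthConfig
from .ephys import detect_ripples, exclude_by_emg, match_events
from .features import trace_features
from .peri_event import (
    PeriEventEnsemble,
    align_events,
    asymmetry_index,
    build_null,
    ensemble_correlation,
    zscore_against_null,
)
from .pipeline import RunConfig, run_session
from .svd_multiplex import (
    decompose_concatenated,
    deep_layer_estimate,
    reconstruct_frames,
    reconstruct_subset,
)
from .synthetic import generate_calcium_population, generate_emg, generate_lfp

__all__ = [
    "cluster_number_recovery",
    "detector_fidelity",
    "null_calibration",
    "svd_recovery",
    "ensemble_correlation_check",
    "modulation_calibration",
    "feature_recovery",
    "multiplex_structure",
]


def _seeds(seed: int, stage: int, n: int = 1):
    vals = np.random.SeedSequence([stage, seed]).generate_state(n) % (2**31)
    return [int(v) for v in vals]


def cluster_number_recovery(seed: int = 1) -> dict:
    """Criterion-based cluster count on a 200-neuron population, 60 ripples."""
    (s,) = _seeds(seed, 101)
    cfg = SynthConfig(rng_seed=s, duration_s=420.0)
    _, truth = generate_lfp(cfg)
    centers = truth.ripple_times[:60]
    traces = generate_calcium_population(
        cfg, truth, n_neurons=200, fractions=(0.4, 0.4, 0.2)
    )
    chunks = align_events(traces.T, cfg.calcium_rate, centers, 0.5)
    means = chunks.values.mean(axis=0).T
    k_star, curves = select_cluster_number(means, chunks.lags, seed=s)
    return {"k_star": k_star, "curves": curves, "n_neurons": 200, "n_events": centers.size}


def detector_fidelity(
    seed: int = 1, n_sessions: int = 4, n_noise: int = 50, snr: float = 6.0
) -> dict:
    """Precision/recall at +-10 ms on snr-6 sessions; noise FP rate; EMG
    exclusion fraction."""
    session_seeds = _seeds(seed, 102, n_sessions)
    tm = tf = td = 0
    n_excluded = n_events = n_true = 0
    for s in session_seeds:
        cfg = SynthConfig(rng_seed=s, ripple_snr=snr)
        lfp, truth = generate_lfp(cfg)
        emg = generate_emg(cfg, truth)
        events = detect_ripples(lfp, cfg.lfp_rate)
        centers = np.array([e.center for e in events])
        m, fp, miss = match_events(centers, truth.ripple_times, 0.010)
        tm, tf, td = tm + m, tf + fp, td + miss
        _, excluded = exclude_by_emg(events, emg, cfg.lfp_rate)
        n_excluded += len(excluded)
        n_events += len(events)
        n_true += truth.ripple_times.size
    noise_seeds = _seeds(seed, 103, n_noise)
    n_fp, total_s = 0, 0.0
    for s in noise_seeds:
        cfg = SynthConfig(rng_seed=s, ripple_rate_per_min=0.0, duration_s=20.0)
        noise, _ = generate_lfp(cfg)
        n_fp += len(detect_ripples(noise, cfg.lfp_rate))
        total_s += cfg.duration_s
    return {
        "precision": tm / max(1, tm + tf),
        "recall": tm / max(1, tm + td),
        "fp_rate_per_s": n_fp / total_s,
        "emg_excluded_fraction": n_excluded / max(1, n_events),
        "n_true_events": n_true,
        "noise_seconds": total_s,
    }


def null_calibration(seed: int = 1, n_sim: int = 200) -> dict:
    """Z-scored null-aligned averages over fresh simulations.

    Per simulation: white noise, a renewal event set, an interval-
    permutation null, and a held-out surrogate set whose aligned average
    is z-scored against the null.  Reports the lag-averaged mean and SD
    of the resulting z values across simulations.
    """
    rng = np.random.default_rng(_seeds(seed, 104)[0])
    rate, duration, r, window = 100.0, 120.0, 20, 0.5
    n = int(duration * rate)
    zs = []
    for _ in range(n_sim):
        sig = rng.standard_normal(n)
        while True:
            centers = 1.0 + np.cumsum(1.5 + rng.exponential(2.5, size=r))
            if centers[-1] < duration - 1.0:
                break
        null = build_null(
            sig, rate, centers, window, n_perm=200, seed=int(rng.integers(2**31))
        )
        probe = centers[0] + np.r_[0.0, np.cumsum(rng.permutation(np.diff(centers)))]
        ens = align_events(sig, rate, probe, window)
        zs.append(zscore_against_null(ens.mean(), null))
    zs = np.asarray(zs)
    return {
        "z_mean": float(zs.mean(axis=0).mean()),
        "z_sd": float(zs.std(axis=0).mean()),
        "z_mean_worst_lag": float(np.abs(zs.mean(axis=0)).max()),
        "n_sim": n_sim,
    }


def svd_recovery(seed: int = 1) -> dict:
    """Mode recovery, reconstruction identity and variance additivity."""
    from .synthetic import default_masks, generate_widefield_stack

    (s,) = _seeds(seed, 105)
    cfg = SynthConfig(rng_seed=s)
    _, truth = generate_lfp(cfg)
    masks = default_masks()
    stack = generate_widefield_stack(cfg, masks, truth)
    chunks = align_events(stack, cfg.stack_rate, truth.ripple_times, 1.0)
    dec = decompose_concatenated(chunks, k=100)
    spatial = [
        abs(
            np.corrcoef(
                truth.component_spatial_modes[i].ravel(), dec.spatial_modes[i].ravel()
            )[0, 1]
        )
        for i in range(2)
    ]
    from .svd_multiplex import component_peri_event_average

    temporal = []
    for i in range(2):
        _, avg, _ = component_peri_event_average(dec, i + 1)
        temporal.append(abs(np.corrcoef(truth.component_temporal_kernels[i], avg)[0, 1]))

    # full-rank identity on a small construction
    rng = np.random.default_rng(s)
    vals = rng.standard_normal((4, 30, 8, 8))
    small = PeriEventEnsemble(vals, np.arange(30) / 100.0, np.arange(4))
    sdec = decompose_concatenated(small, k=64)
    recon = reconstruct_frames(sdec, range(1, 65))
    rel_err = float(np.linalg.norm(recon - vals) / np.linalg.norm(vals))

    full = reconstruct_subset(dec, range(1, 101), masks, "aRSC")
    first = reconstruct_subset(dec, (1,), masks, "aRSC")
    rest = reconstruct_subset(dec, range(2, 101), masks, "aRSC")
    additivity_err = abs(
        full.variance_explained - first.variance_explained - rest.variance_explained
    )
    varexp1 = float(dec.singular_values[0] ** 2 / np.sum(dec.all_singular_values**2))
    return {
        "min_spatial_corr": min(spatial),
        "min_temporal_corr": min(temporal),
        "reconstruction_rel_error": rel_err,
        "variance_additivity_error": float(additivity_err),
        "varexp_component1": varexp1,
        "n_events": chunks.n_events,
    }


def ensemble_correlation_check(seed: int = 1, r: int = 200) -> dict:
    """Implanted cross-process correlation and lag-tracking asymmetry."""
    rng = np.random.default_rng(_seeds(seed, 106)[0])
    l = 41
    lags = np.arange(l) / 100.0
    ids = np.arange(r)
    u = rng.standard_normal((r, l))
    a = PeriEventEnsemble(
        np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal((r, l)), lags, ids
    )
    b = PeriEventEnsemble(
        np.sqrt(0.6) * u + np.sqrt(0.4) * rng.standard_normal((r, l)), lags, ids
    )
    diag = np.diag(ensemble_correlation(a, b).C)
    self_diag = np.diag(ensemble_correlation(a, a).C)

    shift = 5
    lat = rng.standard_normal((r, l + 2 * shift))
    a2 = PeriEventEnsemble(
        lat[:, shift : l + shift] + 0.3 * rng.standard_normal((r, l)), lags, ids
    )
    b_delayed = PeriEventEnsemble(
        lat[:, :l] + 0.3 * rng.standard_normal((r, l)), lags, ids
    )
    b_leading = PeriEventEnsemble(
        lat[:, 2 * shift :] + 0.3 * rng.standard_normal((r, l)), lags, ids
    )
    return {
        "diag_mean": float(diag.mean()),
        "diag_max_abs_dev": float(np.abs(diag - 0.6).max()),
        "diag_frac_in_band": float(np.mean(np.abs(diag - 0.6) <= 2 / np.sqrt(r))),
        "self_diag_max_err": float(np.abs(self_diag - 1.0).max()),
        "ai_positive_lag": asymmetry_index(ensemble_correlation(a2, b_delayed)),
        "ai_negative_lag": asymmetry_index(ensemble_correlation(a2, b_leading)),
        "n_events": r,
    }


def modulation_calibration(
    seed: int = 1,
    n_null: int = 400,
    n_power: int = 100,
    n_shuffle: int = 1000,
) -> dict:
    """Type-I error, power at rate-gain 3 / 50 events, direction labels."""
    s_null, s_pow = _seeds(seed, 107, 2)
    cfg = SynthConfig(rng_seed=s_null, duration_s=300.0)
    _, truth = generate_lfp(cfg)
    null_traces = generate_calcium_population(
        cfg, truth, n_neurons=n_null, fractions=(0.0, 0.0, 1.0)
    )
    act = deconvolve(null_traces, cfg.calcium_rate)
    res = modulation_test(
        act, cfg.calcium_rate, truth.ripple_times, n_shuffle=n_shuffle, seed=s_null
    )
    type1 = float(res.significant.mean())

    cfg2 = SynthConfig(rng_seed=s_pow, duration_s=400.0)
    _, truth2 = generate_lfp(cfg2)
    centers = truth2.ripple_times[:50]
    traces = generate_calcium_population(
        cfg2, truth2, n_neurons=n_power, fractions=(0.5, 0.5, 0.0),
        baseline_rate_hz=0.5, rate_gain=3.0,
    )
    act2 = deconvolve(traces, cfg2.calcium_rate)
    res2 = modulation_test(
        act2, cfg2.calcium_rate, centers, n_shuffle=n_shuffle, seed=s_pow
    )
    labels = truth2.neuron_labels
    power_up = float(res2.significant[labels == "up"].mean())
    sig = res2.significant
    concordance = (
        float(np.mean(res2.direction[sig] == labels[sig])) if sig.any() else np.nan
    )
    return {
        "type1_error": type1,
        "power_up": power_up,
        "direction_concordance": concordance,
        "n_null": n_null,
        "n_events_power": centers.size,
        "n_shuffle": n_shuffle,
    }


def feature_recovery(seed: int = 1) -> dict:
    """Sigmoid onset/offset recovery and deep-layer unmixing."""
    rng = np.random.default_rng(_seeds(seed, 108)[0])
    lags = np.arange(-50, 51) / 100.0
    t0, tau = 0.05, 0.02
    halfwidth = 2.0 * np.arccosh(np.sqrt(2.0)) * tau
    kernel = 1 / (1 + np.exp(-(lags - t0) / tau))
    # pipeline conditions: features come from event-averaged traces;
    # single-event amplitude SNR 5, averaged over the standard draw of 50
    onset_errs, offset_errs = [], []
    for _ in range(20):
        chunks = kernel[None, :] + 0.2 * rng.standard_normal((50, lags.size))
        f = trace_features(chunks.mean(axis=0), lags)
        onset_errs.append(abs(f.onset - (t0 - halfwidth)))
        offset_errs.append(abs(f.offset - (t0 + halfwidth)))

    deep = np.exp(-((lags - 0.05) ** 2) / (2 * 0.04**2))
    superficial = np.exp(-((lags - 0.15) ** 2) / (2 * 0.06**2))
    ras = superficial + 0.05 * rng.standard_normal(lags.size)
    emx = 0.5 * superficial + 0.5 * deep + 0.05 * rng.standard_normal(lags.size)
    est = deep_layer_estimate(emx, ras, alpha=0.5)
    return {
        "onset_err_mean_s": float(np.mean(onset_errs)),
        "offset_err_mean_s": float(np.mean(offset_errs)),
        "deep_corr_estimate": float(np.corrcoef(est, deep)[0, 1]),
        "deep_corr_raw_emx": float(np.corrcoef(emx, deep)[0, 1]),
        "n_trials": 20,
    }


def multiplex_structure(seed: int = 1, duration_s: float = 300.0) -> dict:
    """Qualitative multiplexing reproduction on a full synthetic session.

    Measures the post-ripple dip of the components-2..K aRSC trace (and
    its absence in V1), and the (0, 100 ms)^2 noise-correlation block of
    each reconstructed trace against hippocampal MUA.
    """
    (s,) = _seeds(seed, 109)
    cfg = RunConfig(seed=s, synth=SynthConfig(duration_s=duration_s))
    bundle = run_session(cfg)

    def block(cf, lo, hi):
        sel = (cf.lags_a >= lo) & (cf.lags_a <= hi)
        return float(np.nanmean(cf.C[np.ix_(sel, sel)]))

    corr = bundle["correlations"]
    rec = bundle["reconstructions"]
    return {
        "arsc_rest_dip": float(rec["aRSC"]["rest"].region_trace.min()),
        "v1_rest_min": float(rec["V1"]["rest"].region_trace.min()),
        "arsc_comp1_peak": float(rec["aRSC"]["comp1"].region_trace.max()),
        "block_arsc_rest": block(corr["aRSC_rest"], 0.0, 0.1),
        "block_arsc_comp1": block(corr["aRSC_comp1"], 0.0, 0.1),
        "block_v1_rest": block(corr["V1_rest"], 0.0, 0.1),
        "block_arsc_rest_far": block(corr["aRSC_rest"], -0.5, -0.3),
        "asymmetry_arsc_rest": bundle["asymmetry_aRSC_rest"],
        "n_events": int(bundle["centers"].size),
    }
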