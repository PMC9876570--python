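"""End-to-end session runs over synthetic data, with a validation suite.

``run_session`` executes the full chain -- simulate, detect, EMG-gate,
align, z-score, SVD-decompose, feature-extract, correlate, cluster and
shuffle-test -- and writes the report bundle (CSV tables, HDF5
correlation matrices, JSON manifest, optional PNG figures) to an output
directory.  ``validate_run`` re-scores a bundle against the generator's
ground truth and emits a machine-readable checklist.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calcium import cluster_peri_ripple, deconvolve, modulation_test, select_cluster_number
from .config import DetectionParams, SynthConfig
from .ephys import compute_mua, detect_ripples, exclude_by_emg, match_events
from .features import trace_features
from .imaging import extract_region_trace
from .io import save_correlation_h5, save_events_csv, save_traces_csv
from .peri_event import (
    align_events,
    asymmetry_index,
    build_null,
    ensemble_correlation,
    resample_ensemble,
    zscore_against_null,
    PeriEventEnsemble,
)
from .svd_multiplex import decompose_concatenated, reconstruct_subset
from .synthetic import generate_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_session", "validate_run"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    window_s: float = 1.0
    n_perm: int = 200
    svd_k: int = 100
    n_shuffle: int = 200
    n_neurons: int = 200
    fractions: tuple = (0.4, 0.4, 0.2)
    modality: str = "glutamate"
    out_dir: str | None = None
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self):
        if self.n_perm < 20:
            raise ValueError("n_perm < 20 gives an unstable null")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")


def _sub_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([stage, seed]).generate_state(1)[0] % (2**31))


def run_session(cfg: RunConfig) -> dict:
    """Execute the full pipeline on one synthetic session.

    Returns the report bundle as a dict (arrays and result objects plus a
    ``manifest``); when ``cfg.out_dir`` is set the tables, matrices and
    manifest are also written there.
    """
    synth = SynthConfig(**{**asdict(cfg.synth), "rng_seed": cfg.seed})
    session = generate_session(
        synth,
        modality=cfg.modality,
        n_neurons=cfg.n_neurons,
        fractions=cfg.fractions,
    )
    truth = session["truth"]
    bundle: dict = {"truth": truth, "config": cfg}

    # --- stage: detect ----------------------------------------------------
    events = detect_ripples(session["lfp"], synth.lfp_rate, cfg.detection)
    kept, excluded = exclude_by_emg(
        events,
        session["emg"],
        synth.lfp_rate,
        halfwidth=cfg.detection.emg_exclusion_halfwidth,
    )
    centers = np.array([e.center for e in kept])
    # alignment windows must fit inside the recording
    centers = centers[
        (centers >= cfg.window_s) & (centers <= synth.duration_s - cfg.window_s)
    ]
    if centers.size < 3:
        raise RuntimeError("stage detect: fewer than 3 ripples survived gating")
    bundle.update(events_kept=kept, events_excluded=excluded, centers=centers)

    # --- stage: align + null z-scoring ------------------------------------
    stack = session["stack"]
    chunks = align_events(stack, synth.stack_rate, centers, cfg.window_s)
    null = build_null(
        stack,
        synth.stack_rate,
        centers,
        cfg.window_s,
        n_perm=cfg.n_perm,
        seed=_sub_seed(cfg.seed, 10),
    )
    chunks_z = zscore_against_null(chunks, null)
    bundle.update(stack_chunks=chunks, stack_chunks_z=chunks_z, stack_null=null)

    mua = compute_mua(session["lfp"], synth.lfp_rate)
    # anti-alias before the 100 Hz lag grid: average over one target
    # frame so interpolation does not discard most of the samples
    from scipy.ndimage import uniform_filter1d

    decim = max(1, int(round(synth.lfp_rate / synth.stack_rate)))
    mua = uniform_filter1d(mua, size=decim, mode="nearest")
    mua_ens = align_events(mua, synth.lfp_rate, centers, cfg.window_s)
    mua_ens = resample_ensemble(mua_ens, chunks.lags)
    bundle["mua_ensemble"] = mua_ens

    # --- stage: SVD multiplexing ------------------------------------------
    # raw dF/F chunks: per-pixel null z-scoring rescales pixels
    # nonuniformly and would distort the spatial modes
    k = min(cfg.svd_k, chunks.n_events * chunks.lags.size, stack.shape[1] * stack.shape[2])
    dec = decompose_concatenated(chunks, k=k)
    masks = session["masks"]
    recon = {
        label: {
            "comp1": reconstruct_subset(dec, (1,), masks, label),
            "rest": reconstruct_subset(dec, range(2, k + 1), masks, label),
        }
        for label in masks
    }
    bundle.update(svd=dec, reconstructions=recon)

    # --- stage: ensemble correlation --------------------------------------
    def corr_vs_mua(event_traces):
        ens = PeriEventEnsemble(event_traces, chunks.lags, chunks.event_ids)
        return ensemble_correlation(ens, mua_ens)

    corr = {
        "aRSC_rest": corr_vs_mua(recon["aRSC"]["rest"].event_traces),
        "aRSC_comp1": corr_vs_mua(recon["aRSC"]["comp1"].event_traces),
        "V1_rest": corr_vs_mua(recon["V1"]["rest"].event_traces),
    }
    bundle["correlations"] = corr
    bundle["asymmetry_aRSC_rest"] = asymmetry_index(corr["aRSC_rest"], (0.0, 0.1))

    # --- stage: features ---------------------------------------------------
    features = {}
    for label in masks:
        trace = extract_region_trace(chunks_z.mean(), masks, label)
        polarity = "deactivation" if cfg.modality == "voltage" else "activation"
        try:
            features[label] = trace_features(trace, chunks.lags, polarity=polarity)
        except ValueError as err:
            logger.warning("features for %s undefined: %s", label, err)
    bundle["features"] = features

    # --- stage: calcium ----------------------------------------------------
    traces = session["calcium"]
    cal_window = 0.5
    cal_chunks = align_events(traces.T, synth.calcium_rate, centers, cal_window)
    mean_traces = cal_chunks.values.mean(axis=0).T  # (N, L)
    k_star, curves = select_cluster_number(
        mean_traces, cal_chunks.lags, seed=_sub_seed(cfg.seed, 20)
    )
    clusters = cluster_peri_ripple(
        mean_traces, cal_chunks.lags, k=k_star, seed=_sub_seed(cfg.seed, 21)
    )
    clusters.criterion_curves = curves
    activity = deconvolve(traces, synth.calcium_rate)
    mod = modulation_test(
        activity,
        synth.calcium_rate,
        centers,
        n_shuffle=cfg.n_shuffle,
        seed=_sub_seed(cfg.seed, 22),
    )
    bundle.update(clusters=clusters, k_star=k_star, modulation=mod)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stage_seeds": {s: _sub_seed(cfg.seed, s) for s in (10, 20, 21, 22)},
        "synth": asdict(synth),
        "detection": asdict(cfg.detection),
        "n_events_detected": len(events),
        "n_events_kept": len(kept),
        "n_events_excluded": len(excluded),
        "svd_k": k,
        "k_star": int(k_star),
    }
    bundle["manifest"] = manifest

    if cfg.out_dir is not None:
        _write_bundle(Path(cfg.out_dir), cfg, bundle)
    return bundle


def _write_bundle(out: Path, cfg: RunConfig, bundle: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    save_events_csv(out / "events.csv", bundle["events_kept"], bundle["events_excluded"])
    save_correlation_h5(out / "correlation_aRSC_rest_vs_mua.h5", bundle["correlations"]["aRSC_rest"])

    import pandas as pd

    rows = []
    for label, fs in bundle["features"].items():
        rows.append({"region": label, **asdict(fs)})
    pd.DataFrame(rows).to_csv(out / "features.csv", index=False)

    mod, clusters = bundle["modulation"], bundle["clusters"]
    pd.DataFrame(
        {
            "neuron_id": np.arange(mod.statistic.size),
            "statistic": mod.statistic,
            "percentile": mod.percentile,
            "significant": mod.significant,
            "direction": mod.direction,
            "cluster": clusters.labels,
        }
    ).to_csv(out / "calcium_results.csv", index=False)

    lags = bundle["stack_chunks"].lags
    traces = {"lag_s": lags}
    for label, r in bundle["reconstructions"].items():
        traces[f"{label}_comp1"] = r["comp1"].region_trace
        traces[f"{label}_rest"] = r["rest"].region_trace
    pd.DataFrame(traces).to_csv(out / "region_traces.csv", index=False)
    save_traces_csv(
        out / "component_variance.csv",
        bundle["svd"].singular_values[None, :] ** 2
        / np.sum(bundle["svd"].all_singular_values**2),
        rate=0.0,
    )

    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
    if cfg.make_figures:
        _make_figures(out, bundle)


def _make_figures(out: Path, bundle: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lags = bundle["stack_chunks"].lags
    fig, ax = plt.subplots(1, 2, figsize=(10, 4))
    for label, r in bundle["reconstructions"].items():
        ax[0].plot(lags, r["rest"].region_trace, label=label)
    ax[0].axvline(0, color="k", lw=0.5)
    ax[0].set(xlabel="lag (s)", ylabel="z", title="components 2..K")
    ax[0].legend(fontsize=6)
    cf = bundle["correlations"]["aRSC_rest"]
    im = ax[1].imshow(
        cf.C,
        origin="lower",
        extent=[cf.lags_b[0], cf.lags_b[-1], cf.lags_a[0], cf.lags_a[-1]],
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
    )
    ax[1].set(xlabel="MUA lag (s)", ylabel="aRSC lag (s)", title="ensemble corr")
    fig.colorbar(im, ax=ax[1])
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=120)
    plt.close(fig)


def validate_run(bundle: dict, tolerance_s: float = 0.010) -> dict:
    """Score a synthetic run against its ground truth.

    Checks detector precision/recall, the z-scoring calibration at
    pre-event lags, recovery of the implanted spatial modes, the selected
    cluster count and the direction concordance of significant neurons.
    Returns a scorecard ``{check: {"pass": bool, "value": float}}`` with
    an overall ``"all_pass"`` entry.
    """
    truth = bundle.get("truth")
    if truth is None or truth.ripple_times.size == 0:
        raise ValueError("validation requires generator ground truth")
    card: dict = {}

    detected = np.array(
        [e.center for e in bundle["events_kept"] + bundle["events_excluded"]]
    )
    n_match, n_fp, n_miss = match_events(detected, truth.ripple_times, tolerance_s)
    precision = n_match / max(1, n_match + n_fp)
    recall = n_match / max(1, n_match + n_miss)
    card["detector_precision"] = {"pass": precision >= 0.9, "value": precision}
    card["detector_recall"] = {"pass": recall >= 0.9, "value": recall}

    chunks_z = bundle["stack_chunks_z"]
    pre = chunks_z.lags < -0.5
    z_pre = float(np.abs(chunks_z.values[:, pre].mean(axis=0)).mean())
    card["zscore_calibration"] = {"pass": z_pre < 1.0, "value": z_pre}

    dec = bundle["svd"]
    corrs = []
    for i, mode in enumerate(truth.component_spatial_modes):
        c = abs(
            np.corrcoef(mode.ravel(), dec.spatial_modes[i].ravel())[0, 1]
        )
        corrs.append(c)
    card["svd_mode_recovery"] = {
        "pass": all(c > 0.95 for c in corrs),
        "value": float(min(corrs)),
    }

    card["cluster_number"] = {
        "pass": bundle["k_star"] == 2,
        "value": float(bundle["k_star"]),
    }

    mod = bundle["modulation"]
    labels = truth.neuron_labels
    sig_mod = mod.significant & np.isin(labels, ["up", "down"])
    if sig_mod.any():
        agree = float(np.mean(mod.direction[sig_mod] == labels[sig_mod]))
        errors = int(np.sum(mod.direction[sig_mod] != labels[sig_mod]))
        # small-sample rule: one disagreement is within expectation when
        # few neurons reach significance in a short session
        ok = errors <= max(1, int(np.ceil(0.05 * sig_mod.sum())))
    else:
        agree, ok = np.nan, False
    card["modulation_direction"] = {"pass": ok, "value": agree}

    card["all_pass"] = {
        "pass": all(v["pass"] for k, v in card.items() if k != "all_pass"),
        "value": float(sum(v["pass"] for k, v in card.items() if k != "all_pass")),
    }
    return card
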