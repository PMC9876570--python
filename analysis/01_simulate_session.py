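#!/usr/bin/env python
"""Simulate a full recording session and write it in the on-disk formats.

Produces, under results/session/: CA1 LFP + neck EMG (HDF5), the
wide-field glutamate stack (multi-page TIFF + JSON sidecar), region masks
(labeled TIFF), the calcium trace table (CSV) and the generator ground
truth (JSON).  Every later analysis script starts from these files.
"""

import json
import sys
from pathlib import Path

import numpy as np

from ripplecortex import SynthConfig, default_masks
from ripplecortex.imaging import ImagingStack
from ripplecortex.io import save_masks_tiff, save_signals_h5, save_stack_tiff, save_traces_csv
from ripplecortex.synthetic import generate_session

OUT = Path(__file__).resolve().parent.parent / "results" / "session"
SEED = 11
DURATION_S = 300.0


def main(seed: int = SEED) -> Path:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(rng_seed=seed, duration_s=DURATION_S)
    sess = generate_session(cfg)
    truth = sess["truth"]

    save_signals_h5(OUT / "ephys.h5", cfg.lfp_rate, lfp=sess["lfp"], emg=sess["emg"])
    save_stack_tiff(
        OUT / "glutamate_stack.tif",
        ImagingStack(sess["stack"].astype(np.float32), cfg.stack_rate, "glutamate"),
    )
    save_masks_tiff(OUT / "masks.tif", sess["masks"])
    save_traces_csv(OUT / "calcium_traces.csv", sess["calcium"], cfg.calcium_rate)

    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "seed": seed,
                "duration_s": cfg.duration_s,
                "ripple_times_s": truth.ripple_times.tolist(),
                "ripple_durations_s": truth.ripple_durations.tolist(),
                "emg_bout_times_s": truth.emg_bout_times.tolist(),
                "event_latents": truth.event_latents.tolist(),
                "neuron_labels": truth.neuron_labels.tolist(),
            },
            indent=2,
        )
    )
    print(
        f"session written to {OUT}: {truth.ripple_times.size} ripples, "
        f"{truth.emg_bout_times.size} EMG bouts, "
        f"{sess['calcium'].shape[0]} calcium neurons"
    )
    return OUT


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
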