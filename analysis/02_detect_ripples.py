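#!/usr/bin/env python
"""Detect sharp-wave ripples from the session LFP and gate them by EMG.

Reads results/session/ephys.h5, runs the band-power detector (110-250 Hz
Morlet bank, mean + 4 SD threshold, 75% boundary, 50 ms concatenation),
excludes ripples with EMG tone within +-500 ms, and scores the detections
against the generator's implanted event times.  Writes
results/events.csv and prints the summary numbers.
"""

import json
from pathlib import Path

import numpy as np

from ripplecortex.ephys import detect_ripples, exclude_by_emg, match_events
from ripplecortex.io import load_signals_h5, save_events_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    session = ROOT / "session"
    if not (session / "ephys.h5").exists():
        import importlib

        importlib.import_module("01_simulate_session")  # pragma: no cover
    lfp, emg, rate = load_signals_h5(session / "ephys.h5")
    truth = json.loads((session / "truth.json").read_text())
    true_times = np.asarray(truth["ripple_times_s"])

    events = detect_ripples(lfp, rate)
    kept, excluded = exclude_by_emg(events, emg, rate)
    save_events_csv(ROOT / "events.csv", kept, excluded)

    centers = np.array([e.center for e in events])
    matched, n_fp, n_miss = match_events(centers, true_times, tolerance=0.010)
    precision = matched / max(1, matched + n_fp)
    recall = matched / max(1, matched + n_miss)
    frac_excluded = len(excluded) / max(1, len(events))

    print(f"implanted ripples : {true_times.size}")
    print(f"detected          : {len(events)}  (kept {len(kept)}, EMG-excluded {len(excluded)})")
    print(f"precision         : {precision:.3f}  (+-10 ms match)")
    print(f"recall            : {recall:.3f}")
    print(f"excluded fraction : {frac_excluded:.3f}")
    durations = 1000 * np.array([e.duration for e in kept])
    peaks = np.array([e.peak_power for e in kept])
    print(f"kept-event duration: {durations.mean():.0f} +- {durations.std():.0f} ms; "
          f"peak power {peaks.mean():.1f} +- {peaks.std():.1f} z")


if __name__ == "__main__":
    main()
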