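"""File formats: HDF5 signals, TIFF stacks, CSV tables, JSON metadata."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ephys import RippleEvent
from .imaging import ImagingStack

__all__ = [
    "save_signals_h5",
    "load_signals_h5",
    "save_stack_tiff",
    "load_stack_tiff",
    "save_masks_tiff",
    "load_masks_tiff",
    "events_to_frame",
    "save_events_csv",
    "load_events_csv",
    "save_traces_csv",
    "load_traces_csv",
    "save_correlation_h5",
    "load_correlation_h5",
]


def save_signals_h5(path, rate_hz: float, lfp=None, emg=None) -> None:
    with h5py.File(path, "w") as f:
        if lfp is not None:
            f.create_dataset("lfp", data=np.asarray(lfp))
        if emg is not None:
            f.create_dataset("emg", data=np.asarray(emg))
        f.attrs["rate_hz"] = float(rate_hz)


def load_signals_h5(path):
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate_hz"])
        lfp = f["lfp"][:] if "lfp" in f else None
        emg = f["emg"][:] if "emg" in f else None
    return lfp, emg, rate


def save_stack_tiff(path, stack: ImagingStack) -> None:
    """Multi-page TIFF plus a JSON sidecar carrying rate and modality."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {"rate_hz": stack.rate, "modality": stack.modality, "time0": stack.time0}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_stack_tiff(path) -> ImagingStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImagingStack(
        frames, meta["rate_hz"], meta["modality"], meta.get("time0", 0.0)
    )


def save_masks_tiff(path, masks: dict) -> None:
    """Labeled 16-bit TIFF (0 = background) with a JSON label map."""
    path = Path(path)
    labels = sorted(masks)
    shape = masks[labels[0]].shape
    img = np.zeros(shape, dtype=np.uint16)
    for i, label in enumerate(labels, start=1):
        img[masks[label]] = i
    tifffile.imwrite(path, img)
    path.with_suffix(".json").write_text(
        json.dumps({str(i): label for i, label in enumerate(labels, start=1)})
    )


def load_masks_tiff(path) -> dict:
    path = Path(path)
    img = tifffile.imread(path)
    label_map = json.loads(path.with_suffix(".json").read_text())
    return {label: img == int(i) for i, label in label_map.items()}


def events_to_frame(kept, excluded=()) -> pd.DataFrame:
    rows = [
        {
            "onset_s": e.onset,
            "offset_s": e.offset,
            "center_s": e.center,
            "duration_s": e.duration,
            "peak_power_z": e.peak_power,
            "excluded_flag": flag,
        }
        for group, flag in ((kept, False), (excluded, True))
        for e in group
    ]
    return pd.DataFrame(rows).sort_values("center_s", ignore_index=True) if rows else (
        pd.DataFrame(
            columns=[
                "onset_s",
                "offset_s",
                "center_s",
                "duration_s",
                "peak_power_z",
                "excluded_flag",
            ]
        )
    )


def save_events_csv(path, kept, excluded=()) -> None:
    events_to_frame(kept, excluded).to_csv(path, index=False)


def load_events_csv(path):
    df = pd.read_csv(path)
    kept, excluded = [], []
    for _, row in df.iterrows():
        ev = RippleEvent(
            onset=row.onset_s,
            offset=row.offset_s,
            center=row.center_s,
            duration=row.duration_s,
            peak_power=row.peak_power_z,
        )
        (excluded if row.excluded_flag else kept).append(ev)
    return kept, excluded


def save_traces_csv(path, traces: np.ndarray, rate: float) -> None:
    """Neurons x time CSV; the sampling rate rides in the header comment."""
    df = pd.DataFrame(np.atleast_2d(traces))
    with open(path, "w") as f:
        f.write(f"# rate_hz={rate}\n")
        df.to_csv(f, index=False)


def load_traces_csv(path):
    with open(path) as f:
        header = f.readline().strip()
        rate = float(header.split("=", 1)[1]) if header.startswith("#") else 19.6
        df = pd.read_csv(f)
    return df.to_numpy(), rate


def save_correlation_h5(path, cf) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=cf.C)
        f.create_dataset("lags_a", data=cf.lags_a)
        f.create_dataset("lags_b", data=cf.lags_b)
        f.attrs["n_events"] = cf.n_events


def load_correlation_h5(path):
    from .peri_event import CorrelationFunction

    with h5py.File(path, "r") as f:
        return CorrelationFunction(
            C=f["C"][:],
            lags_a=f["lags_a"][:],
            lags_b=f["lags_b"][:],
            n_events=int(f.attrs["n_events"]),
        )
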