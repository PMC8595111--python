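"""On-disk formats.

Continuous recordings are stored as raw little-endian float32 (`.dat`,
channel-major) with a JSON sidecar carrying rate, channel labels, unit and
metadata, plus a BIDS-events-style TSV (columns onset, label). Epoch sets
round-trip through NPZ. Tables are TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ContinuousRecording, EpochSet, StimulusSequence


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_events(sequence: StimulusSequence, path: Path) -> Path:
    df = pd.DataFrame({"onset": sequence.onsets_s, "label": sequence.labels})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: Path, isi_s: float) -> StimulusSequence:
    df = pd.read_csv(path, sep="\t")
    return StimulusSequence(tuple(df["label"]),
                            df["onset"].to_numpy(float), isi_s)


def write_recording(rec: ContinuousRecording, stem) -> Path:
    """Write ``<stem>.dat`` + ``<stem>.json`` + ``<stem>_events.tsv``;
    returns the sidecar path (the round-trip entry point)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(rec.data, dtype="<f4")
    dat = stem.with_suffix(".dat")
    payload.tofile(dat)
    events = Path(f"{stem}_events.tsv")
    write_events(rec.events, events)
    meta = {k: v for k, v in rec.meta.items()}
    sidecar = {
        "fs_hz": rec.fs_hz,
        "channels": list(rec.channels),
        "unit": "uV",
        "dtype": "<f4",
        "n_channels": int(payload.shape[0]),
        "n_samples": int(payload.shape[1]),
        "isi_s": rec.events.isi_s,
        "data_file": dat.name,
        "events_file": events.name,
        "meta": meta,
    }
    side = stem.with_suffix(".json")
    side.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return side


def read_recording(path) -> ContinuousRecording:
    """Read a recording from its JSON sidecar (or stem) path."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar {path}")
    side = json.loads(path.read_text())
    dat = path.parent / side["data_file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing data file {dat}")
    n_ch, n_samp = side["n_channels"], side["n_samples"]
    expected = n_ch * n_samp * 4
    found = dat.stat().st_size
    if found != expected:
        raise IOError(
            f"truncated or corrupt data file {dat.name}: expected "
            f"{expected} bytes ({n_ch} channels x {n_samp} samples x "
            f"float32), found {found}")
    data = np.fromfile(dat, dtype="<f4").reshape(n_ch, n_samp)
    events = read_events(path.parent / side["events_file"], side["isi_s"])
    return ContinuousRecording(
        channels=tuple(side["channels"]), fs_hz=float(side["fs_hz"]),
        data=data, events=events, meta=dict(side.get("meta", {})))


def write_epochs(epochs: EpochSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, data=epochs.data.astype("<f4"), time_ms=epochs.time_ms,
        fs_hz=np.array(epochs.fs_hz),
        trial_class=np.asarray(epochs.trial_class, dtype="U16"),
        channels=np.asarray(epochs.channels, dtype="U8"),
        retained=epochs.retained,
        meta=np.frombuffer(
            json.dumps(epochs.meta, sort_keys=True, default=str)
            .encode(), dtype=np.uint8))
    return path if path.suffix == ".npz" else path.with_suffix(".npz")


def read_epochs(path) -> EpochSet:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode()) if "meta" in z else {}
        return EpochSet(
            data=z["data"].astype(float), time_ms=z["time_ms"],
            fs_hz=float(z["fs_hz"]), trial_class=z["trial_class"],
            channels=tuple(z["channels"]), retained=z["retained"],
            meta=meta)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
    return path
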