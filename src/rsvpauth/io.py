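"""On-disk formats: array container + JSON sidecar, events/metrics TSV,
model bundles, and optional EDF reading.

The pipeline's native continuous-EEG format is a documented array container:
``<prefix>.npy`` (channels × samples float64, µV) with a ``<prefix>.json``
sidecar (sampling rate, channel names, provenance) and a ``<prefix>.events.tsv``
event table (columns ``sample_index``, ``label``).  Epoch sets and trained
models are ``.npz`` bundles with JSON sidecars.  All writes round-trip
bit-identically.  EDF import is available when ``mne`` is installed (the
``edf`` extra); no EDF writer is provided, the array container being the
interchange format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hdca import HDCAModel, WindowingScheme
from .preprocess import EpochSet
from .simulate import ContinuousRecording


def _sidecar(prefix: Path) -> Path:
    return prefix.with_suffix(".json")


def write_events_tsv(events: list[tuple[int, str]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["sample_index", "label"]).to_csv(
        path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(r.sample_index), str(r.label)) for r in df.itertuples()]


def save_recording(rec: ContinuousRecording, prefix: str | Path,
                   meta: dict | None = None) -> None:
    """Write ``<prefix>.npy`` + ``<prefix>.json`` + ``<prefix>.events.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), rec.data)
    write_events_tsv(rec.events, prefix.with_suffix(".events.tsv"))
    sidecar = {
        "format": "rsvpauth-recording",
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "n_samples": rec.n_samples,
        "units": "uV",
        **(meta or {}),
    }
    _sidecar(prefix).write_text(json.dumps(sidecar, indent=2))


def load_recording(prefix: str | Path) -> ContinuousRecording:
    prefix = Path(prefix)
    meta = json.loads(_sidecar(prefix).read_text())
    data = np.load(prefix.with_suffix(".npy"))
    events = read_events_tsv(prefix.with_suffix(".events.tsv"))
    return ContinuousRecording(data=data, fs=float(meta["fs"]),
                               channel_names=tuple(meta["channel_names"]),
                               events=events)


def save_epochs(ep: EpochSet, prefix: str | Path, meta: dict | None = None) -> None:
    """Write ``<prefix>.npz`` (data, labels) + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(prefix.with_suffix(".npz"), data=ep.data, labels=ep.labels)
    sidecar = {
        "format": "rsvpauth-epochs",
        "fs": ep.fs,
        "t0": ep.t0,
        "channel_names": list(ep.channel_names),
        "provenance": _jsonable(ep.provenance),
        **(meta or {}),
    }
    _sidecar(prefix).write_text(json.dumps(sidecar, indent=2))


def load_epochs(prefix: str | Path) -> EpochSet:
    prefix = Path(prefix)
    meta = json.loads(_sidecar(prefix).read_text())
    with np.load(prefix.with_suffix(".npz")) as npz:
        data, labels = npz["data"], npz["labels"]
    return EpochSet(data=data, labels=labels, fs=float(meta["fs"]),
                    t0=float(meta["t0"]),
                    channel_names=tuple(meta["channel_names"]),
                    provenance=meta.get("provenance", {}))


def save_model(model: HDCAModel, prefix: str | Path, meta: dict | None = None) -> None:
    """Write ``<prefix>.npz`` (weights, mask) + ``<prefix>.json`` metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(prefix.with_suffix(".npz"),
             spatial_weights=model.spatial_weights,
             temporal_weights=model.temporal_weights,
             channel_mask=model.channel_mask)
    sidecar = {
        "format": "rsvpauth-model",
        "intercept": model.intercept,
        "threshold": model.threshold,
        "window_ms": model.windows.window_ms,
        "window_bounds": [list(b) for b in model.windows.bounds],
        "channel_names": list(model.channel_names),
        "selected_channels": [n for n, m in zip(model.channel_names, model.channel_mask) if m],
        **(meta or {}),
    }
    _sidecar(prefix).write_text(json.dumps(sidecar, indent=2))


def load_model(prefix: str | Path) -> HDCAModel:
    prefix = Path(prefix)
    meta = json.loads(_sidecar(prefix).read_text())
    with np.load(prefix.with_suffix(".npz")) as npz:
        W = npz["spatial_weights"]
        v = npz["temporal_weights"]
        mask = npz["channel_mask"]
    windows = WindowingScheme(window_ms=float(meta["window_ms"]),
                              bounds=tuple(tuple(b) for b in meta["window_bounds"]))
    return HDCAModel(spatial_weights=W, temporal_weights=v,
                     intercept=float(meta["intercept"]),
                     threshold=float(meta["threshold"]),
                     windows=windows, channel_mask=mask,
                     channel_names=tuple(meta["channel_names"]))


def write_mask_tsv(mask: np.ndarray, channel_names: tuple[str, ...],
                   path: str | Path, fitness: float | None = None) -> None:
    """Channel mask as one 0/1 row under a channel-name header."""
    df = pd.DataFrame([[int(b) for b in mask]], columns=list(channel_names))
    df.insert(len(channel_names), "n_selected", int(np.sum(mask)))
    if fitness is not None:
        df["cv_accuracy"] = fitness
    df.to_csv(path, sep="\t", index=False)


def write_trace_tsv(history: dict, path: str | Path) -> None:
    pd.DataFrame({"generation": range(len(history["best"])),
                  "best_fitness": history["best"],
                  "mean_fitness": history["mean"]}).to_csv(path, sep="\t", index=False)


def load_edf(path: str | Path, events_path: str | Path) -> ContinuousRecording:
    """Read a continuous EDF recording plus an events TSV (needs ``mne``)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional extra
        raise ImportError("EDF reading requires the 'edf' extra (mne)") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return ContinuousRecording(data=data, fs=float(raw.info["sfreq"]),
                               channel_names=tuple(raw.ch_names),
                               events=read_events_tsv(events_path))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
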