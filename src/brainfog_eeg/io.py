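"""File formats: recordings (EDF or CSV-matrix + JSON header), montages,
schedules, epochs and feature tables.

EDF writing uses the package's own writer (:mod:`._edf`); EDF reading goes
through mne's reader, which keeps the round trip honest — two independent
codebases must agree to within one 16-bit quantization step.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import write_edf
from .containers import Epochs, Montage, Recording

__all__ = [
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
    "load_bundled_montage",
    "write_epochs",
    "read_epochs",
]

BUNDLED_MONTAGE = "gsn_hydrocel_256.csv"


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def read_montage(path) -> Montage:
    """Read a montage CSV with columns name, x, y, z, radius."""
    table = pd.read_csv(path)
    missing = {"name", "x", "y", "z", "radius"} - set(table.columns)
    if missing:
        raise ValueError(f"montage file {path} missing columns {sorted(missing)}")
    return Montage(table)


def write_montage(montage: Montage, path) -> None:
    montage.table.to_csv(path, index=False)


def load_bundled_montage() -> Montage:
    """The bundled 256-channel geodesic-net montage with projected radii."""
    ref = resources.files("brainfog_eeg").joinpath("data", BUNDLED_MONTAGE)
    with resources.as_file(ref) as p:
        return read_montage(p)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """Write a recording as ``.edf`` or as ``.csv`` + JSON sidecar.

    The CSV dialect stores the ``channels x samples`` matrix with channel
    names as the index and a ``<stem>.json`` sidecar carrying the sampling
    rate and subject metadata.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(path, rec.data, rec.fs, rec.channel_names,
                  patient_id=rec.subject_id or "X",
                  recording_id=f"cohort={rec.cohort_label or 'NA'}")
    elif path.suffix.lower() == ".csv":
        df = pd.DataFrame(rec.data, index=rec.channel_names)
        df.to_csv(path, index_label="channel")
        sidecar = {
            "fs": rec.fs,
            "n_channels": rec.n_channels,
            "n_samples": rec.n_samples,
            "subject_id": rec.subject_id,
            "cohort_label": rec.cohort_label,
            "units": "uV",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown recording extension {path.suffix!r} "
                         "(expected .edf or .csv)")


def read_recording(path, montage: Montage | None = None) -> Recording:
    """Read an ``.edf`` or ``.csv``+JSON recording, data in microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty, not a recording")
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts for uV channels
        subject = (raw.info.get("subject_info") or {}).get("his_id", "") or ""
        return Recording(
            data=data,
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            montage=montage,
            subject_id=subject,
        )
    if path.suffix.lower() == ".csv":
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(f"matrix recording {path} lacks JSON sidecar "
                             f"{sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        fs = float(sidecar.get("fs", 0))
        if fs <= 0:
            raise ValueError(f"sidecar of {path} has non-positive fs={fs}")
        df = pd.read_csv(path, index_col="channel")
        data = df.to_numpy(dtype=float)
        if "n_channels" in sidecar and sidecar["n_channels"] != data.shape[0]:
            raise ValueError(
                f"sidecar declares {sidecar['n_channels']} channels but the "
                f"matrix has {data.shape[0]}"
            )
        return Recording(
            data=data, fs=fs, channel_names=[str(c) for c in df.index],
            montage=montage,
            subject_id=sidecar.get("subject_id", ""),
            cohort_label=sidecar.get("cohort_label", ""),
        )
    raise ValueError(f"unknown recording extension {path.suffix!r} "
                     "(expected .edf or .csv)")


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

def write_epochs(epochs: Epochs, path) -> None:
    """Long-format CSV (trial, channel, t0..tN columns) + JSON sidecar."""
    path = Path(path)
    n_tr, n_ch, n_t = epochs.data.shape
    idx = pd.MultiIndex.from_product(
        [range(n_tr), epochs.channel_names], names=["trial", "channel"]
    )
    df = pd.DataFrame(epochs.data.reshape(n_tr * n_ch, n_t), index=idx)
    df.to_csv(path)
    sidecar = {
        "fs": epochs.fs,
        "tmin_ms": epochs.tmin_ms,
        "tmax_ms": epochs.tmax_ms,
        "condition_codes": epochs.condition_codes,
        "baseline_window_ms": epochs.baseline_window_ms,
        "subject_id": epochs.subject_id,
        "cohort_label": epochs.cohort_label,
        "paradigm": epochs.paradigm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path) -> Epochs:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, index_col=[0, 1])
    trials = df.index.get_level_values(0).unique()
    channels = list(dict.fromkeys(df.index.get_level_values(1)))
    n_t = df.shape[1]
    data = df.to_numpy(dtype=float).reshape(len(trials), len(channels), n_t)
    baseline = sidecar.get("baseline_window_ms")
    return Epochs(
        data=data, fs=sidecar["fs"], tmin_ms=sidecar["tmin_ms"],
        tmax_ms=sidecar["tmax_ms"], channel_names=[str(c) for c in channels],
        condition_codes=list(sidecar["condition_codes"]),
        baseline_window_ms=tuple(baseline) if baseline else None,
        subject_id=sidecar.get("subject_id", ""),
        cohort_label=sidecar.get("cohort_label", ""),
        paradigm=sidecar.get("paradigm", ""),
    )
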