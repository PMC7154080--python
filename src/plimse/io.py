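"""Reading and writing recordings (EDF and a documented CSV dialect).

CSV dialect: one file per recording, a header row of channel labels, one
sample per row, values in microvolt-like units.  The sampling rate lives in a
JSON sidecar ``<file>.meta.json`` (key ``fs``) or is passed explicitly.

EDF files are read through :mod:`mne`.  Writing uses a small built-in EDF
writer (16-bit, 1-s data records) so cohorts can be exchanged with standard
EEG tools; the mne reader doubles as an independent check on round trips.
"""

from __future__ import annotations

import csv
import json
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import DEFAULT_MONTAGE, Recording


class RecordingParseError(ValueError):
    """A recording file is missing, malformed, or inconsistent."""


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False, float_format="%.6f")
    _sidecar_path(path).write_text(json.dumps({"fs": rec.fs}))
    return path


def read_recording_csv(path: str | Path, fs: float | None = None) -> Recording:
    path = Path(path)
    if not path.exists():
        raise RecordingParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise RecordingParseError(f"empty recording file: {path}")
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if header is None or not header or any(lbl.strip() == "" for lbl in header):
        raise RecordingParseError(f"{path}: missing or blank channel-label header row")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RecordingParseError(f"{path}: failed to parse CSV ({exc})") from exc
    if df.shape[0] == 0:
        raise RecordingParseError(f"{path}: header only, no samples")
    if df.isna().any().any():
        raise RecordingParseError(f"{path}: ragged rows (unequal channel lengths)")
    if fs is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise RecordingParseError(
                f"{path}: sampling rate unknown; provide fs or a {sidecar.name} sidecar"
            )
        fs = float(json.loads(sidecar.read_text())["fs"])
    return Recording(samples=df.to_numpy().T, fs=fs, channel_labels=tuple(df.columns))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")[:width]
    return out + b" " * (width - len(out))


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file with 1-second data records.

    Requires an integer number of seconds of data (true for the cohorts this
    package generates); physical units are declared as uV.
    """
    path = Path(path)
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs_int != 0:
        raise ValueError("EDF writer requires a whole number of 1-s records")
    n_records = rec.n_samples // fs_int
    ns = rec.n_channels

    phys_min = np.minimum(rec.samples.min(axis=1), -1e-6)
    phys_max = np.maximum(rec.samples.max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((rec.samples - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field("X X X X", 80),
        _ascii_field("Startdate X X X X", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(str(256 * (ns + 1)), 8),
        _ascii_field("", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),
        _ascii_field(str(ns), 4),
    ])
    per_signal = b"".join([
        b"".join(_ascii_field(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_ascii_field("", 80) for _ in range(ns)),
        b"".join(_ascii_field("uV", 8) for _ in range(ns)),
        b"".join(_ascii_field(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(_ascii_field(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(_ascii_field(str(dig_min), 8) for _ in range(ns)),
        b"".join(_ascii_field(str(dig_max), 8) for _ in range(ns)),
        b"".join(_ascii_field("", 80) for _ in range(ns)),
        b"".join(_ascii_field(str(fs_int), 8) for _ in range(ns)),
        b"".join(_ascii_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            block = digital[:, r * fs_int:(r + 1) * fs_int]
            fh.write(struct.pack(f"<{ns * fs_int}h", *block.reshape(-1)))
    return path


def read_recording_edf(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise RecordingParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise RecordingParseError(f"empty recording file: {path}")
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise RecordingParseError(f"{path}: failed to parse EDF ({exc})") from exc
    # mne rescales channels it recognises as EEG to volts; restore uV.
    data = raw.get_data() * 1e6
    return Recording(samples=data, fs=float(raw.info["sfreq"]),
                     channel_labels=tuple(raw.ch_names))


# ---------------------------------------------------------------------------
# Dispatch and cohort manifests
# ---------------------------------------------------------------------------

def check_montage(rec: Recording) -> bool:
    """Warn when the channel set differs from the default 16-channel montage."""
    ok = rec.channel_labels == DEFAULT_MONTAGE
    if not ok:
        warnings.warn(
            f"recording has {rec.n_channels} channels "
            f"({', '.join(rec.channel_labels[:4])}...); downstream analyses "
            f"assume the default 16-channel 10-20 montage",
            UserWarning,
            stacklevel=2,
        )
    return ok


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return write_recording_edf(rec, path)
    if fmt == "csv":
        return write_recording_csv(rec, path)
    raise ValueError(f"unknown recording format {fmt!r} (expected 'edf' or 'csv')")


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None,
                   expect_default_montage: bool = False) -> Recording:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        rec = read_recording_edf(path)
    elif fmt == "csv":
        rec = read_recording_csv(path, fs=fs)
    else:
        raise RecordingParseError(f"unknown recording format {fmt!r}")
    if expect_default_montage:
        check_montage(rec)
    return rec


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a cohort manifest (subject_id, group, seed, file) as CSV."""
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "group", "seed", "file"]).to_csv(
        path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "seed", "file"} - set(df.columns)
    if missing:
        raise RecordingParseError(f"manifest {path} missing columns: {sorted(missing)}")
    return df
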