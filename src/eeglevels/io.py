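"""Reading and writing recordings, manifests and feature tables as delimited text.

Signal values are serialized with 17 significant digits so a write/read round
trip reproduces float64 samples bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FeatureTable, Recording

_FLOAT_FMT = "%.17g"


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write one recording as CSV: header = channel names, one row per sample."""
    path = Path(path)
    header = ",".join(recording.channel_names)
    np.savetxt(path, recording.samples.T, delimiter=",", header=header,
               comments="", fmt=_FLOAT_FMT)


def read_recording(path: str | Path, subject_id: str, sampling_rate: float,
                   time_origin: float) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    with open(path) as fh:
        channel_names = fh.readline().strip().split(",")
    samples = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Recording(
        subject_id=subject_id,
        channel_names=channel_names,
        sampling_rate=sampling_rate,
        samples=samples.T,
        time_origin=time_origin,
    )


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write one CSV per subject plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        write_recording(rec, out_dir / fname)
        entries.append({
            "subject_id": rec.subject_id,
            "file": fname,
            "sampling_rate": rec.sampling_rate,
            "time_origin": rec.time_origin,
        })
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=2, sort_keys=True))
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Recording]:
    """Read every recording listed in a cohort manifest."""
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    recs = []
    for entry in meta["recordings"]:
        recs.append(read_recording(
            manifest_path.parent / entry["file"],
            subject_id=entry["subject_id"],
            sampling_rate=entry["sampling_rate"],
            time_origin=entry["time_origin"],
        ))
    return recs


def read_recording_edf(path: str | Path, subject_id: str, time_origin: float) -> Recording:
    """Adapter for European Data Format files (requires the optional ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'mne' package (pip install eeglevels[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        subject_id=subject_id,
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        samples=raw.get_data(),
        time_origin=time_origin,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Export a feature table as CSV with label, subject and window columns."""
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path: str | Path, level: str) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = [c for c in ("label", "subject", "window") if c in df.columns]
    feature_names = [c for c in df.columns if c not in meta_cols]
    return FeatureTable(
        level=level,
        feature_names=feature_names,
        X=df[feature_names].to_numpy(dtype=np.float64),
        y=df["label"].to_numpy(),
        groups=df["subject"].to_numpy(),
        window_ids=df["window"].to_numpy() if "window" in df.columns else None,
    )
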