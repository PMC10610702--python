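"""Cohort and report I/O.

Records travel as one CSV per subject (rows = samples, columns = channels,
header = channel names) with a JSON sidecar carrying label, sampling rate and
generator seed.  All writers are deterministic: fixed float formatting, sorted
JSON keys, trailing newline — re-running a pipeline with identical seeds must
reproduce files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .simulate import EEGRecord

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_cohort",
    "read_cohort",
    "write_segments",
    "read_segments",
    "read_edf",
    "write_json",
    "config_hash",
]

_FLOAT_FMT = "%.4f"  # 0.1 µV resolution, far below any decision threshold


def write_json(path: str | Path, obj) -> None:
    """Canonical JSON writer (sorted keys, 2-space indent, trailing newline)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def write_record_csv(record: EEGRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(record.data.T, columns=list(record.channel_names))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "subject_id": record.subject_id,
        "label": record.label,
        "fs": record.fs,
        "channel_names": list(record.channel_names),
        "meta": record.meta,
    }
    write_json(path.with_suffix(".json"), sidecar)


def read_record_csv(path: str | Path) -> EEGRecord:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InvalidArgumentError(f"missing sidecar metadata: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    if list(df.columns) != list(sidecar["channel_names"]):
        raise InvalidArgumentError(
            f"channel names in {path} disagree with sidecar"
        )
    return EEGRecord(
        subject_id=sidecar["subject_id"],
        label=sidecar["label"],
        data=df.to_numpy(dtype=np.float64).T,
        fs=float(sidecar["fs"]),
        channel_names=list(df.columns),
        meta=sidecar.get("meta", {}),
    )


def write_cohort(records: Iterable[EEGRecord], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = out_dir / f"{rec.subject_id}.csv"
        write_record_csv(rec, p)
        paths.append(p)
    return paths


def read_cohort(in_dir: str | Path) -> list[EEGRecord]:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.csv"))
    if not paths:
        raise InvalidArgumentError(f"no record CSVs found in {in_dir}")
    return [read_record_csv(p) for p in paths]


def write_segments(segments, out_dir: str | Path) -> Path:
    """Write preprocessed segments as one long-format CSV plus metadata.

    Rows are samples in segment order; columns: subject, label, segment, then
    one column per channel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not segments:
        raise InvalidArgumentError("no segments to write")
    channels = list(segments[0].channel_names)
    frames = []
    for seg in segments:
        df = pd.DataFrame(seg.channel_data.T, columns=channels)
        df.insert(0, "segment", seg.segment_index)
        df.insert(0, "label", seg.label)
        df.insert(0, "subject", seg.subject_id)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    path = out_dir / "segments.csv"
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_json(out_dir / "segments.json", {
        "channel_names": channels,
        "L_EEG": segments[0].L_EEG,
        "n_segments": len(segments),
    })
    return path


def read_segments(in_dir: str | Path):
    """Read segments written by :func:`write_segments`, preserving order."""
    from .preprocess import Segment  # local import to avoid a cycle

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "segments.json").read_text())
    df = pd.read_csv(in_dir / "segments.csv")
    channels = meta["channel_names"]
    L = int(meta["L_EEG"])
    segments = []
    for (subject, label, seg_idx), block in df.groupby(
        ["subject", "label", "segment"], sort=False
    ):
        segments.append(Segment(
            subject_id=str(subject),
            label=str(label),
            channel_data=block[channels].to_numpy(dtype=np.float64).T,
            L_EEG=L,
            segment_index=int(seg_idx),
            channel_names=channels,
        ))
    return segments


def read_edf(path: str | Path, label: str = "", subject_id: str | None = None) -> EEGRecord:
    """Read an EDF record via MNE into an :class:`EEGRecord` (data in µV).

    Requires ``mne``; labels are not stored in EDF and must be supplied.
    """
    import mne  # deferred: optional backend

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return EEGRecord(
        subject_id=subject_id or Path(path).stem,
        label=label,
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )
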