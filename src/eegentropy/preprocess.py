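"""Band-pass filtering, segmentation and amplitude-threshold artifact rejection.

The protocol this implements: a fifth-order Butterworth band-pass at
0.5-32 Hz applied zero-phase (forward-backward, so the effective magnitude
order is doubled and phase distortion is nil), division of each record into
non-overlapping contiguous segments of L_EEG samples, and rejection of any
segment containing a sample whose magnitude strictly exceeds ±85 µV.  The
ordering filter → segment → reject is fixed; an alternative ``clip`` artifact
mode truncates amplitudes in place instead of discarding segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .exceptions import InvalidArgumentError, ShortageError
from .simulate import EEGRecord

__all__ = [
    "Segment",
    "bandpass_filter",
    "segment_record",
    "reject_artifacts",
    "preprocess_record",
    "preprocess_cohort",
    "PROTOCOL_SEGMENT_RANGE",
]

#: Segment lengths (samples) used by the reference protocol.
PROTOCOL_SEGMENT_RANGE = (150, 1000)


@dataclass
class Segment:
    """One contiguous multichannel window treated as an independent observation."""

    subject_id: str
    label: str
    channel_data: np.ndarray  # channels x L_EEG, µV
    L_EEG: int
    segment_index: int
    channel_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channel_data = np.asarray(self.channel_data, dtype=np.float64)
        if self.channel_data.ndim != 2 or self.channel_data.shape[1] != self.L_EEG:
            raise InvalidArgumentError("channel_data must be channels x L_EEG")


def bandpass_filter(
    record: EEGRecord,
    low_hz: float = 0.5,
    high_hz: float = 32.0,
    order: int = 5,
) -> EEGRecord:
    """Zero-phase Butterworth band-pass of every channel."""
    if not (0 < low_hz < high_hz < record.fs / 2):
        raise InvalidArgumentError(
            f"need 0 < low_hz < high_hz < fs/2; got ({low_hz}, {high_hz}) at fs={record.fs}"
        )
    if order < 1:
        raise InvalidArgumentError("order must be at least 1")
    sos = _signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=record.fs, output="sos")
    # sosfiltfilt pads with ~6x the section count of samples on each side.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if record.n_samples <= padlen:
        raise InvalidArgumentError(
            f"record of {record.n_samples} samples is too short for zero-phase "
            f"filtering (needs > {padlen})"
        )
    data = _signal.sosfiltfilt(sos, record.data, axis=1)
    return EEGRecord(
        subject_id=record.subject_id,
        label=record.label,
        data=data,
        fs=record.fs,
        channel_names=list(record.channel_names),
        meta=dict(record.meta),
    )


def segment_record(
    record: EEGRecord,
    L_EEG: int,
    n_segments: int | None = None,
) -> list[Segment]:
    """Cut ``n_segments`` contiguous non-overlapping windows from the start.

    ``n_segments=None`` returns every full window.  Lengths outside the
    reference protocol range are allowed but flagged with a warning.
    """
    if L_EEG < 2:
        raise InvalidArgumentError("L_EEG must be at least 2 samples")
    lo, hi = PROTOCOL_SEGMENT_RANGE
    if not lo <= L_EEG <= hi:
        warnings.warn(
            f"L_EEG={L_EEG} lies outside the protocol range [{lo}, {hi}]",
            UserWarning, stacklevel=2,
        )
    available = record.n_samples // L_EEG
    if n_segments is None:
        n_segments = available
    if n_segments < 1:
        raise InvalidArgumentError("n_segments must be at least 1")
    if available < n_segments:
        deficit = n_segments * L_EEG - record.n_samples
        raise ShortageError(
            f"record {record.subject_id} has {record.n_samples} samples; "
            f"{n_segments} segments of {L_EEG} need {deficit} more"
        )
    return [
        Segment(
            subject_id=record.subject_id,
            label=record.label,
            channel_data=record.data[:, i * L_EEG:(i + 1) * L_EEG].copy(),
            L_EEG=L_EEG,
            segment_index=i,
            channel_names=list(record.channel_names),
        )
        for i in range(n_segments)
    ]


def reject_artifacts(
    segments: Sequence[Segment],
    threshold_uV: float = 85.0,
) -> tuple[list[Segment], int]:
    """Drop segments containing any sample with \\|x\\| strictly above threshold.

    A sample exactly at the threshold is kept (strict-inequality convention),
    so threshold 0 rejects exactly the segments with any non-zero sample.
    Kept segments preserve their order and original ``segment_index``.
    """
    if threshold_uV < 0:
        raise InvalidArgumentError("threshold_uV must be non-negative")
    kept = [s for s in segments
            if not np.any(np.abs(s.channel_data) > threshold_uV)]
    return kept, len(segments) - len(kept)


def preprocess_record(
    record: EEGRecord,
    L_EEG: int = 1000,
    n_segments: int = 5,
    low_hz: float = 0.5,
    high_hz: float = 32.0,
    order: int = 5,
    threshold_uV: float = 85.0,
    artifact_mode: str = "reject_segment",
) -> list[Segment]:
    """filter → segment → reject, then keep the first ``n_segments`` survivors."""
    if artifact_mode not in ("reject_segment", "clip"):
        raise InvalidArgumentError(f"unknown artifact_mode: {artifact_mode!r}")
    filtered = bandpass_filter(record, low_hz=low_hz, high_hz=high_hz, order=order)
    segments = segment_record(filtered, L_EEG, n_segments=None)
    if artifact_mode == "clip":
        for s in segments:
            np.clip(s.channel_data, -threshold_uV, threshold_uV, out=s.channel_data)
        kept = segments
    else:
        kept, _ = reject_artifacts(segments, threshold_uV)
    if len(kept) < n_segments:
        raise ShortageError(
            f"record {record.subject_id}: only {len(kept)} artifact-free "
            f"segments of {L_EEG} samples, {n_segments} required"
        )
    return kept[:n_segments]


def preprocess_cohort(records: Sequence[EEGRecord], **kwargs) -> list[Segment]:
    """Apply :func:`preprocess_record` to every record, concatenating segments."""
    out: list[Segment] = []
    for rec in records:
        out.extend(preprocess_record(rec, **kwargs))
    return out
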