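"""Assembly of per-segment feature matrices.

Each feature is one entropy value computed on one wavelet variant of one
channel of a segment; columns are named ``channel|variant|method|params``
(e.g. ``T8|cA3|FuzzyEn|m=1,r=0.15,r2=5``) so every number in the matrix is
traceable to its full parameterization.  The wavelet decomposition is applied
per segment (segment-local DWT), treating segments as independent
observations.  Column order is channels-major, variants-minor and fixed;
row order follows the input segment order.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyConfig
from .exceptions import (
    AssemblyError,
    DegenerateInputError,
    InvalidArgumentError,
)
from .preprocess import Segment
from .wavelets import VARIANT_ORDER, make_variants

__all__ = ["FeatureMatrix", "build_features", "select_columns"]


@dataclass
class FeatureMatrix:
    """Segments × named features, with class labels and subject groups."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    groups: np.ndarray
    segment_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        self.segment_index = np.asarray(self.segment_index, dtype=int)
        n, f = self.values.shape
        if len(self.feature_names) != f:
            raise InvalidArgumentError("feature_names length mismatch")
        if not (len(self.labels) == len(self.groups) == len(self.segment_index) == n):
            raise InvalidArgumentError("row metadata length mismatch")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df["subject"] = self.groups
        df["segment"] = self.segment_index
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = ["label", "subject", "segment"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"feature table lacks columns {missing}")
        names = [c for c in df.columns if c not in meta]
        return cls(
            values=df[names].to_numpy(dtype=np.float64),
            feature_names=names,
            labels=df["label"].to_numpy(),
            groups=df["subject"].to_numpy(),
            segment_index=df["segment"].to_numpy(dtype=int),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        return select_columns(self, names)


def build_features(
    segments: Sequence[Segment],
    config: EntropyConfig,
    channels: Sequence[str] | None = None,
    variants: Sequence[str] | None = None,
    wavelet_name: str = "db4",
    levels: int = 4,
) -> FeatureMatrix:
    """Compute the (channel × variant) feature block of ``config`` per segment.

    Fails loudly (``AssemblyError`` naming segment/channel/variant) on any
    degenerate or undefined entropy value — missing values are never imputed.
    """
    if not segments:
        raise InvalidArgumentError("no segments given")
    lengths = {s.L_EEG for s in segments}
    if len(lengths) != 1:
        raise InvalidArgumentError(f"segments have mixed lengths {sorted(lengths)}")
    all_channels = list(segments[0].channel_names)
    channels = list(channels) if channels is not None else all_channels
    variants = list(variants) if variants is not None else list(VARIANT_ORDER)
    if not channels or not variants:
        raise InvalidArgumentError("channels and variants must be non-empty")
    unknown = [c for c in channels if c not in all_channels]
    if unknown:
        raise InvalidArgumentError(f"unknown channels: {unknown}")
    unknown_v = [v for v in variants if v not in VARIANT_ORDER]
    if unknown_v:
        raise InvalidArgumentError(f"unknown variants: {unknown_v}")

    names = [f"{ch}|{var}|{config.label()}" for ch in channels for var in variants]
    values = np.empty((len(segments), len(names)))
    ch_idx = {c: i for i, c in enumerate(all_channels)}
    for si, seg in enumerate(segments):
        col = 0
        for ch in channels:
            vs = make_variants(seg.channel_data[ch_idx[ch]],
                               wavelet_name=wavelet_name, levels=levels)
            for var in variants:
                try:
                    val = config.compute(vs[var])
                except DegenerateInputError as exc:
                    raise AssemblyError(
                        f"degenerate input at subject={seg.subject_id} "
                        f"segment={seg.segment_index} channel={ch} variant={var}: {exc}"
                    ) from exc
                if math.isnan(val):
                    raise AssemblyError(
                        f"undefined entropy at subject={seg.subject_id} "
                        f"segment={seg.segment_index} channel={ch} variant={var}"
                    )
                values[si, col] = val
                col += 1
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=np.array([s.label for s in segments]),
        groups=np.array([s.subject_id for s in segments]),
        segment_index=np.array([s.segment_index for s in segments]),
    )


def select_columns(fm: FeatureMatrix, names: Sequence[str]) -> FeatureMatrix:
    """Column subset preserving row order, labels and groups."""
    names = list(names)
    if not names:
        raise InvalidArgumentError("names must be non-empty")
    index = {n: i for i, n in enumerate(fm.feature_names)}
    missing = [n for n in names if n not in index]
    if missing:
        hints = {
            n: difflib.get_close_matches(n, fm.feature_names, n=3)
            for n in missing
        }
        raise KeyError(f"unknown feature names {missing}; close matches: {hints}")
    cols = [index[n] for n in names]
    return FeatureMatrix(
        values=fm.values[:, cols].copy(),
        feature_names=names,
        labels=fm.labels.copy(),
        groups=fm.groups.copy(),
        segment_index=fm.segment_index.copy(),
    )
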