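"""Per-stride feature extraction and assembly of the 12 analysis datasets.

Seven features per kinematic channel per stride: four time-domain (mean,
standard deviation, maximum, minimum) and three autocorrelation-based
(height of the main autocorrelation peak, and height/lag of the second
peak).  The autocorrelation is the biased sample autocorrelation of the
mean-removed channel, so the main peak ``r(0)`` is the (biased) variance --
the within-stride signal power -- and the second peak captures within-stride
periodicity.  "Second peak" means the largest local maximum at lag >= 1 that
occurs after the first zero crossing of ``r``; for channels where no such
peak exists (e.g. zero variance), the three autocorrelation features are 0.

Datasets: 4 body segments (pelvis PL, thighs TH, shanks SH, feet FT) x 3
signal combinations (``a`` = accelerations, ``w`` = angular velocities,
``aw`` = both), with left and right strides of paired segments pooled as
separate rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InputError
from .segment import Stride
from .synthdata import CHANNELS

FEATURE_NAMES = (
    "mean",
    "sd",
    "max",
    "min",
    "acf_main",
    "acf_peak2_height",
    "acf_peak2_lag",
)

SEGMENT_CODES = {"pelvis": "PL", "thigh": "TH", "shank": "SH", "foot": "FT"}
COMBO_CHANNELS = {
    "a": tuple(c for c in CHANNELS if c.startswith("acc")),
    "w": tuple(c for c in CHANNELS if c.startswith("gyr")),
    "aw": CHANNELS,
}
META_COLUMNS = ("athlete_id", "repetition", "side", "condition")


def autocorr(sequence) -> np.ndarray:
    """Biased sample autocorrelation of the mean-removed sequence, lags 0..N-1."""
    x = np.asarray(sequence, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise InputError("autocorr needs a 1-D sequence of length >= 4")
    n = len(x)
    xc = x - x.mean()
    return np.correlate(xc, xc, mode="full")[n - 1 :] / n


def _second_peak(r: np.ndarray) -> tuple[float, int]:
    """Height and lag of the largest local maximum after the first zero crossing."""
    if r[0] <= 0:
        return 0.0, 0
    below = np.nonzero(r <= 0)[0]
    if below.size == 0:
        return 0.0, 0
    first_zero = below[0]
    peaks, _ = sps.find_peaks(r)
    peaks = peaks[peaks > first_zero]
    if peaks.size == 0:
        return 0.0, 0
    best = peaks[np.argmax(r[peaks])]
    return float(r[best]), int(best)


def extract_stride_features(channel, expected_length: int = 100) -> np.ndarray:
    """The 7 features of one channel, in FEATURE_NAMES order."""
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or len(x) != expected_length:
        raise InputError(f"expected a channel of length {expected_length}")
    r = autocorr(x)
    height, lag = _second_peak(r)
    return np.array(
        [x.mean(), x.std(), x.max(), x.min(), r[0], height, float(lag)]
    )


@dataclass
class FeatureMatrix:
    """n strides x f features for one (segment, combo) dataset."""

    segment: str  # PL / TH / SH / FT
    combo: str  # a / w / aw
    data: pd.DataFrame  # META_COLUMNS + feature columns

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data["condition"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def _stride_feature_row(stride: Stride) -> dict[str, float]:
    row: dict[str, float] = {}
    for chan, values in zip(stride.channel_names, stride.channels):
        feats = extract_stride_features(values, expected_length=stride.channels.shape[1])
        for name, value in zip(FEATURE_NAMES, feats):
            row[f"{chan}_{name}"] = float(value)
    return row


def _frame_from_strides(strides: list[Stride]) -> pd.DataFrame:
    rows = []
    for s in strides:
        row = {
            "athlete_id": s.athlete_id,
            "repetition": s.repetition,
            "side": s.side,
            "condition": s.condition,
        }
        row.update(_stride_feature_row(s))
        rows.append(row)
    return pd.DataFrame(rows)


def _combo_columns(combo: str) -> list[str]:
    return [f"{chan}_{feat}" for chan in COMBO_CHANNELS[combo] for feat in FEATURE_NAMES]


def assemble_dataset(strides: list[Stride], segment: str, combo: str) -> FeatureMatrix:
    """One FeatureMatrix for a segment (name or code) and signal combination."""
    seg_name = {v: k for k, v in SEGMENT_CODES.items()}.get(segment, segment)
    if seg_name not in SEGMENT_CODES:
        raise InputError(f"unknown segment {segment!r}")
    if combo not in COMBO_CHANNELS:
        raise InputError(f"unknown signal combination {combo!r}")
    selected = [s for s in strides if s.segment == seg_name]
    if not selected:
        raise InputError(f"no strides available for segment {seg_name!r}")
    selected.sort(key=lambda s: (s.side, s.start))
    frame = _frame_from_strides(selected)
    columns = list(META_COLUMNS) + _combo_columns(combo)
    return FeatureMatrix(
        segment=SEGMENT_CODES[seg_name], combo=combo, data=frame[columns]
    )


def build_datasets(strides: list[Stride]) -> dict[tuple[str, str], FeatureMatrix]:
    """All 12 (segment x combo) feature matrices of one athlete-repetition."""
    present = {s.segment for s in strides}
    missing = sorted(set(SEGMENT_CODES) - present)
    if missing:
        raise InputError(f"missing strides for segment(s): {missing}")
    # compute the full 42-feature frame once per segment, slice per combo
    datasets: dict[tuple[str, str], FeatureMatrix] = {}
    for seg_name, code in SEGMENT_CODES.items():
        selected = sorted(
            (s for s in strides if s.segment == seg_name),
            key=lambda s: (s.side, s.start),
        )
        frame = _frame_from_strides(selected)
        for combo in COMBO_CHANNELS:
            columns = list(META_COLUMNS) + _combo_columns(combo)
            datasets[(code, combo)] = FeatureMatrix(
                segment=code, combo=combo, data=frame[columns].copy()
            )
    return datasets
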