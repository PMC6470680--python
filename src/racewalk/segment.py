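"""Stride segmentation: heel strikes, partitioning, trimming, normalization.

Heel strikes are detected from the shank sagittal angular velocity with the
classic shank-gyro scheme: mid-swing is a prominent positive peak of the
sagittal angular velocity; the heel strike is the first negative local
minimum that follows it.  A stride is the interval between two consecutive
heel strikes of the same foot.  Strides spanning a condition transition are
discarded; the first and last three strides of each condition (per side) are
trimmed to let the athlete settle into the announced condition; finally all
conditions are truncated to the same stride count (keeping the earliest
strides, so the selection is deterministic) and each stride is
time-normalized to 100 samples by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InputError, InsufficientDataError
from .synthdata import CHANNELS, SAGITTAL_GYRO, SEGMENT_SIDES, SessionRecording

#: which foot defines the gait cycle of each sensor location (pelvis: left foot)
SIDE_OF_BLOCK = {
    (seg, side): ("left" if side == "center" else side) for seg, side in SEGMENT_SIDES
}

StrideInterval = tuple[int, int, str]  # (start, end, condition), half-open


@dataclass
class Stride:
    """One time-normalized gait cycle of one segment/side."""

    athlete_id: str
    repetition: int
    segment: str
    side: str
    condition: str
    start: int
    end: int
    channels: np.ndarray  # (6, n_samples) in CHANNELS order
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError("stride end must exceed start")


def _dominant_period(x: np.ndarray, sampling_rate: float) -> float | None:
    """Cycle length in samples from the autocorrelation peak (FFT-based)."""
    n = len(x)
    lo = max(2, int(round(0.3 * sampling_rate)))
    hi = min(n // 2, int(round(3.0 * sampling_rate)))
    if hi <= lo:
        return None
    xc = x - x.mean()
    spectrum = np.abs(np.fft.rfft(xc, n=2 * n)) ** 2
    r = np.fft.irfft(spectrum)[:n]
    lag = lo + int(np.argmax(r[lo:hi]))
    return float(lag)


def detect_heel_strikes(shank_sagittal_gyro, sampling_rate: float) -> np.ndarray:
    """Heel-strike sample indices from (filtered) shank sagittal angular velocity.

    Mid-swing is the dominant positive peak per cycle (prominence threshold,
    minimum peak distance 0.7x the autocorrelation-estimated cycle length);
    each heel strike is the first negative local minimum after a mid-swing
    peak (falling back to the global minimum of the search window when the
    window is truncated at the signal end).
    """
    x = np.asarray(shank_sagittal_gyro, dtype=float)
    if x.ndim != 1:
        raise InputError("expected a 1-D angular-velocity channel")
    if x.size < 4 or np.ptp(x) < 1e-9:
        return np.asarray([], dtype=int)

    prominence = 0.25 * (np.percentile(x, 98) - np.percentile(x, 50))
    if prominence <= 0:
        return np.asarray([], dtype=int)
    period = _dominant_period(x, sampling_rate)
    min_dist = (
        max(1, int(round(0.7 * period)))
        if period is not None
        else max(1, int(round(0.3 * sampling_rate)))
    )
    peaks, _ = sps.find_peaks(x, prominence=prominence, distance=min_dist)
    if peaks.size == 0:
        return np.asarray([], dtype=int)
    median_cycle = (
        float(np.median(np.diff(peaks))) if peaks.size > 1 else 1.2 * sampling_rate
    )

    heel_strikes: list[int] = []
    for j, p in enumerate(peaks):
        stop = peaks[j + 1] if j + 1 < len(peaks) else min(
            len(x), p + int(round(1.2 * median_cycle))
        )
        window = x[p:stop]
        if window.size < 3:
            continue
        minima, _ = sps.find_peaks(-window)
        minima = [m for m in minima if window[m] < 0]
        if minima:
            heel_strikes.append(int(p + minima[0]))
        elif stop == len(x) and window[-1] < 0 and window[-1] == window.min():
            # descending tail truncated by the end of the recording
            heel_strikes.append(int(stop - 1))
    return np.unique(np.asarray(heel_strikes, dtype=int))


def partition_strides(
    recording: SessionRecording,
    sample_labels: np.ndarray,
    heel_strikes: dict[str, np.ndarray],
) -> dict[str, list[StrideInterval]]:
    """Label strides between consecutive same-foot heel strikes.

    A stride whose samples are not covered by a single condition span (i.e.
    it straddles a transition) is discarded.
    """
    n = recording.n_samples
    if len(sample_labels) != n:
        raise InputError("sample_labels length must match the recording")
    out: dict[str, list[StrideInterval]] = {}
    for side, events in heel_strikes.items():
        events = np.asarray(events, dtype=int)
        if np.any(np.diff(events) <= 0):
            raise InputError(f"heel strikes for side {side!r} must be sorted")
        intervals: list[StrideInterval] = []
        for start, end in zip(events[:-1], events[1:]):
            if start < 0 or end > n:
                continue
            labels = sample_labels[start:end]
            uniq = set(labels.tolist())
            if len(uniq) != 1:
                continue  # spans a transition
            intervals.append((int(start), int(end), uniq.pop()))
        out[side] = intervals
    return out


def trim_and_balance(
    intervals_by_side: dict[str, list[StrideInterval]],
    n_trim: int = 3,
) -> dict[str, list[StrideInterval]]:
    """Drop the first/last ``n_trim`` strides per condition (per side), then
    truncate every condition to the minimum remaining count (earliest kept)."""
    balanced: dict[str, list[StrideInterval]] = {}
    for side, intervals in intervals_by_side.items():
        by_cond: dict[str, list[StrideInterval]] = {}
        for interval in sorted(intervals, key=lambda iv: iv[0]):
            by_cond.setdefault(interval[2], []).append(interval)
        for cond, items in by_cond.items():
            if len(items) <= 2 * n_trim:
                raise InsufficientDataError(
                    f"condition {cond!r} (side {side!r}) has only {len(items)} "
                    f"strides; need more than {2 * n_trim}"
                )
        trimmed = {c: items[n_trim:-n_trim] for c, items in by_cond.items()}
        keep = min(len(items) for items in trimmed.values())
        selected = [items[:keep] for items in trimmed.values()]
        merged = sorted((iv for items in selected for iv in items), key=lambda iv: iv[0])
        balanced[side] = merged
    return balanced


def resample_stride(raw_channels, target: int = 100) -> np.ndarray:
    """Time-normalize stride channels to ``target`` samples (linear interpolation).

    Accepts a 1-D sequence or a (channels, length) array; first and last
    samples are preserved exactly.
    """
    arr = np.asarray(raw_channels, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise InputError("stride must contain at least 2 samples")
    old = np.arange(arr.shape[1], dtype=float)
    new = np.linspace(0.0, arr.shape[1] - 1.0, target)
    out = np.vstack([np.interp(new, old, row) for row in arr])
    return out[0] if squeeze else out


def extract_strides(
    recording: SessionRecording,
    intervals_by_side: dict[str, list[StrideInterval]],
    target: int = 100,
) -> list[Stride]:
    """Cut every segment block into time-normalized strides of its side."""
    strides: list[Stride] = []
    for segment, side in SEGMENT_SIDES:
        foot = SIDE_OF_BLOCK[(segment, side)]
        for start, end, cond in intervals_by_side.get(foot, []):
            raw = np.vstack(
                [
                    recording.segment_channel(segment, side, chan)[start:end]
                    for chan in CHANNELS
                ]
            )
            strides.append(
                Stride(
                    athlete_id=recording.athlete_id,
                    repetition=recording.repetition,
                    segment=segment,
                    side=side,
                    condition=cond,
                    start=start,
                    end=end,
                    channels=resample_stride(raw, target=target),
                )
            )
    return strides


def segment_recording(
    recording: SessionRecording,
    sample_labels: np.ndarray,
    target: int = 100,
    n_trim: int = 3,
) -> list[Stride]:
    """Full segmentation of one filtered, labelled recording."""
    heel_strikes = {
        side: detect_heel_strikes(
            recording.segment_channel("shank", side, SAGITTAL_GYRO),
            recording.sampling_rate,
        )
        for side in ("left", "right")
    }
    raw = partition_strides(recording, sample_labels, heel_strikes)
    balanced = trim_and_balance(raw, n_trim=n_trim)
    return extract_strides(recording, balanced, target=target)
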