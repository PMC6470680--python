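"""Filtering, coach-channel transition detection, and sample labelling.

All kinematic channels are low-pass filtered with a net fourth-order
Butterworth response at 20 Hz cutoff.  The filter is applied forward and
backward (a half-order design run twice), so it is zero-phase: gait events
keep their timing, and the net magnitude at the cutoff is -3 dB.

The coach channel is a +/-g square-ish wave whose sign flips at each
condition transition; transitions are detected as debounced sign changes of
the filtered signal and turned into the reference sequence ``S_ref`` used to
label every sample with its race-walking condition.  Spans are half-open
``[start, next_start)`` with 0-based sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DetectionError, InputError, ParameterError
from .synthdata import SessionRecording


@dataclass(frozen=True)
class ReferenceSequence:
    """Ordered condition spans: ``len(labels) == len(transitions) + 1``."""

    transitions: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.transitions) + 1:
            raise InputError("need exactly one more label than transitions")
        t = np.asarray(self.transitions)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise InputError("transitions must be strictly increasing and >= 0")


def lowpass_filter(
    channel, sampling_rate: float, cutoff: float = 20.0, order: int = 4
):
    """Zero-phase low-pass Butterworth filter (net order ``order``)."""
    if cutoff >= sampling_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {sampling_rate / 2} Hz"
        )
    if order < 2 or order % 2:
        raise ParameterError("order must be an even integer >= 2")
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise InputError("expected a 1-D channel")
    if len(x) <= 3 * order:
        raise InputError(f"channel too short to filter (need > {3 * order} samples)")
    # half order per pass: forward-backward application doubles the order
    sos = sps.butter(order // 2, cutoff, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_transitions(
    coach_channel,
    sampling_rate: float = 60.0,
    cutoff: float = 20.0,
    debounce_s: float = 0.5,
) -> np.ndarray:
    """Sample indices where the coach signal flips sign and holds it.

    The channel is filtered with the same low-pass filter as the kinematic
    channels; a sign change only counts if the new sign persists for the
    debounce window (default 0.5 s).
    """
    window = max(1, int(round(debounce_s * sampling_rate)))
    x = np.asarray(coach_channel, dtype=float)
    if len(x) < window:
        raise InputError("coach channel shorter than the debounce window")
    x = lowpass_filter(x, sampling_rate, cutoff=cutoff)
    if np.max(np.abs(x)) < 1e-8:
        raise DetectionError("coach channel carries no gravity component")

    sign = np.sign(x)
    # zeros inherit the previous sign so they cannot split a span
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    if sign[0] == 0:
        first = np.nonzero(sign)[0]
        if first.size == 0:
            raise DetectionError("coach channel carries no gravity component")
        sign[0] = sign[first[0]]

    transitions = []
    current = sign[0]
    change_points = np.nonzero(np.diff(sign))[0] + 1
    for i in change_points:
        if sign[i] == current:
            continue
        tail = sign[i : i + window]
        if np.all(tail == sign[i]):
            transitions.append(int(i))
            current = sign[i]
    return np.asarray(transitions, dtype=int)


def build_reference_sequence(transitions, condition_order) -> ReferenceSequence:
    """Pair detected transitions with the announced lap order."""
    transitions = tuple(int(t) for t in np.asarray(transitions, dtype=int))
    condition_order = tuple(condition_order)
    if len(condition_order) != len(transitions) + 1:
        raise InputError(
            f"{len(transitions)} transitions require {len(transitions) + 1} "
            f"condition labels, got {len(condition_order)}"
        )
    return ReferenceSequence(transitions=transitions, labels=condition_order)


def label_samples(recording: SessionRecording | int, sref: ReferenceSequence) -> np.ndarray:
    """Condition label per sample; spans are half-open ``[start, next_start)``."""
    n = recording if isinstance(recording, (int, np.integer)) else recording.n_samples
    t = np.asarray(sref.transitions)
    if t.size and t[-1] >= n:
        raise InputError("reference-sequence transitions fall outside the recording")
    span = np.searchsorted(t, np.arange(n), side="right")
    return np.asarray(sref.labels, dtype=object)[span]


def filter_recording(
    recording: SessionRecording, cutoff: float = 20.0, order: int = 4
) -> SessionRecording:
    """Return a copy of the recording with every kinematic channel filtered."""
    channels = {
        key: lowpass_filter(x, recording.sampling_rate, cutoff=cutoff, order=order)
        for key, x in recording.channels.items()
    }
    return SessionRecording(
        athlete_id=recording.athlete_id,
        repetition=recording.repetition,
        sampling_rate=recording.sampling_rate,
        channels=channels,
        coach=recording.coach.copy(),
    )
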