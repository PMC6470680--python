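"""Plain-text readers/writers for every pipeline artifact.

Sessions are delimited tables, one row per sample: ``time_s``, the 42
kinematic channels named ``<segment>_<side>_<acc|gyr>_<x|y|z>``, and
``coach_acc_v``; ground truth travels in a JSON sidecar.  Stride sets,
feature matrices and result records are CSV tables with headers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ResultRecord
from .errors import FormatError
from .features import META_COLUMNS, FeatureMatrix
from .segment import Stride
from .synthdata import (
    ALL_CHANNEL_KEYS,
    CHANNELS,
    GroundTruth,
    SessionRecording,
)

COACH_COLUMN = "coach_acc_v"


# -- sessions ---------------------------------------------------------------

def write_session(path, recording: SessionRecording, labels=None) -> None:
    t = np.arange(recording.n_samples) / recording.sampling_rate
    data = {"time_s": t}
    for key in ALL_CHANNEL_KEYS:
        data[key] = recording.channels[key]
    data[COACH_COLUMN] = recording.coach
    frame = pd.DataFrame(data)
    if labels is not None:
        frame["condition"] = labels
    frame.to_csv(path, index=False, float_format="%.17g")


def read_session(
    path, athlete_id: str = "unknown", repetition: int = 1
) -> tuple[SessionRecording, np.ndarray | None]:
    """Read a session table; returns (recording, labels-or-None)."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse session table {path}: {exc}") from exc
    missing = [c for c in ("time_s", *ALL_CHANNEL_KEYS, COACH_COLUMN) if c not in frame]
    if missing:
        raise FormatError(f"session table {path} lacks column(s): {missing}")
    known = {"time_s", *ALL_CHANNEL_KEYS, COACH_COLUMN, "condition"}
    extra = [c for c in frame.columns if c not in known]
    if extra:
        warnings.warn(f"ignoring unknown session column(s): {extra}", stacklevel=2)
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"session table {path} holds fewer than 2 samples")
    sampling_rate = 1.0 / float(np.median(np.diff(t)))
    recording = SessionRecording(
        athlete_id=athlete_id,
        repetition=repetition,
        sampling_rate=sampling_rate,
        channels={k: frame[k].to_numpy(dtype=float) for k in ALL_CHANNEL_KEYS},
        coach=frame[COACH_COLUMN].to_numpy(dtype=float),
    )
    labels = frame["condition"].to_numpy(dtype=object) if "condition" in frame else None
    return recording, labels


# -- ground truth sidecar ---------------------------------------------------

def write_ground_truth(path, truth: GroundTruth, athlete_id: str, repetition: int) -> None:
    payload = {
        "athlete_id": athlete_id,
        "repetition": repetition,
        "sampling_rate": truth.sampling_rate,
        "n_samples": truth.n_samples,
        "conditions": list(truth.conditions),
        "transitions": [int(v) for v in truth.transitions],
        "heel_strikes": {
            side: [int(v) for v in idx] for side, idx in truth.heel_strikes.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        transitions=np.asarray(payload["transitions"], dtype=int),
        conditions=tuple(payload["conditions"]),
        heel_strikes={
            side: np.asarray(idx, dtype=int)
            for side, idx in payload["heel_strikes"].items()
        },
        n_samples=int(payload["n_samples"]),
        sampling_rate=float(payload["sampling_rate"]),
    )


# -- stride sets ------------------------------------------------------------

def write_strides(path, strides: list[Stride]) -> None:
    rows = []
    for s in strides:
        row = {
            "athlete_id": s.athlete_id,
            "repetition": s.repetition,
            "segment": s.segment,
            "side": s.side,
            "condition": s.condition,
            "start": s.start,
            "end": s.end,
        }
        for chan, values in zip(s.channel_names, s.channels):
            for i, v in enumerate(values):
                row[f"{chan}_{i:03d}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_strides(path) -> list[Stride]:
    frame = pd.read_csv(path, float_precision="round_trip")
    meta = ["athlete_id", "repetition", "segment", "side", "condition", "start", "end"]
    missing = [c for c in meta if c not in frame]
    if missing:
        raise FormatError(f"stride table {path} lacks column(s): {missing}")
    n_samples = sum(c.startswith(f"{CHANNELS[0]}_") for c in frame.columns)
    strides = []
    for _, row in frame.iterrows():
        channels = np.vstack(
            [
                [row[f"{chan}_{i:03d}"] for i in range(n_samples)]
                for chan in CHANNELS
            ]
        )
        strides.append(
            Stride(
                athlete_id=row["athlete_id"],
                repetition=int(row["repetition"]),
                segment=row["segment"],
                side=row["side"],
                condition=row["condition"],
                start=int(row["start"]),
                end=int(row["end"]),
                channels=channels,
            )
        )
    return strides


# -- feature matrices -------------------------------------------------------

def feature_path(directory, segment: str, combo: str) -> Path:
    return Path(directory) / f"features_{segment}_{combo}.csv"


def write_datasets(directory, datasets: dict[tuple[str, str], FeatureMatrix]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (segment, combo), fm in datasets.items():
        fm.data.to_csv(
            feature_path(directory, segment, combo), index=False, float_format="%.17g"
        )


def read_dataset(path, segment: str, combo: str) -> FeatureMatrix:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in frame]
    if missing:
        raise FormatError(f"feature table {path} lacks column(s): {missing}")
    return FeatureMatrix(segment=segment, combo=combo, data=frame)


# -- result records ---------------------------------------------------------

def write_records(path, records: list[ResultRecord]) -> None:
    rows = []
    for rec in records:
        row = {
            "athlete_id": rec.athlete_id,
            "name": rec.name,
            "classifier": rec.classifier,
            "segment": rec.segment,
            "combo": rec.combo,
        }
        for i in range(3):
            for j in range(3):
                row[f"cm_{i + 1}{j + 1}"] = rec.cm[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_records(path) -> list[ResultRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    needed = ["athlete_id", "classifier", "segment", "combo"] + [
        f"cm_{i + 1}{j + 1}" for i in range(3) for j in range(3)
    ]
    missing = [c for c in needed if c not in frame]
    if missing:
        raise FormatError(f"results table {path} lacks column(s): {missing}")
    records = []
    for _, row in frame.iterrows():
        cm = np.array(
            [[row[f"cm_{i + 1}{j + 1}"] for j in range(3)] for i in range(3)],
            dtype=float,
        )
        records.append(
            ResultRecord(
                athlete_id=row["athlete_id"],
                classifier=row["classifier"],
                segment=row["segment"],
                combo=row["combo"],
                cm=cm,
            )
        )
    return records
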