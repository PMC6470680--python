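"""End-to-end orchestration: simulate -> label -> segment -> featurize ->
classify -> funnel, with every intermediate artifact written as plain text.

A run is fully described by a :class:`RunConfig`; identical configs produce
identical artifacts (one master seed is split into per-stage, per-athlete
sub-seeds inside the generator and the classifier bank).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rwio
from .classify import ResultRecord, run_bank
from .errors import ConfigurationError, InputError
from .evaluate import aggregate, binary_report, records_to_frame, selection_funnel
from .features import FeatureMatrix, build_datasets
from .preprocess import (
    build_reference_sequence,
    detect_transitions,
    filter_recording,
    label_samples,
)
from .segment import Stride, segment_recording
from .synthdata import GeneratorConfig, NoiseConfig, SessionRecording, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cutoff: float = 20.0
    filter_order: int = 4
    target_samples: int = 100
    n_trim: int = 3
    thresholds: tuple[float, float, float, float] = (0.80, 0.80, 0.80, 0.80)
    classifier_seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload or {})
        gen = dict(payload.pop("generator", {}))
        if "noise_sd" in gen and isinstance(gen["noise_sd"], dict):
            gen["noise_sd"] = NoiseConfig(**gen["noise_sd"])
        if "conditions_order" in gen:
            gen["conditions_order"] = tuple(gen["conditions_order"])
        if "thresholds" in payload:
            payload["thresholds"] = tuple(payload["thresholds"])
        try:
            return cls(generator=GeneratorConfig(**gen), **payload)
        except TypeError as exc:
            raise ConfigurationError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self, generator=replace(self.generator, seed=seed), classifier_seed=seed
        )


def label_recording(recording: SessionRecording, config: RunConfig) -> np.ndarray:
    """Per-sample condition labels from the coach channel and the lap order."""
    order = config.generator.conditions_order
    transitions = detect_transitions(
        recording.coach, recording.sampling_rate, cutoff=config.cutoff
    )
    if len(transitions) != len(order) - 1:
        raise InputError(
            f"detected {len(transitions)} transitions for athlete "
            f"{recording.athlete_id!r} rep {recording.repetition}, expected "
            f"{len(order) - 1}"
        )
    sref = build_reference_sequence(transitions, order)
    return label_samples(recording, sref)


def session_to_strides(recording: SessionRecording, config: RunConfig) -> list[Stride]:
    """Filter, label and segment one session."""
    filtered = filter_recording(
        recording, cutoff=config.cutoff, order=config.filter_order
    )
    labels = label_recording(filtered, config)
    return segment_recording(
        filtered, labels, target=config.target_samples, n_trim=config.n_trim
    )


def session_to_datasets(
    recording: SessionRecording, config: RunConfig
) -> dict[tuple[str, str], FeatureMatrix]:
    return build_datasets(session_to_strides(recording, config))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Full reproducible run; returns the result tables and writes artifacts."""
    if config.generator.n_repetitions != 2:
        raise ConfigurationError(
            "the repetition-wise cross-validation requires exactly 2 repetitions"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    cohort = generate_cohort(config.generator)
    datasets_by_athlete: dict[str, dict[int, dict]] = {}
    for (athlete_id, rep), (recording, truth) in sorted(cohort.items()):
        session_dir = out / athlete_id / f"rep{rep}"
        session_dir.mkdir(parents=True, exist_ok=True)
        rwio.write_session(session_dir / "session.csv", recording)
        rwio.write_ground_truth(
            session_dir / "ground_truth.json", truth, athlete_id, rep
        )
        strides = session_to_strides(recording, config)
        rwio.write_strides(session_dir / "strides.csv", strides)
        datasets = build_datasets(strides)
        rwio.write_datasets(session_dir, datasets)
        datasets_by_athlete.setdefault(athlete_id, {})[rep] = datasets

    records: list[ResultRecord] = []
    for athlete_id in sorted(datasets_by_athlete):
        reps = datasets_by_athlete[athlete_id]
        records.extend(
            run_bank(reps[1], reps[2], athlete_id, seed=config.classifier_seed)
        )
    rwio.write_records(out / "results.csv", records)

    metrics = records_to_frame(records)
    metrics.to_csv(out / "metrics_per_athlete.csv", index=False)
    aggregated = aggregate(metrics)
    aggregated.to_csv(out / "metrics_aggregated.csv")
    funnel = selection_funnel(aggregated, thresholds=config.thresholds)
    funnel.to_csv(out / "funnel.csv")
    survivors = funnel.index[funnel["survivor"]].tolist()
    binary = binary_report(records, names=set(survivors))
    binary.to_csv(out / "binary_models.csv")

    return {
        "records": records,
        "metrics": metrics,
        "aggregated": aggregated,
        "funnel": funnel,
        "binary": binary,
    }


def funnel_from_results(results_path, thresholds=(0.80,) * 4) -> pd.DataFrame:
    """Re-run aggregation + funnel from a saved results table."""
    records = rwio.read_records(results_path)
    return selection_funnel(aggregate(records), thresholds=thresholds)
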