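import pytest

from racewalk.features import build_datasets
from racewalk.pipeline import RunConfig, session_to_strides
from racewalk.synthdata import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """A small but fully structured cohort: 2 athletes x 2 reps x 20 strides."""
    return GeneratorConfig(
        n_athletes=2, n_repetitions=2, strides_per_condition=20, seed=42
    )


@pytest.fixture(scope="session")
def tiny_run_config(tiny_config) -> RunConfig:
    return RunConfig(generator=tiny_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_datasets(tiny_cohort, tiny_run_config):
    """{athlete_id: {rep: {(segment, combo): FeatureMatrix}}} for the tiny cohort."""
    out = {}
    for (athlete_id, rep), (recording, _) in sorted(tiny_cohort.items()):
        strides = session_to_strides(recording, tiny_run_config)
        out.setdefault(athlete_id, {})[rep] = build_datasets(strides)
    return out
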