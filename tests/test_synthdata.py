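"""Generator contracts: determinism, class-separation scaling, protocol shape."""

import dataclasses

import numpy as np
import pytest

from racewalk.errors import ConfigurationError, InputError
from racewalk.synthdata import (
    ALL_CHANNEL_KEYS,
    GRAVITY,
    GeneratorConfig,
    NoiseConfig,
    evaluate_template,
    generate_cohort,
    make_profile,
    synthesize_coach_channel,
    synthesize_session,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_athletes": 0},
        {"strides_per_condition": 0},
        {"class_separation": -1.0},
        {"stride_duration_mean": 0.0},
        {"sampling_rate": -60.0},
        {"conditions_order": ("regular", "regular")},
        {"conditions_order": ("walking",)},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        GeneratorConfig(**kwargs)


def test_profile_determinism():
    config = GeneratorConfig(n_athletes=2, seed=9)
    a = make_profile(config, 1)
    b = make_profile(config, 1)
    assert a.stride_duration_mean == b.stride_duration_mean
    for key in a.templates:
        assert np.array_equal(a.templates[key], b.templates[key])


def test_zero_separation_collapses_conditions():
    config = GeneratorConfig(n_athletes=1, class_separation=0.0, seed=3)
    profile = make_profile(config, 0)
    for coeffs in profile.templates.values():
        assert np.array_equal(coeffs[0], coeffs[1])
        assert np.array_equal(coeffs[0], coeffs[2])


def test_separation_scales_linearly():
    base = GeneratorConfig(n_athletes=1, class_separation=1.0, seed=5)
    doubled = dataclasses.replace(base, class_separation=2.0)
    p1 = make_profile(base, 0)
    p2 = make_profile(doubled, 0)
    key = ("shank", "left", "acc_z")
    d1 = np.linalg.norm(p1.templates[key][0] - p1.templates[key][1])
    d2 = np.linalg.norm(p2.templates[key][0] - p2.templates[key][1])
    assert d1 > 0
    assert d2 / d1 == pytest.approx(2.0, rel=1e-9)


def test_shank_template_has_dominant_midswing_peak():
    """One dominant positive peak flanked by negative dips, so shank-gyro
    heel-strike detection is well-posed."""
    config = GeneratorConfig(n_athletes=1, seed=0)
    profile = make_profile(config, 0)
    phi = np.linspace(0, 1, 400, endpoint=False)
    for cond_row in range(3):
        y = evaluate_template(
            profile.templates[("shank", "left", "gyr_y")][cond_row], phi
        )
        peak_phase = phi[np.argmax(y)]
        assert 0.6 < peak_phase < 0.95
        assert y.max() > 0 > y.min()
        # negative dip at the heel strike (cycle boundary)
        assert y[0] < 0.2 * y.min() or y[0] < 0


def test_session_structure_and_counts():
    config = GeneratorConfig(n_athletes=1, strides_per_condition=25, seed=7)
    profile = make_profile(config, 0)
    recording, truth = synthesize_session(profile, 1, config)
    recording.validate()
    assert set(recording.channels) == set(ALL_CHANNEL_KEYS)
    assert len(ALL_CHANNEL_KEYS) == 42
    assert len(truth.transitions) == 2
    # one block per condition, n stride-start events per side per condition
    for side in ("left", "right"):
        events = truth.heel_strikes[side]
        assert np.all(np.diff(events) > 0)
        labels = truth.condition_at(events)
        for cond in config.conditions_order:
            assert np.sum(labels == cond) == 25
    expected = 3 * 25 * profile.stride_duration_mean * config.sampling_rate
    assert recording.n_samples == pytest.approx(expected, rel=0.05)


def test_noise_free_strides_repeat_exactly_up_to_duration_jitter():
    config = GeneratorConfig(
        n_athletes=1,
        strides_per_condition=5,
        stride_duration_cv=0.0,
        noise_sd=NoiseConfig(acc=0.0, gyr=0.0),
        seed=1,
    )
    profile = make_profile(config, 0)
    recording, truth = synthesize_session(profile, 1, config)
    hs = truth.heel_strikes["left"]
    x = recording.channels["shank_left_gyr_y"]
    # with no jitter and no noise, the first block is exactly the periodic
    # template sampled at phase (t / stride_duration)
    n = hs[4]  # stay inside the first (regular) condition block
    cycle = np.arange(n) / config.sampling_rate / profile.stride_duration_mean
    expected = evaluate_template(
        profile.templates[("shank", "left", "gyr_y")][0], cycle
    )
    assert np.allclose(x[:n], expected, atol=1e-9)


def test_repetitions_share_counts_but_not_noise():
    config = GeneratorConfig(n_athletes=1, strides_per_condition=10, seed=2)
    profile = make_profile(config, 0)
    rec1, t1 = synthesize_session(profile, 1, config)
    rec2, t2 = synthesize_session(profile, 2, config)
    assert len(t1.heel_strikes["left"]) == len(t2.heel_strikes["left"])
    assert not np.array_equal(rec1.channels["pelvis_center_acc_z"][:100],
                              rec2.channels["pelvis_center_acc_z"][:100])


def test_coach_channel_sign_pattern():
    clean = synthesize_coach_channel([500], 1000, 0.0)
    assert np.all(clean[:500] == GRAVITY)
    assert np.all(clean[500:] == -GRAVITY)
    constant = synthesize_coach_channel([], 100, 0.0)
    assert np.all(constant == GRAVITY)
    double = synthesize_coach_channel([300, 600], 900, 0.0)
    assert np.all(double[:300] == GRAVITY)
    assert np.all(double[300:600] == -GRAVITY)
    assert np.all(double[600:] == GRAVITY)
    with pytest.raises(InputError):
        synthesize_coach_channel([600, 300], 900, 0.0)
    with pytest.raises(InputError):
        synthesize_coach_channel([900], 900, 0.0)


def test_cohort_size_and_determinism(tiny_config, tiny_cohort):
    assert len(tiny_cohort) == tiny_config.n_athletes * tiny_config.n_repetitions
    single = generate_cohort(GeneratorConfig(n_athletes=1, n_repetitions=1, seed=0))
    assert len(single) == 1
    again = generate_cohort(tiny_config)
    key = sorted(tiny_cohort)[0]
    a, b = tiny_cohort[key][0], again[key][0]
    for chan in a.channels:
        assert np.array_equal(a.channels[chan], b.channels[chan])
    assert np.array_equal(a.coach, b.coach)
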