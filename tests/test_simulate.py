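"""The virtual-observer generator: determinism, noiseless closure, the
law-of-large-numbers structure, anisotropy, and config validation."""

import math

import numpy as np
import pandas as pd
import pydantic
import pytest

from memcolour import (
    GeneratorConfig,
    StimulusSpec,
    default_stimuli,
    generate_dataset,
    ground_truth_effect,
)


def one_stimulus_config(**overrides):
    params = dict(
        stimuli=[StimulusSpec(stimulus_id="banana", hue_angle=1.5,
                              prior_mean=0.2, prior_sd=0.1)],
        n_observers=3,
        n_repeats=5,
        seed=42,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def test_same_config_same_tables(small_dataset):
    config, data, truth = small_dataset
    data2, truth2 = generate_dataset(config)
    pd.testing.assert_frame_equal(data, data2)
    pd.testing.assert_frame_equal(truth, truth2)


def test_different_seed_different_tables(small_dataset):
    config, data, _ = small_dataset
    data2, _ = generate_dataset(config.model_copy(update={"seed": config.seed + 1}))
    assert not data["chroma_x"].equals(data2["chroma_x"])


def test_noiseless_closure_exact_positions():
    """With all SDs zero and lambda = 1, typicals sit exactly at the prior
    mean and grey-object adjustments exactly at the negated posterior
    shift with M = P."""
    spec = StimulusSpec(stimulus_id="s", hue_angle=0.7, prior_mean=0.25,
                        prior_sd=0.0)
    config = GeneratorConfig(stimuli=[spec], n_observers=2, n_repeats=3,
                             signal_sd_axis=0.0, signal_sd_ortho=0.0, seed=1)
    data, truth = generate_dataset(config)
    u = np.array([math.cos(0.7), math.sin(0.7)])
    typ = data[data["task"] == "typical"][["chroma_x", "chroma_y"]].to_numpy()
    np.testing.assert_allclose(typ - 0.25 * u, 0.0, atol=1e-15)
    grey = data[(data["task"] == "grey") & (data["condition"] != "disk")]
    np.testing.assert_allclose(
        grey[["chroma_x", "chroma_y"]].to_numpy() + 0.25 * u, 0.0, atol=1e-15
    )
    assert (truth["posterior_mean"] == 0.25).all()


def test_generator_moments_match_design(rng):
    """Projected typicals have the configured mean, and the variance of
    per-observer means realises prior_sd^2 / n_repeats."""
    config = one_stimulus_config(n_observers=3000, n_repeats=5, seed=11)
    data, _ = generate_dataset(config)
    spec = config.stimuli[0]
    u = np.array([math.cos(spec.hue_angle), math.sin(spec.hue_angle)])
    typ = data[data["task"] == "typical"]
    proj = typ[["chroma_x", "chroma_y"]].to_numpy() @ u
    n = len(proj)
    assert proj.mean() == pytest.approx(
        spec.prior_mean, abs=3 * spec.prior_sd / math.sqrt(n)
    )
    obs_means = (
        typ.assign(proj=proj).groupby("observer_id")["proj"].mean().to_numpy()
    )
    assert obs_means.var(ddof=1) == pytest.approx(
        spec.prior_sd**2 / config.n_repeats, rel=0.10
    )


@pytest.mark.parametrize(
    "prior_mean, prior_sd, signal_sd, lam, expected",
    [
        (0.2, 0.2, 0.1, 1.0, 0.04),   # w1 = 0.2 -> effect 0.04
        (0.2, 0.2, 0.1, 0.0, 0.0),    # no-effect stimulus
        (0.2, 0.0, 0.1, 1.0, 0.2),    # certain prior -> full prior mean
        (0.3, 0.0, 0.0, 1.0, 0.3),    # double-degenerate analytic limit
    ],
)
def test_ground_truth_effect_closed_form(prior_mean, prior_sd, signal_sd, lam,
                                         expected):
    spec = StimulusSpec(stimulus_id="s", hue_angle=1.0, prior_mean=prior_mean,
                        prior_sd=prior_sd, effect_adherence=lam)
    config = GeneratorConfig(stimuli=[spec], signal_sd_axis=signal_sd,
                             signal_sd_ortho=signal_sd)
    assert ground_truth_effect(spec, config) == pytest.approx(expected)


def test_daylight_anisotropy_boosts_on_axis_effects():
    """With grey-setting variance largest along the daylight locus, a
    stimulus whose hue lies on that locus gets a larger memory colour
    effect than a matched stimulus orthogonal to it."""
    daylight = math.pi / 2
    on_axis = StimulusSpec(stimulus_id="on", hue_angle=daylight,
                           prior_mean=0.2, prior_sd=0.1)
    off_axis = StimulusSpec(stimulus_id="off", hue_angle=daylight - math.pi / 2,
                            prior_mean=0.2, prior_sd=0.1)
    config = GeneratorConfig(stimuli=[on_axis, off_axis], n_observers=300,
                             n_repeats=5, signal_sd_axis=0.08,
                             signal_sd_ortho=0.02, daylight_angle=daylight,
                             seed=3)
    assert ground_truth_effect(on_axis, config) > ground_truth_effect(off_axis, config)
    data, _ = generate_dataset(config)
    grey = data[(data["task"] == "grey") & (data["condition"] != "disk")]

    def mean_effect(stim, u):
        sub = grey[grey["stimulus_id"] == stim]
        return -(sub[["chroma_x", "chroma_y"]].to_numpy() @ u).mean()

    u_on = np.array([math.cos(daylight), math.sin(daylight)])
    u_off = np.array([math.cos(daylight - math.pi / 2),
                      math.sin(daylight - math.pi / 2)])
    assert mean_effect("on", u_on) > mean_effect("off", u_off)


def test_response_noise_inflates_variance():
    quiet = one_stimulus_config(n_observers=200, seed=5)
    noisy = one_stimulus_config(n_observers=200, seed=5, response_noise_sd=0.1)
    dq, _ = generate_dataset(quiet)
    dn, _ = generate_dataset(noisy)
    vq = dq[dq["condition"] == "disk"]["chroma_x"].var()
    vn = dn[dn["condition"] == "disk"]["chroma_x"].var()
    assert vn > vq


def test_observer_heterogeneity_spreads_variances():
    homog = one_stimulus_config(n_observers=300, seed=6)
    heter = one_stimulus_config(n_observers=300, seed=6, observer_sd_scale=0.6)
    per_obs_var = lambda d: (
        d[d["condition"] == "disk"].groupby("observer_id")["chroma_x"].var()
    )
    assert per_obs_var(generate_dataset(heter)[0]).std() > \
        per_obs_var(generate_dataset(homog)[0]).std()


def test_config_validation():
    with pytest.raises(pydantic.ValidationError):
        GeneratorConfig(stimuli=[])
    with pytest.raises(pydantic.ValidationError, match="reserved"):
        GeneratorConfig(stimuli=[StimulusSpec(stimulus_id="disk", hue_angle=0,
                                              prior_mean=0.1, prior_sd=0.1)])
    dup = default_stimuli()[:1] * 2
    with pytest.raises(pydantic.ValidationError, match="duplicate"):
        GeneratorConfig(stimuli=dup)
    with pytest.raises(pydantic.ValidationError, match="unknown_key"):
        GeneratorConfig.model_validate(
            {"stimuli": [s.model_dump() for s in default_stimuli()],
             "unknown_key": 1}
        )


def test_negative_adherence_requires_flag():
    spec = StimulusSpec(stimulus_id="heart", hue_angle=0.1, prior_mean=0.2,
                        prior_sd=0.1, effect_adherence=-0.5)
    with pytest.raises(pydantic.ValidationError, match="negative"):
        GeneratorConfig(stimuli=[spec])
    config = GeneratorConfig(stimuli=[spec], allow_negative_adherence=True,
                             n_observers=50, seed=2)
    # negative adherence produces a negative expected measured effect
    assert ground_truth_effect(spec, config) < 0
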