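"""Synthetic virtual-observer generator for achromatic-adjustment studies.

The generator emulates the three measurement types of the modelled
psychophysics designs, per observer and stimulus:

1. *typical adjustments* of a colour-diagnostic object -- 2-D Gaussian
   centred at ``prior_mean`` along the stimulus's hue direction, with the
   prior SD along that axis;
2. *grey adjustments of a colour-neutral disk* -- zero-mean Gaussian
   whose covariance is anisotropic in a daylight frame (grey settings
   vary most along the blue-yellow daylight locus);
3. *grey adjustments of the object* -- centred at the **negated**
   posterior shift ``-lambda * M * u``, where ``M`` is the closed-form
   reliability-weighted posterior mean computed from the observer's own
   generative variances, and ``lambda`` (``effect_adherence``) scales how
   much of the model-prescribed shift the stimulus actually expresses.
   ``lambda = 1`` makes the data obey the model exactly in expectation;
   ``lambda = 0`` emulates objects with no memory colour effect (a red
   heart, a cola logo); negative values emulate the occasional shift
   *toward* the typical colour, behind an explicit flag.

Isotropic ``response_noise_sd`` (input-device/motor noise, the component
the fusion model deliberately omits) can be added to every adjustment,
and a log-normal per-observer SD multiplier introduces observer
heterogeneity.  Ground truth (generative cue variances, closed-form M,
expected measured effect) is returned alongside the data for parameter
recovery.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "StimulusSpec",
    "GeneratorConfig",
    "generate_dataset",
    "ground_truth_effect",
    "default_stimuli",
    "fruit_stimuli_8",
    "manmade_stimuli",
    "default_config",
]

#: Reserved stimulus id for the colour-neutral disk.
DISK_ID = "disk"


class StimulusSpec(BaseModel):
    """Generative description of one colour-diagnostic stimulus."""

    model_config = ConfigDict(extra="forbid")

    stimulus_id: str
    condition: str = Field(
        default="photo", pattern="^(photo|outline|painted|other)$"
    )
    hue_angle: float = Field(description="direction of the typical colour, radians")
    prior_mean: float = Field(gt=0, description="typical-colour distance from grey")
    prior_sd: float = Field(ge=0, description="within-observer SD of typicals, on-axis")
    prior_sd_ortho: Optional[float] = Field(
        default=None, ge=0, description="orthogonal SD of typicals; None = on-axis SD"
    )
    effect_adherence: float = Field(
        default=1.0, ge=-1.0, le=1.0,
        description="lambda: fraction of the posterior shift expressed in data",
    )


class GeneratorConfig(BaseModel):
    """Full study design for one synthetic dataset."""

    model_config = ConfigDict(extra="forbid")

    stimuli: list[StimulusSpec] = Field(min_length=1)
    n_observers: int = Field(default=15, ge=1)
    n_repeats: int = Field(default=5, ge=2)
    signal_sd_axis: float = Field(default=0.06, ge=0)
    signal_sd_ortho: float = Field(default=0.03, ge=0)
    daylight_angle: float = Field(default=math.pi / 2)
    response_noise_sd: float = Field(default=0.0, ge=0)
    observer_sd_scale: float = Field(default=0.0, ge=0)
    allow_negative_adherence: bool = False
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate stimulus ids in {ids}")
        if DISK_ID in ids:
            raise ValueError(f"stimulus id {DISK_ID!r} is reserved for the disk")
        if not self.allow_negative_adherence:
            bad = [s.stimulus_id for s in self.stimuli if s.effect_adherence < 0]
            if bad:
                raise ValueError(
                    f"negative effect_adherence for {bad} requires "
                    "allow_negative_adherence=True"
                )
        return self


def _posterior_mean(P: float, var_prior: float, var_signal: float) -> tuple[float, float]:
    """Closed-form fused mean and prior weight, with analytic limits for
    zero variances (an exactly known prior dominates; an exactly known
    grey signal pins the percept at grey)."""
    if var_prior == 0.0:
        return P, 1.0
    if var_signal == 0.0:
        return 0.0, 0.0
    w1 = var_signal / (var_signal + var_prior)  # = r1 / (r1 + r2)
    return w1 * P, w1


def _projected_signal_var(config: GeneratorConfig, hue_angle: float) -> float:
    """Variance of disk grey settings along a stimulus's hue axis."""
    delta = hue_angle - config.daylight_angle
    return (
        config.signal_sd_axis**2 * math.cos(delta) ** 2
        + config.signal_sd_ortho**2 * math.sin(delta) ** 2
    )


def ground_truth_effect(spec: StimulusSpec, config: GeneratorConfig) -> float:
    """Expected measured memory colour effect under the generator:
    ``lambda * w1 * prior_mean`` with the signal variance taken along the
    stimulus's hue axis.  Zero-variance limits are handled analytically
    (both SDs zero, or a zero prior SD, give ``lambda * prior_mean``)."""
    var_prior = spec.prior_sd**2
    var_signal = _projected_signal_var(config, spec.hue_angle)
    m, _ = _posterior_mean(spec.prior_mean, var_prior, var_signal)
    return spec.effect_adherence * m


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one experiment-shaped adjustment table plus ground truth.

    Returns
    -------
    adjustments : DataFrame
        Columns observer_id, stimulus_id, condition, task, repeat_index,
        chroma_x, chroma_y.  Deterministic given the config (seed
        included); the same config yields byte-identical tables.
    ground_truth : DataFrame
        One row per observer x stimulus with the generative prior mean,
        cue variances, prior weight, closed-form posterior mean M and the
        expected measured effect lambda * M.
    """
    rng = np.random.default_rng(config.seed)
    n_obs, n_rep = config.n_observers, config.n_repeats
    if config.observer_sd_scale > 0:
        kappas = np.exp(rng.normal(0.0, config.observer_sd_scale, size=n_obs))
    else:
        kappas = np.ones(n_obs)

    d_axis = np.array([math.cos(config.daylight_angle), math.sin(config.daylight_angle)])
    d_orth = np.array([-d_axis[1], d_axis[0]])

    rows: list[tuple] = []
    truth: list[tuple] = []
    for o in range(n_obs):
        obs_id = f"obs{o + 1:03d}"
        kappa = float(kappas[o])

        # colour-neutral disk: grey-perception noise in the daylight frame
        a = rng.normal(0.0, kappa * config.signal_sd_axis, size=n_rep)
        b = rng.normal(0.0, kappa * config.signal_sd_ortho, size=n_rep)
        disk_xy = np.outer(a, d_axis) + np.outer(b, d_orth)
        for rep in range(n_rep):
            rows.append(
                (obs_id, DISK_ID, "disk", "grey", rep + 1,
                 disk_xy[rep, 0], disk_xy[rep, 1])
            )

        for spec in config.stimuli:
            u = np.array([math.cos(spec.hue_angle), math.sin(spec.hue_angle)])
            u_orth = np.array([-u[1], u[0]])
            sd_on = kappa * spec.prior_sd
            sd_off = kappa * (
                spec.prior_sd if spec.prior_sd_ortho is None else spec.prior_sd_ortho
            )

            # (1) typical adjustments around the remembered typical colour
            ta = rng.normal(0.0, sd_on, size=n_rep)
            tb = rng.normal(0.0, sd_off, size=n_rep)
            typ_xy = spec.prior_mean * u + np.outer(ta, u) + np.outer(tb, u_orth)
            for rep in range(n_rep):
                rows.append(
                    (obs_id, spec.stimulus_id, spec.condition, "typical", rep + 1,
                     typ_xy[rep, 0], typ_xy[rep, 1])
                )

            # (3) grey adjustments of the object: compensated posterior shift
            var_prior = sd_on**2
            var_signal = kappa**2 * _projected_signal_var(config, spec.hue_angle)
            m, w1 = _posterior_mean(spec.prior_mean, var_prior, var_signal)
            centre = -spec.effect_adherence * m * u
            ga = rng.normal(0.0, kappa * config.signal_sd_axis, size=n_rep)
            gb = rng.normal(0.0, kappa * config.signal_sd_ortho, size=n_rep)
            grey_xy = centre + np.outer(ga, d_axis) + np.outer(gb, d_orth)
            for rep in range(n_rep):
                rows.append(
                    (obs_id, spec.stimulus_id, spec.condition, "grey", rep + 1,
                     grey_xy[rep, 0], grey_xy[rep, 1])
                )

            truth.append(
                (obs_id, spec.stimulus_id, spec.condition, spec.prior_mean, 0.0,
                 var_prior, var_signal, w1, m,
                 spec.effect_adherence * m)
            )

    adjustments = pd.DataFrame(
        rows,
        columns=[
            "observer_id", "stimulus_id", "condition", "task", "repeat_index",
            "chroma_x", "chroma_y",
        ],
    )
    if config.response_noise_sd > 0:
        noise = rng.normal(0.0, config.response_noise_sd, size=(len(adjustments), 2))
        adjustments["chroma_x"] += noise[:, 0]
        adjustments["chroma_y"] += noise[:, 1]

    ground_truth = pd.DataFrame(
        truth,
        columns=[
            "observer_id", "stimulus_id", "condition", "prior_mean", "signal_mean",
            "prior_var", "signal_var", "weight_prior", "posterior_mean",
            "expected_effect",
        ],
    )
    return adjustments, ground_truth


def default_stimuli() -> list[StimulusSpec]:
    """Seven fruit-like stimuli spanning weak to strong memory colours.

    Prior means and SDs are order-of-magnitude plausible DKL-plane values
    (0.05-0.3 units), chosen so the expected effects cover a wide range:
    yellow stimuli near the daylight axis with precise colour memories
    produce large effects, off-axis stimuli with diffuse memories small
    ones.  They are illustrative, not fitted to any dataset.
    """
    mk = StimulusSpec
    return [
        mk(stimulus_id="banana", hue_angle=1.48, prior_mean=0.30, prior_sd=0.04),
        mk(stimulus_id="lemon", hue_angle=1.60, prior_mean=0.26, prior_sd=0.06),
        mk(stimulus_id="orange", hue_angle=0.80, prior_mean=0.22, prior_sd=0.09),
        mk(stimulus_id="carrot", hue_angle=0.60, prior_mean=0.18, prior_sd=0.12),
        mk(stimulus_id="lettuce", hue_angle=2.70, prior_mean=0.12, prior_sd=0.14),
        mk(stimulus_id="grape", hue_angle=4.30, prior_mean=0.09, prior_sd=0.16),
        mk(stimulus_id="courgette", hue_angle=2.95, prior_mean=0.15, prior_sd=0.08),
    ]


def fruit_stimuli_8() -> list[StimulusSpec]:
    """The seven default fruits plus a strawberry (8-stimulus design)."""
    return default_stimuli() + [
        StimulusSpec(stimulus_id="strawberry", hue_angle=0.15, prior_mean=0.20,
                     prior_sd=0.10),
    ]


def manmade_stimuli() -> list[StimulusSpec]:
    """Sixteen man-made-object analogues, including model-violating
    controls: two no-effect red-ish objects and a no-memory-colour sock
    and golf ball (effect_adherence 0), and a cartoon figure expressing
    only part of the predicted shift."""
    mk = StimulusSpec
    return [
        mk(stimulus_id="mailbox", condition="photo", hue_angle=1.50, prior_mean=0.28, prior_sd=0.06),
        mk(stimulus_id="gluestick", condition="photo", hue_angle=1.55, prior_mean=0.24, prior_sd=0.07),
        mk(stimulus_id="maus", condition="outline", hue_angle=0.70, prior_mean=0.22, prior_sd=0.08, effect_adherence=0.0),
        mk(stimulus_id="chair", condition="photo", hue_angle=0.90, prior_mean=0.10, prior_sd=0.09),
        mk(stimulus_id="closet", condition="photo", hue_angle=0.95, prior_mean=0.08, prior_sd=0.10),
        mk(stimulus_id="heart", condition="outline", hue_angle=0.10, prior_mean=0.25, prior_sd=0.07, effect_adherence=0.0),
        mk(stimulus_id="coke", condition="other", hue_angle=0.05, prior_mean=0.26, prior_sd=0.07, effect_adherence=0.0),
        mk(stimulus_id="extinguisher", condition="photo", hue_angle=0.00, prior_mean=0.24, prior_sd=0.09),
        mk(stimulus_id="pinkpanther", condition="outline", hue_angle=0.35, prior_mean=0.14, prior_sd=0.11),
        mk(stimulus_id="milka", condition="photo", hue_angle=4.40, prior_mean=0.16, prior_sd=0.10),
        mk(stimulus_id="nivea", condition="photo", hue_angle=4.65, prior_mean=0.20, prior_sd=0.08),
        mk(stimulus_id="smurf", condition="outline", hue_angle=4.70, prior_mean=0.30, prior_sd=0.04, effect_adherence=0.3),
        mk(stimulus_id="sign", condition="other", hue_angle=4.60, prior_mean=0.22, prior_sd=0.07),
        mk(stimulus_id="pingpong", condition="photo", hue_angle=2.40, prior_mean=0.12, prior_sd=0.10),
        mk(stimulus_id="sock", condition="other", hue_angle=0.50, prior_mean=0.12, prior_sd=0.12, effect_adherence=0.0),
        mk(stimulus_id="golfball", condition="other", hue_angle=1.00, prior_mean=0.02, prior_sd=0.10, effect_adherence=0.0),
    ]


def default_config(**overrides) -> GeneratorConfig:
    """The default study design: 15 observers x 7 stimuli x 5 repeats."""
    params: dict = {"stimuli": default_stimuli()}
    params.update(overrides)
    return GeneratorConfig(**params)
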