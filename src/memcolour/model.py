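"""Reliability-weighted Gaussian fusion of a memory-colour prior and a
grey-perception signal.

The model has no free parameters.  Both cues are Gaussians estimated from
repeated colour adjustments projected onto a stimulus's typical-hue axis:

* the *prior* ``P`` from typical adjustments of the colour-diagnostic
  object (the remembered typical colour and its precision), and
* the *signal* ``S`` from grey adjustments of a colour-neutral disk
  (the noise of grey perception itself).

With reliabilities ``r = 1 / var`` the posterior (predicted memory colour
effect) is the precision-weighted average

    M  = w1 * P + w2 * S,      w1 = r1 / (r1 + r2),  w2 = 1 - w1,
    SD = sqrt(1 / (r1 + r2)).

Because ``S`` is at grey (zero) and ``P`` lies toward the typical colour,
``M`` always falls between them: the model cannot predict negative
effects.  The noisier the signal, the more the percept shifts toward the
prior.

Two analysis levels exist.  *individual*: variances are across an
observer's repeated adjustments.  *aggregate*: variances are across
per-observer mean adjustments, which estimates within-observer
variance / n_repeats (the standard-error construction) and is the
appropriate uncertainty for averaged data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import (
    DegenerateCueError,
    InsufficientDataError,
    InvalidInputError,
    LevelMismatchError,
)

__all__ = [
    "CueSource",
    "AnalysisLevel",
    "CueEstimate",
    "PosteriorPrediction",
    "estimate_cue",
    "aggregate_cue",
    "reliability",
    "combine",
    "predict_effect",
]

#: Default regularisation added to a zero variance when opted in.
DEFAULT_EPSILON = 1e-9

SdMode = Literal["sqrt", "inverse"]


class CueSource(str, enum.Enum):
    PRIOR = "prior"
    SIGNAL = "signal"


class AnalysisLevel(str, enum.Enum):
    INDIVIDUAL = "individual"
    AGGREGATE = "aggregate"


@dataclass(frozen=True)
class CueEstimate:
    """Mean, variance and sample size of one cue's projected adjustments."""

    mean: float
    variance: float
    n: int
    source: CueSource
    level: AnalysisLevel

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise InvalidInputError("non-finite cue estimate")
        if self.variance < 0:
            raise InvalidInputError(f"negative variance {self.variance}")
        if self.n < 1:
            raise InvalidInputError(f"n must be >= 1, got {self.n}")
        if self.level is AnalysisLevel.AGGREGATE and self.n < 2:
            raise InvalidInputError("aggregate cue needs >= 2 observer means")


@dataclass(frozen=True)
class PosteriorPrediction:
    """Fused posterior: the predicted memory colour effect and its spread."""

    M: float
    sd: float
    w_prior: float
    r_prior: float
    r_signal: float
    level: AnalysisLevel

    @property
    def w_signal(self) -> float:
        return 1.0 - self.w_prior


def estimate_cue(
    samples: Iterable[float],
    source: CueSource | str,
    level: AnalysisLevel | str = AnalysisLevel.INDIVIDUAL,
) -> CueEstimate:
    """Cue mean and unbiased (n-1) variance from repeated projections.

    Raises
    ------
    InsufficientDataError
        With fewer than two samples (the variance needs df >= 1).
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"cue estimation needs >= 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite sample values")
    return CueEstimate(
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)),
        n=int(x.size),
        source=CueSource(source),
        level=AnalysisLevel(level),
    )


def aggregate_cue(
    per_observer_means: Iterable[float], source: CueSource | str
) -> CueEstimate:
    """Aggregate-level cue from per-observer mean projections.

    The variance is the unbiased variance *across observer means*.  Since
    each mean averages n_repeats adjustments, this empirically realises
    within-observer variance / n_repeats, the uncertainty appropriate for
    aggregated data.
    """
    x = np.asarray(list(per_observer_means), dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"aggregate cue needs >= 2 observer means, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite observer means")
    return CueEstimate(
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)),
        n=int(x.size),
        source=CueSource(source),
        level=AnalysisLevel.AGGREGATE,
    )


def reliability(variance: float, epsilon: float | None = None) -> float:
    """Reliability r = 1 / variance, optionally regularised to
    1 / (variance + epsilon) so that zero-variance cues stay finite.

    Regularisation is opt-in: with ``epsilon=None`` a zero variance raises
    :class:`DegenerateCueError` instead of silently producing an
    infinitely reliable cue.
    """
    if not math.isfinite(variance):
        raise InvalidInputError("non-finite variance")
    if variance < 0:
        raise InvalidInputError(f"negative variance {variance}")
    if epsilon is not None:
        if epsilon <= 0:
            raise InvalidInputError(f"epsilon must be > 0, got {epsilon}")
        return 1.0 / (variance + epsilon)
    if variance == 0:
        raise DegenerateCueError(
            "zero-variance cue; enable epsilon-regularisation to proceed"
        )
    return 1.0 / variance


def combine(
    prior: CueEstimate,
    signal: CueEstimate,
    epsilon: float | None = None,
    sd_mode: SdMode = "sqrt",
) -> PosteriorPrediction:
    """Fuse prior and signal into the posterior prediction.

    Parameters
    ----------
    prior, signal
        Cue estimates at the same analysis level.
    epsilon
        Optional variance regularisation passed to :func:`reliability`.
    sd_mode
        ``"sqrt"`` (default) reports SD = sqrt(1/(r1+r2)), the fused
        Gaussian's standard deviation; ``"inverse"`` reports 1/(r1+r2)
        (the posterior variance) for comparison.
    """
    if prior.level is not signal.level:
        raise LevelMismatchError(
            f"cannot combine {prior.level.value} prior with "
            f"{signal.level.value} signal"
        )
    if epsilon is None and prior.variance == 0 and signal.variance == 0:
        raise DegenerateCueError("both cues have zero variance")
    r1 = reliability(prior.variance, epsilon)
    r2 = reliability(signal.variance, epsilon)
    w1 = r1 / (r1 + r2)
    m = w1 * prior.mean + (1.0 - w1) * signal.mean
    var_post = 1.0 / (r1 + r2)
    sd = math.sqrt(var_post) if sd_mode == "sqrt" else var_post
    return PosteriorPrediction(
        M=m, sd=sd, w_prior=w1, r_prior=r1, r_signal=r2, level=prior.level
    )


def predict_effect(
    typicals: Iterable[float],
    disk_greys: Iterable[float],
    level: AnalysisLevel | str = AnalysisLevel.INDIVIDUAL,
    epsilon: float | None = None,
    sd_mode: SdMode = "sqrt",
) -> PosteriorPrediction:
    """Predicted memory colour effect from projected adjustments.

    Convenience composition of cue estimation and fusion.  At the
    individual level the inputs are one observer's repeated projections;
    at the aggregate level they are per-observer mean projections.
    """
    level = AnalysisLevel(level)
    if level is AnalysisLevel.AGGREGATE:
        prior = aggregate_cue(typicals, CueSource.PRIOR)
        signal = aggregate_cue(disk_greys, CueSource.SIGNAL)
    else:
        prior = estimate_cue(typicals, CueSource.PRIOR, level)
        signal = estimate_cue(disk_greys, CueSource.SIGNAL, level)
    return combine(prior, signal, epsilon=epsilon, sd_mode=sd_mode)
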