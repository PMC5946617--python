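"""Comparing predicted and measured memory colour effects.

Three complementary approaches:

1. **individual** -- correlate predicted and measured effects across
   stimuli within each observer, Fisher-transform the per-observer
   correlations, and t-test the z values across observers (one-tailed,
   positive).  This is the strictest test: a Bayesian observer model is
   meant to work within individuals.
2. **pooled** -- a single correlation over all observer x stimulus pairs.
   High statistical power, but between-observer variation becomes part of
   the signal.
3. **aggregated** -- one pair per stimulus from aggregate-level cue
   estimates; correlate across stimuli.  Response noise averages out
   here, which is why aggregate data can succeed where individual data
   fail.

Also here: the *relative* memory colour effect (condition-centred
measured effects, removing e.g. a photo-vs-outline offset) and the paired
difference test on predicted minus measured effects.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, OutOfRangeError

__all__ = [
    "Tail",
    "EffectPair",
    "CorrelationResult",
    "DifferenceTestResult",
    "IndividualSummary",
    "fisher_z",
    "fisher_z_inv",
    "pearson_with_test",
    "individual_approach",
    "pooled_approach",
    "aggregated_approach",
    "relative_effects",
    "difference_test",
]

logger = logging.getLogger(__name__)

#: |r| is clamped at 1 - CLAMP_EPS before the Fisher transform when clamping
#: is enabled; with 3-5 stimuli per observer, |r| = 1 is a real occurrence.
CLAMP_EPS = 1e-12


class Tail(str, enum.Enum):
    ONE_TAILED_POSITIVE = "one_tailed_positive"
    TWO_TAILED = "two_tailed"


class Approach(str, enum.Enum):
    INDIVIDUAL = "individual"
    POOLED = "pooled"
    AGGREGATED = "aggregated"


@dataclass(frozen=True)
class EffectPair:
    """One predicted/measured effect pair for an observer x stimulus cell
    (observer_id ``"aggregate"`` marks aggregate-level pairs)."""

    observer_id: str
    stimulus_id: str
    condition: str
    predicted: float
    measured: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.predicted) and math.isfinite(self.measured)):
            raise InvalidInputError(
                f"non-finite effect pair for {self.observer_id}/{self.stimulus_id}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    approach: Approach
    r: float
    df: int
    t: float
    p: float
    tail: Tail
    fisher_z: float
    n: int


@dataclass(frozen=True)
class DifferenceTestResult:
    """Paired t test of predicted minus measured effects.

    ``delta`` is mean(predicted) - mean(measured); df = n_pairs - 1.
    """

    delta: float
    t: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class IndividualSummary:
    """t test of Fisher-transformed per-observer correlations against zero."""

    mean_r: float
    t: float
    df: int
    p: float
    tail: Tail
    n_observers: int
    per_observer_z: dict[str, float] = field(default_factory=dict)
    dropped: list[tuple[str, str]] = field(default_factory=list)


def fisher_z(r: float, clamp: bool = False) -> float:
    """Fisher z transform, arctanh(r).

    With ``clamp=True``, |r| >= 1 is pulled to 1 - 1e-12 first (degenerate
    perfect correlations from tiny designs); otherwise it raises.
    """
    if not math.isfinite(r):
        raise InvalidInputError("non-finite correlation")
    if abs(r) >= 1.0:
        if not clamp:
            raise OutOfRangeError(f"|r| = {abs(r)} >= 1; Fisher z undefined")
        r = math.copysign(1.0 - CLAMP_EPS, r)
    return math.atanh(r)


def fisher_z_inv(z: float) -> float:
    """Inverse Fisher transform, tanh(z)."""
    return math.tanh(z)


def pearson_with_test(
    pairs: Sequence[EffectPair],
    tail: Tail | str = Tail.ONE_TAILED_POSITIVE,
    approach: Approach | str = Approach.AGGREGATED,
) -> CorrelationResult:
    """Pearson correlation between predicted and measured effects with a
    Student-t test, df = n - 2.

    For ``one_tailed_positive`` the p value is the upper-tail probability
    of t (directional); two-tailed doubles the smaller tail.
    """
    tail = Tail(tail)
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {len(pairs)}")
    x = np.array([p.predicted for p in pairs])
    y = np.array([p.measured for p in pairs])
    if x.std() == 0 or y.std() == 0:
        raise InsufficientDataError("zero variance in predicted or measured effects")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = len(pairs) - 2
    with np.errstate(divide="ignore"):
        t = float(r * math.sqrt(df / (1.0 - r * r))) if abs(r) < 1 else math.copysign(
            math.inf, r
        )
    if tail is Tail.ONE_TAILED_POSITIVE:
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        approach=Approach(approach),
        r=r,
        df=df,
        t=t,
        p=p,
        tail=tail,
        fisher_z=fisher_z(r, clamp=True),
        n=len(pairs),
    )


def _observer_z(
    pairs: Sequence[EffectPair], clamp: bool, by_condition: bool
) -> float:
    """Fisher z for one observer; mean z across conditions if requested."""
    if by_condition:
        zs = []
        for cond in sorted({p.condition for p in pairs}):
            sub = [p for p in pairs if p.condition == cond]
            zs.append(_observer_z(sub, clamp, by_condition=False))
        return float(np.mean(zs))
    if len(pairs) < 3:
        raise InsufficientDataError("observer has < 3 pairs")
    x = np.array([p.predicted for p in pairs])
    y = np.array([p.measured for p in pairs])
    if x.std() == 0 or y.std() == 0:
        raise InsufficientDataError("zero variance within observer")
    r = float(np.corrcoef(x, y)[0, 1])
    return fisher_z(r, clamp=clamp)


def individual_approach(
    per_observer_pairs: Mapping[str, Sequence[EffectPair]],
    clamp: bool = True,
    by_condition: bool = False,
    tail: Tail | str = Tail.ONE_TAILED_POSITIVE,
) -> IndividualSummary:
    """First evaluation approach: per-observer correlations tested across
    observers.

    Each observer's predicted/measured pairs give a Pearson r, Fisher
    transformed to z; a one-sample t test across observers asks whether z
    is positive (one-tailed by default).  ``mean_r`` is the inverse-Fisher
    of the mean z.  With ``by_condition=True`` each observer's z is first
    averaged over their per-condition correlations (used when image
    conditions are combined).

    Observers with degenerate correlations (too few pairs, constant
    columns, or |r| = 1 when clamping is off) are excluded and logged.
    """
    tail = Tail(tail)
    zs: dict[str, float] = {}
    dropped: list[tuple[str, str]] = []
    for obs, pairs in per_observer_pairs.items():
        try:
            zs[obs] = _observer_z(list(pairs), clamp, by_condition)
        except (InsufficientDataError, OutOfRangeError) as exc:
            reason = "DEGENERATE_CORRELATION"
            dropped.append((obs, reason))
            logger.info("individual approach: dropped observer %s (%s: %s)",
                        obs, reason, exc)
    if len(zs) < 2:
        raise InsufficientDataError(
            f"individual approach needs >= 2 usable observers, got {len(zs)}"
        )
    zvals = np.array(list(zs.values()))
    zbar = float(zvals.mean())
    if zvals.std(ddof=1) == 0.0:  # identical z values: se = 0
        t = 0.0 if zbar == 0.0 else math.copysign(math.inf, zbar)
        if tail is Tail.ONE_TAILED_POSITIVE:
            p = 0.5 if zbar == 0.0 else (0.0 if zbar > 0 else 1.0)
        else:
            p = 1.0 if zbar == 0.0 else 0.0
    else:
        alternative = "greater" if tail is Tail.ONE_TAILED_POSITIVE else "two-sided"
        res = stats.ttest_1samp(zvals, 0.0, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    return IndividualSummary(
        mean_r=fisher_z_inv(zbar),
        t=t,
        df=len(zvals) - 1,
        p=p,
        tail=tail,
        n_observers=len(zvals),
        per_observer_z=zs,
        dropped=dropped,
    )


def pooled_approach(
    pairs: Sequence[EffectPair], tail: Tail | str = Tail.ONE_TAILED_POSITIVE
) -> CorrelationResult:
    """Second approach: one correlation over all observer x stimulus pairs."""
    return pearson_with_test(pairs, tail=tail, approach=Approach.POOLED)


def aggregated_approach(
    pairs: Sequence[EffectPair], tail: Tail | str = Tail.ONE_TAILED_POSITIVE
) -> CorrelationResult:
    """Third approach: correlation across stimuli of aggregate-level pairs.

    Expects one pair per stimulus (or stimulus x condition); df is
    n_stimuli - 2.
    """
    keys = [(p.stimulus_id, p.condition) for p in pairs]
    if len(set(keys)) != len(keys):
        raise InvalidInputError(
            "aggregated approach expects one pair per stimulus x condition"
        )
    return pearson_with_test(pairs, tail=tail, approach=Approach.AGGREGATED)


def relative_effects(
    pairs: Sequence[EffectPair], centre_predicted: bool = False
) -> list[EffectPair]:
    """Relative memory colour effects: subtract from each measured effect
    the mean measured effect of its image condition.

    Removes condition offsets (photographs vs outline shapes) that the
    model, by construction, cannot express.  Predicted effects are left
    unchanged by default; ``centre_predicted=True`` centres both sides.
    Centring is idempotent.
    """
    if not pairs:
        raise InvalidInputError("no pairs to centre")
    out: list[EffectPair] = []
    conditions = sorted({p.condition for p in pairs})
    for cond in conditions:
        sub = [p for p in pairs if p.condition == cond]
        if len(sub) < 2:
            logger.warning(
                "relative_effects: condition %r has < 2 pairs; centred to 0", cond
            )
        m_mean = float(np.mean([p.measured for p in sub]))
        p_mean = float(np.mean([p.predicted for p in sub]))
        for p in sub:
            out.append(
                replace(
                    p,
                    measured=p.measured - m_mean,
                    predicted=p.predicted - p_mean if centre_predicted else p.predicted,
                )
            )
    return out


def difference_test(pairs: Sequence[EffectPair]) -> DifferenceTestResult:
    """Paired t test of predicted vs measured effects (two-tailed).

    ``delta`` is the mean of predicted - measured; df = n - 1.  A positive
    delta means the model over-predicts the measured effect.
    """
    if len(pairs) < 2:
        raise InsufficientDataError(f"difference test needs >= 2 pairs, got {len(pairs)}")
    diffs = np.array([p.predicted - p.measured for p in pairs])
    delta = float(diffs.mean())
    if diffs.std(ddof=1) == 0.0:  # constant differences: se = 0
        t = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        res = stats.ttest_1samp(diffs, 0.0)
        t, p = float(res.statistic), float(res.pvalue)
    return DifferenceTestResult(delta=delta, t=t, df=len(diffs) - 1, p=p, n=len(diffs))


def pairs_by_observer(
    pairs: Iterable[EffectPair],
) -> dict[str, list[EffectPair]]:
    """Group a flat pair list by observer, preserving encounter order."""
    grouped: dict[str, list[EffectPair]] = {}
    for p in pairs:
        grouped.setdefault(p.observer_id, []).append(p)
    return grouped
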