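"""Simulation studies: model verification and parameter recovery.

These are the package's own checks of its scientific claims, run on
synthetic virtual observers:

* a brute-force product-of-Gaussians oracle for the fusion equations,
* pipeline closure (model-conforming, noise-free data are recovered),
* parameter recovery at the modelled study designs,
* attenuation of individual-level predictive power under response noise
  (estimated with common random numbers across noise levels), and
* type-I calibration of the one-tailed correlation test.

Problem sizes default to the designs of the modelled studies
(15 observers x 7-8 stimuli x 5 repeats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate as ev
from .io import RunConfig
from .pipeline import run_pipeline
from .simulate import (
    GeneratorConfig,
    default_stimuli,
    fruit_stimuli_8,
    generate_dataset,
    ground_truth_effect,
)

__all__ = [
    "numeric_fusion_moments",
    "fusion_oracle_errors",
    "closure_study",
    "parameter_recovery",
    "noise_attenuation",
    "type_i_rate",
    "var_over_n_ratio",
]


def numeric_fusion_moments(
    mean_prior: float,
    var_prior: float,
    mean_signal: float,
    var_signal: float,
    n_grid: int = 20001,
    half_width_sds: float = 12.0,
) -> tuple[float, float]:
    """Mean and variance of the normalised product of two Gaussians by
    numerical integration on a fine grid.

    Independent of the fusion formulas: it literally multiplies the two
    densities, normalises, and integrates for the first two moments.
    """
    sd1, sd2 = math.sqrt(var_prior), math.sqrt(var_signal)
    lo = min(mean_prior - half_width_sds * sd1, mean_signal - half_width_sds * sd2)
    hi = max(mean_prior + half_width_sds * sd1, mean_signal + half_width_sds * sd2)
    x = np.linspace(lo, hi, n_grid)
    log_dens = (
        -0.5 * ((x - mean_prior) ** 2 / var_prior)
        - 0.5 * ((x - mean_signal) ** 2 / var_signal)
    )
    dens = np.exp(log_dens - log_dens.max())
    z = np.trapezoid(dens, x)
    mean = float(np.trapezoid(x * dens, x) / z)
    var = float(np.trapezoid((x - mean) ** 2 * dens, x) / z)
    return mean, var


def fusion_oracle_errors(n_pairs: int = 1000, seed: int = 0) -> np.ndarray:
    """Relative errors of the closed-form fusion against the numerical
    oracle over random cue pairs.  Returns an (n_pairs, 2) array of
    relative errors in (M, sd^2)."""
    from .model import AnalysisLevel, CueEstimate, CueSource, combine

    rng = np.random.default_rng(seed)
    errs = np.empty((n_pairs, 2))
    for i in range(n_pairs):
        mp = rng.uniform(-0.5, 0.5)
        ms = rng.uniform(-0.5, 0.5)
        vp = rng.uniform(1e-4, 0.1)
        vs = rng.uniform(1e-4, 0.1)
        prior = CueEstimate(mp, vp, 5, CueSource.PRIOR, AnalysisLevel.INDIVIDUAL)
        signal = CueEstimate(ms, vs, 5, CueSource.SIGNAL, AnalysisLevel.INDIVIDUAL)
        post = combine(prior, signal)
        m_num, v_num = numeric_fusion_moments(mp, vp, ms, vs)
        scale_m = max(abs(m_num), 1e-3)
        errs[i, 0] = abs(post.M - m_num) / scale_m
        errs[i, 1] = abs(post.sd**2 - v_num) / v_num
    return errs


@dataclass(frozen=True)
class ClosureResult:
    r: float
    p: float
    delta: float
    delta_t: float
    n_stimuli: int


def closure_study(
    seed: int = 0, n_observers: int = 20, n_repeats: int = 5
) -> ClosureResult:
    """Generate model-conforming, response-noise-free data (lambda = 1)
    and check that the aggregated approach recovers the model: high
    predicted-vs-measured correlation, delta indistinguishable from 0."""
    config = GeneratorConfig(
        stimuli=default_stimuli(),
        n_observers=n_observers,
        n_repeats=n_repeats,
        response_noise_sd=0.0,
        seed=seed,
    )
    data, _truth = generate_dataset(config)
    bundle = run_pipeline(data, RunConfig(levels=["aggregated"]))
    corr = bundle.correlations
    row = corr[(corr["approach"] == "aggregated") & (corr["condition"] == "all")].iloc[0]
    diff = bundle.difference_tests
    drow = diff[diff["condition"] == "all"].iloc[0]
    return ClosureResult(
        r=float(row["r"]),
        p=float(row["p"]),
        delta=float(drow["delta"]),
        delta_t=float(drow["t"]),
        n_stimuli=int(row["n"]),
    )


@dataclass(frozen=True)
class ClosureReplicates:
    """Closure study repeated over independent seeds.

    ``delta_t`` is the mean delta over replicates divided by its
    Monte-Carlo standard error; with unbiased closure it is a standard
    normal deviate, and replication makes the check sensitive to far
    smaller systematic bias than any single run's paired t test.
    """

    mean_r: float
    min_r: float
    mean_delta: float
    delta_se: float
    delta_t: float
    n_replicates: int
    n_stimuli: int


def closure_replicates(
    n_replicates: int = 10, seed: int = 0, n_observers: int = 20,
    n_repeats: int = 5,
) -> ClosureReplicates:
    """Replicate :func:`closure_study` over independent seeds and pool."""
    results = [
        closure_study(seed=seed + i, n_observers=n_observers, n_repeats=n_repeats)
        for i in range(n_replicates)
    ]
    rs = np.array([r.r for r in results])
    deltas = np.array([r.delta for r in results])
    se = float(deltas.std(ddof=1) / math.sqrt(n_replicates))
    return ClosureReplicates(
        mean_r=float(rs.mean()),
        min_r=float(rs.min()),
        mean_delta=float(deltas.mean()),
        delta_se=se,
        delta_t=float(deltas.mean() / se),
        n_replicates=n_replicates,
        n_stimuli=results[0].n_stimuli,
    )


def parameter_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_observers: int = 15,
    n_repeats: int = 5,
    stimuli=None,
) -> np.ndarray:
    """Correlation between aggregate predicted effects and the
    generator's closed-form expected effects, across stimuli, one value
    per seed.  Defaults to the 15-observer x 8-stimulus x 5-repeat
    design."""
    stimuli = stimuli if stimuli is not None else fruit_stimuli_8()
    rs = np.empty(n_seeds)
    run_cfg = RunConfig(levels=["aggregated"])
    for i in range(n_seeds):
        config = GeneratorConfig(
            stimuli=stimuli,
            n_observers=n_observers,
            n_repeats=n_repeats,
            seed=seed + i,
        )
        truth_effects = {
            s.stimulus_id: ground_truth_effect(s, config) for s in stimuli
        }
        data, _ = generate_dataset(config)
        bundle = run_pipeline(data, run_cfg)
        agg = bundle.pairs[bundle.pairs["level"] == "aggregate"]
        pred = agg.set_index("stimulus_id")["predicted"]
        ids = sorted(truth_effects)
        x = np.array([pred[j] for j in ids])
        y = np.array([truth_effects[j] for j in ids])
        rs[i] = np.corrcoef(x, y)[0, 1]
    return rs


def _mean_individual_r(data: pd.DataFrame) -> float:
    """Mean per-observer predicted-vs-measured correlation (inverse-
    Fisher of the mean z) via the individual evaluation approach."""
    bundle = run_pipeline(data, RunConfig(levels=["individual"]))
    corr = bundle.correlations
    row = corr[(corr["approach"] == "individual") & (corr["condition"] == "all")]
    return float(row.iloc[0]["r"])


def noise_attenuation(
    noise_grid=(0.0, 0.025, 0.05, 0.1, 0.2),
    n_seeds: int = 200,
    seed: int = 0,
    n_observers: int = 15,
    n_repeats: int = 5,
    stimuli=None,
) -> pd.DataFrame:
    """Mean individual-approach correlation as a function of response
    noise.

    Uses common random numbers: per seed, one noise-free dataset and one
    standard-normal noise field are drawn, and each grid level adds the
    *same* field scaled by its SD.  Differences between grid points are
    then purely the effect of the noise magnitude.
    """
    stimuli = stimuli if stimuli is not None else default_stimuli()
    sums = np.zeros(len(noise_grid))
    counts = np.zeros(len(noise_grid))
    for i in range(n_seeds):
        config = GeneratorConfig(
            stimuli=stimuli,
            n_observers=n_observers,
            n_repeats=n_repeats,
            response_noise_sd=0.0,
            seed=seed + i,
        )
        data, _ = generate_dataset(config)
        noise_rng = np.random.default_rng(2**30 + seed + i)
        field = noise_rng.standard_normal((len(data), 2))
        for j, sd in enumerate(noise_grid):
            noisy = data.copy()
            noisy["chroma_x"] += sd * field[:, 0]
            noisy["chroma_y"] += sd * field[:, 1]
            sums[j] += _mean_individual_r(noisy)
            counts[j] += 1
    return pd.DataFrame(
        {"response_noise_sd": list(noise_grid), "mean_individual_r": sums / counts}
    )


def type_i_rate(
    n_sims: int = 20000, n_pairs: int = 7, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical one-tailed rejection rate of the correlation test under
    the null (independent Gaussian predicted and measured effects)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n_pairs)
        y = rng.standard_normal(n_pairs)
        pairs = [
            ev.EffectPair(f"o", f"s{k}", "photo", float(x[k]), float(y[k]))
            for k in range(n_pairs)
        ]
        res = ev.pearson_with_test(pairs, tail=ev.Tail.ONE_TAILED_POSITIVE)
        if res.p < alpha:
            rejections += 1
    return rejections / n_sims


def var_over_n_ratio(
    n_observers: int = 10000, n_repeats: int = 5, sd: float = 0.1, seed: int = 0
) -> float:
    """Ratio of the variance of per-observer means to (within-observer
    variance / n_repeats); approaches 1 for homogeneous observers."""
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, sd, size=(n_observers, n_repeats))
    var_of_means = samples.mean(axis=1).var(ddof=1)
    return float(var_of_means / (sd**2 / n_repeats))
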