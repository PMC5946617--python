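"""The three evaluation approaches, the Fisher-z machinery, relative
effects, and the paired difference test."""

import math

import numpy as np
import pytest
from scipy import stats

from memcolour import (
    EffectPair,
    InsufficientDataError,
    OutOfRangeError,
    Tail,
    aggregated_approach,
    difference_test,
    fisher_z,
    fisher_z_inv,
    individual_approach,
    pearson_with_test,
    pooled_approach,
    relative_effects,
)


def mkpairs(xs, ys, observer="o1", condition="photo"):
    return [
        EffectPair(observer, f"s{i}", condition, float(x), float(y))
        for i, (x, y) in enumerate(zip(xs, ys))
    ]


def test_fisher_z_examples_and_round_trip(rng):
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)
    for r in rng.uniform(-0.99, 0.99, 100):
        assert fisher_z_inv(fisher_z(float(r))) == pytest.approx(r, abs=1e-12)


def test_fisher_z_out_of_range():
    with pytest.raises(OutOfRangeError):
        fisher_z(1.0)
    assert fisher_z(1.0, clamp=True) > 13  # atanh(1 - 1e-12)


def test_pearson_perfect_correlations():
    res = pearson_with_test(mkpairs([1, 2, 3], [1, 2, 3]))
    assert res.r == pytest.approx(1.0)
    assert res.p == 0.0
    anti = pearson_with_test(mkpairs([1, 2, 3], [3, 2, 1]))
    assert anti.r == pytest.approx(-1.0)


def test_pearson_matches_scipy_two_tailed(rng):
    x, y = rng.normal(size=10), rng.normal(size=10)
    res = pearson_with_test(mkpairs(x, y), tail=Tail.TWO_TAILED)
    ref = stats.pearsonr(x, y)
    assert res.r == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_one_tailed_p_is_half_two_tailed_in_direction(rng):
    x = rng.normal(size=8)
    y = x + rng.normal(size=8)  # positively correlated direction
    one = pearson_with_test(mkpairs(x, y), tail=Tail.ONE_TAILED_POSITIVE)
    two = pearson_with_test(mkpairs(x, y), tail=Tail.TWO_TAILED)
    if one.r > 0:
        assert one.p == pytest.approx(two.p / 2, rel=1e-9)


def test_pearson_guards():
    with pytest.raises(InsufficientDataError):
        pearson_with_test(mkpairs([1, 2], [1, 2]))
    with pytest.raises(InsufficientDataError):
        pearson_with_test(mkpairs([1, 1, 1], [1, 2, 3]))


def test_individual_approach_homogeneous_observers():
    """Every observer shows the same positive correlation."""
    per_obs = {}
    base_x = [0.0, 1.0, 2.0, 3.0, 4.0]
    base_y = [0.1, 1.2, 1.7, 3.4, 3.6]
    r_each = float(np.corrcoef(base_x, base_y)[0, 1])
    for o in range(6):
        per_obs[f"o{o}"] = mkpairs(base_x, base_y, observer=f"o{o}")
    summary = individual_approach(per_obs)
    assert summary.mean_r == pytest.approx(r_each, abs=1e-9)
    assert summary.t > 0
    assert summary.df == 5
    assert summary.p < 0.001


def test_individual_approach_symmetric_z_cancel():
    """Observers split between +r and -r give mean z 0, one-tailed p = .5."""
    x = [0.0, 1.0, 2.0, 3.0]
    y = [0.2, 0.8, 2.3, 2.9]
    per_obs = {
        "a": mkpairs(x, y, "a"),
        "b": mkpairs(x, [-v for v in y], "b"),
        "c": mkpairs(x, y, "c"),
        "d": mkpairs(x, [-v for v in y], "d"),
    }
    summary = individual_approach(per_obs)
    assert summary.t == pytest.approx(0.0, abs=1e-9)
    assert summary.p == pytest.approx(0.5, abs=1e-9)


def test_individual_approach_noiseless_model_data():
    """measured == predicted exactly: r = 1 everywhere; clamping keeps the
    observers and the t test is overwhelmingly positive, while clamp=False
    drops them all."""
    per_obs = {
        f"o{o}": mkpairs([0.1 * (i + o % 2) for i in range(4)],
                         [0.1 * (i + o % 2) for i in range(4)], f"o{o}")
        for o in range(5)
    }
    summary = individual_approach(per_obs, clamp=True)
    assert summary.p < 0.001
    assert summary.n_observers == 5
    with pytest.raises(InsufficientDataError):
        individual_approach(per_obs, clamp=False)


def test_individual_approach_drops_degenerate_observers():
    good_x, good_y = [0.0, 1.0, 2.0, 3.0], [0.2, 0.8, 2.3, 2.9]
    per_obs = {
        "a": mkpairs(good_x, good_y, "a"),
        "b": mkpairs(good_x, good_y, "b"),
        "flat": mkpairs(good_x, [0.5] * 4, "flat"),  # zero measured variance
        "tiny": mkpairs([1, 2], [1, 2], "tiny"),     # too few pairs
    }
    summary = individual_approach(per_obs)
    assert summary.n_observers == 2
    assert {obs for obs, _ in summary.dropped} == {"flat", "tiny"}


def test_individual_by_condition_averages_z_across_conditions():
    x, y = [0.0, 1.0, 2.0, 3.0], [0.2, 0.8, 2.3, 2.9]
    per_obs = {}
    for o in ("a", "b", "c"):
        per_obs[o] = (mkpairs(x, y, o, condition="photo")
                      + mkpairs(x, [-v for v in y], o, condition="outline"))
    summary = individual_approach(per_obs, by_condition=True)
    # +z and -z per observer average to 0
    assert summary.t == pytest.approx(0.0, abs=1e-9)


def test_pooled_df_matches_design():
    """15 observers x 8 stimuli pooled -> df = 118."""
    rng = np.random.default_rng(0)
    pairs = []
    for o in range(15):
        x = rng.normal(size=8)
        pairs += mkpairs(x, x + rng.normal(size=8), observer=f"o{o}")
    res = pooled_approach(pairs)
    assert res.df == 118
    assert res.n == 120


def test_pooled_between_observer_offsets_inflate_r(rng):
    """Shared per-observer offsets on both coordinates raise the pooled
    correlation above the within-observer one."""
    within = []
    pooled_pairs = []
    for o in range(12):
        x = rng.normal(size=6)
        y = x * 0.3 + rng.normal(size=6)
        within.append(np.corrcoef(x, y)[0, 1])
        offset = rng.normal(scale=4.0)
        pooled_pairs += mkpairs(x + offset, y + offset, observer=f"o{o}")
    pooled_r = pooled_approach(pooled_pairs).r
    assert pooled_r > np.mean(within)


@pytest.mark.parametrize("n_stimuli, df", [(7, 5), (16, 14)])
def test_aggregated_df(n_stimuli, df, rng):
    x = rng.normal(size=n_stimuli)
    res = aggregated_approach(mkpairs(x, x + rng.normal(size=n_stimuli),
                                      observer="aggregate"))
    assert res.df == df


def test_aggregated_rejects_duplicate_stimuli():
    pairs = mkpairs([1, 2, 3], [1, 2, 3]) + mkpairs([1, 2, 3], [1, 2, 3])
    with pytest.raises(Exception):
        aggregated_approach(pairs)


def test_relative_effects_mean_removal_and_idempotence():
    pairs = mkpairs([0.5, 0.6], [0.1, 0.3])
    rel = relative_effects(pairs)
    assert [p.measured for p in rel] == pytest.approx([-0.1, 0.1])
    assert [p.predicted for p in rel] == [0.5, 0.6]  # predicted untouched
    again = relative_effects(rel)
    assert [p.measured for p in again] == pytest.approx([-0.1, 0.1])


def test_relative_effects_removes_condition_offsets():
    photo = mkpairs([0.1, 0.2, 0.3], [0.2, 0.4, 0.6], condition="photo")
    outline = mkpairs([0.1, 0.2, 0.3], [0.0, 0.2, 0.4], condition="outline")
    rel = relative_effects(photo + outline)
    photo_rel = sorted(p.measured for p in rel if p.condition == "photo")
    outline_rel = sorted(p.measured for p in rel if p.condition == "outline")
    assert photo_rel == pytest.approx(outline_rel)


def test_relative_effects_preserves_rank_within_condition(rng):
    ys = rng.normal(size=6)
    pairs = mkpairs(rng.normal(size=6), ys)
    rel = relative_effects(pairs)
    assert list(np.argsort([p.measured for p in rel])) == list(np.argsort(ys))


def test_relative_effects_can_centre_predicted_too():
    pairs = mkpairs([0.5, 0.7], [0.1, 0.3])
    rel = relative_effects(pairs, centre_predicted=True)
    assert [p.predicted for p in rel] == pytest.approx([-0.1, 0.1])


def test_difference_test_hand_case():
    pairs = mkpairs([0.11, 0.22, 0.33], [0.10, 0.20, 0.30])
    res = difference_test(pairs)
    assert res.delta == pytest.approx(0.02)
    assert res.t == pytest.approx(0.02 / (0.01 / math.sqrt(3)), rel=1e-6)
    assert res.df == 2


def test_difference_test_df_and_degenerate():
    pairs = mkpairs(range(7), range(7))
    res = difference_test(pairs)
    assert res.df == 6
    assert res.delta == 0.0
    assert res.t == 0.0
    with pytest.raises(InsufficientDataError):
        difference_test(pairs[:1])
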