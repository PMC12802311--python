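"""Population summaries, rank-sum tests, regression, trajectories."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import swarmetrics as sw
from swarmetrics.popstats import summaries_to_frame


def _table(groups: dict, feature="length_um"):
    rows = []
    for g, vals in groups.items():
        for v in vals:
            rows.append({"hour": g, feature: v})
    return pd.DataFrame(rows)


def test_hand_computed_summary():
    df = _table({2: [2.0, 2.0, 4.0, 4.0]})
    (s,) = sw.summarize_population(df, "hour")
    assert s.median == 3.0
    assert s.variance == pytest.approx(4.0 / 3.0)
    assert s.long_fraction == 0.0
    assert s.q1 <= s.median <= s.q3
    assert s.variance_ci[0] <= s.variance <= s.variance_ci[1]


def test_duplicated_group_identical_summaries():
    vals = list(np.random.default_rng(0).normal(3, 1, 50))
    df = _table({1: vals, 2: vals})
    s1, s2 = sw.summarize_population(df, "hour", seed=5)
    for attr in ("n", "median", "q1", "q3", "min", "max", "variance", "long_fraction"):
        assert getattr(s1, attr) == getattr(s2, attr)


def test_summary_bootstrap_deterministic():
    df = _table({1: list(np.random.default_rng(1).normal(3, 1, 80))})
    a = sw.summarize_population(df, "hour", seed=9)[0]
    b = sw.summarize_population(df, "hour", seed=9)[0]
    assert a.variance_ci == b.variance_ci


def test_undersized_group_warns_and_is_omitted():
    df = _table({1: [1.0], 2: [2.0, 3.0, 4.0]})
    with pytest.warns(UserWarning):
        out = sw.summarize_population(df, "hour")
    assert [s.group for s in out] == [2]


def _u_oracle(a, b):
    """Exact two-sided rank-sum p by direct pairwise-comparison enumeration.

    U(a) = #(x > y) + 0.5·#(x = y) over all cross pairs; the null distribution
    is built by enumerating every split of the pooled sample.
    """
    pooled = np.concatenate([a, b])
    na = len(a)
    n = len(pooled)

    def u_of(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        gt = (x[:, None] > y[None, :]).sum()
        eq = (x[:, None] == y[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(na))
    mu = na * (n - na) / 2.0
    d = abs(u_obs - mu)
    hits = sum(1 for idx in combinations(range(n), na) if abs(u_of(idx) - mu) >= d - 1e-9)
    return hits / comb(n, na)


def test_exact_p_for_separated_triples():
    df = _table({"a": [1, 2, 3], "b": [4, 5, 6]})
    (res,) = sw.pairwise_wilcoxon(df, "hour")
    assert res.p_raw == pytest.approx(0.1)
    assert res.p_adjusted >= res.p_raw


def test_identical_groups_high_p():
    df = _table({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
    (res,) = sw.pairwise_wilcoxon(df, "hour")
    assert res.p_raw > 0.9


def test_pair_count_combinatorics():
    rng = np.random.default_rng(3)
    df = _table({g: list(rng.normal(g, 1, 12)) for g in range(5)})
    results = sw.pairwise_wilcoxon(df, "hour")
    assert len(results) == 5 * 4 // 2
    assert all(r.p_adjusted >= r.p_raw for r in results)


@given(
    na=st.integers(2, 7),
    nb=st.integers(2, 7),
    seed=st.integers(0, 10_000),
    ties=st.booleans(),
)
def test_rank_sum_matches_enumeration_oracle(na, nb, seed, ties):
    """Implementation agrees with exhaustive permutation enumeration for sizes ≤ 7."""
    rng = np.random.default_rng(seed)
    if ties:
        a = rng.integers(0, 4, na).astype(float)
        b = rng.integers(0, 4, nb).astype(float)
    else:
        a = rng.normal(0, 1, na)
        b = rng.normal(1, 1, nb)
    df = _table({"a": list(a), "b": list(b)})
    (res,) = sw.pairwise_wilcoxon(df, "hour")
    assert res.p_raw == pytest.approx(_u_oracle(a, b), abs=1e-9)


def test_noiseless_regression():
    x = np.linspace(1, 10, 30)
    df = pd.DataFrame({"length_um": x, "mean_intensity_au": 2 * x + 1})
    reg = sw.regress_intensity_on_length(df)
    assert reg.slope == pytest.approx(2.0)
    assert reg.intercept == pytest.approx(1.0)
    assert reg.r_squared_adjusted == pytest.approx(1.0)


def test_null_slope_within_three_se(rng):
    x = rng.uniform(1, 10, 1000)
    y = rng.normal(0, 1, 1000)
    df = pd.DataFrame({"length_um": x, "mean_intensity_au": y})
    reg = sw.regress_intensity_on_length(df)
    se = 1.0 / (np.std(x) * np.sqrt(1000))
    assert abs(reg.slope) < 3 * se


def test_regression_errors():
    with pytest.raises(ValueError):
        sw.regress_intensity_on_length(
            pd.DataFrame({"length_um": [1, 2], "mean_intensity_au": [1, 2]})
        )
    with pytest.raises(ValueError):
        sw.regress_intensity_on_length(
            pd.DataFrame({"length_um": [2, 2, 2], "mean_intensity_au": [1, 2, 3]})
        )


def test_regression_rescaling_equivariance():
    pop = sw.sample_fluorescence_population(500, seed=4)
    reg = sw.regress_intensity_on_length(pop)
    scaled = pop.copy()
    scaled["length_um"] *= 10.0
    reg_s = sw.regress_intensity_on_length(scaled)
    assert reg_s.slope == pytest.approx(reg.slope / 10.0, rel=1e-9)
    assert reg_s.r_squared_adjusted == pytest.approx(reg.r_squared_adjusted, rel=1e-9)


def test_subpopulation_trajectory_sums_to_one():
    rng = np.random.default_rng(6)
    df = _table({h: list(rng.uniform(1.5, 9.0, 60)) for h in range(2, 7)})
    summaries = sw.summarize_population(df, "hour")
    traj = sw.subpopulation_trajectory(summaries)
    assert np.allclose(traj["long_fraction"] + traj["short_fraction"], 1.0, atol=1e-12)
    all_long = sw.summarize_population(_table({1: [5.0, 6.0, 7.0]}), "hour")
    t = sw.subpopulation_trajectory(all_long)
    assert t.loc[0, "long_fraction"] == 1.0 and t.loc[0, "short_fraction"] == 0.0


def test_timecourse_long_fraction_peaks_at_hour_six_end_to_end():
    rng = np.random.default_rng(8)
    frames = []
    for hour in range(2, 9):
        cfg = sw.timecourse_presets(hour)
        n = 400
        is_long = rng.random(n) < cfg.long_fraction
        lengths = np.where(
            is_long,
            cfg.long_length_dist.sample(rng, n),
            cfg.short_length_dist.sample(rng, n),
        )
        frames.append(pd.DataFrame({"hour": hour, "length_um": lengths}))
    df = sw.classify_length(pd.concat(frames, ignore_index=True))
    traj = sw.subpopulation_trajectory(sw.summarize_population(df, "hour"))
    peak = traj.loc[traj["long_fraction"].idxmax(), "group"]
    assert peak == 6


def test_summaries_frame_round_trip():
    df = _table({1: [1.0, 2.0, 3.0], 2: [4.0, 5.0, 6.0]})
    frame = summaries_to_frame(sw.summarize_population(df, "hour"))
    assert set(frame.columns) >= {"group", "n", "median", "variance", "long_fraction"}
    assert len(frame) == 2
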