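"""Group-level inference: BCa bootstrap, comparisons, associations,
violation contingency test."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import bootstrap as scipy_bootstrap, fisher_exact

from wktap import (StatsError, association, bca_ci, compare_groups,
                   drift_direction_interaction, fisher_exact_rx2,
                   violation_test)


def _mean_diff(data):
    y, g = data[:, 0], data[:, 1]
    return float(y[g == 1].mean() - y[g == 0].mean())


# ---------------------------------------------------------------------------
# BCa bootstrap


def test_bca_close_to_percentile_for_symmetric_mean():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(60)
    data = y[:, None]
    stat = lambda d: float(d[:, 0].mean())
    ci = bca_ci(stat, data, n_boot=2000, seed=1)
    # reference percentile interval from an identical resampling scheme
    rng2 = np.random.default_rng(1)
    thetas = [stat(data[rng2.integers(0, 60, 60)]) for _ in range(2000)]
    lo, hi = np.quantile(thetas, [0.025, 0.975])
    width = hi - lo
    assert abs(ci.low - lo) < 0.15 * width and abs(ci.high - hi) < 0.15 * width


def test_bca_constant_data_zero_width_flagged():
    data = np.ones((10, 1))
    ci = bca_ci(lambda d: float(d.mean()), data, n_boot=500, seed=0)
    assert ci.low == ci.high == 1.0
    assert "degenerate" in ci.flags


def test_bca_reproducible_bit_for_bit():
    rng = np.random.default_rng(5)
    data = np.column_stack([rng.standard_normal(40), np.repeat([0., 1.], 20)])
    a = bca_ci(_mean_diff, data, n_boot=600, seed=9, strata=data[:, 1])
    b = bca_ci(_mean_diff, data, n_boot=600, seed=9, strata=data[:, 1])
    assert (a.low, a.high) == (b.low, b.high)


def test_bca_matches_scipy_on_two_sample_mean_difference():
    rng = np.random.default_rng(7)
    a_s = rng.standard_normal(25)
    b_s = rng.standard_normal(25) + 0.5
    g = np.repeat([0.0, 1.0], 25)
    data = np.column_stack([np.concatenate([a_s, b_s]), g])
    mine = bca_ci(_mean_diff, data, n_boot=4000, seed=3, strata=g)
    ref = scipy_bootstrap((b_s, a_s),
                          lambda x, y, axis=-1: x.mean(axis=axis) - y.mean(axis=axis),
                          n_resamples=4000, method="BCa", random_state=3)
    width = ref.confidence_interval.high - ref.confidence_interval.low
    assert mine.low == pytest.approx(ref.confidence_interval.low, abs=0.1 * width)
    assert mine.high == pytest.approx(ref.confidence_interval.high, abs=0.1 * width)


def test_bca_input_validation():
    data = np.ones((2, 1))
    with pytest.raises(StatsError, match="3 observations"):
        bca_ci(lambda d: 0.0, data, n_boot=500, seed=0)
    with pytest.raises(StatsError, match="n_boot"):
        bca_ci(lambda d: 0.0, np.ones((10, 1)), n_boot=50, seed=0)


# ---------------------------------------------------------------------------
# group comparisons


def test_identical_groups_give_null_difference(synthetic_metric_table):
    results, cohort = synthetic_metric_table(n_ref=40, n_cmp=40, shift=0.0,
                                             sd_ref=100.0, sd_cmp=100.0, seed=0)
    res = compare_groups(results, cohort, "mean_iri", "control", "bvFTD",
                         adjust=True, n_boot=500, seed=0,
                         condition="self_paced")
    assert abs(res.adjusted_diff) < 70.0
    assert res.ci_low <= 0.0 <= res.ci_high


def test_known_shift_recovered(synthetic_metric_table):
    """A -175 ms generated difference is recovered across replicates."""
    estimates, covered = [], 0
    for seed in range(5):
        results, cohort = synthetic_metric_table(shift=-175.0, seed=seed)
        res = compare_groups(results, cohort, "mean_iri", "control", "bvFTD",
                             adjust=True, n_boot=500, seed=seed,
                             condition="self_paced")
        estimates.append(res.adjusted_diff)
        covered += res.ci_low <= -175.0 <= res.ci_high
    assert np.mean(estimates) == pytest.approx(-175.0, abs=50.0)
    assert covered >= 3


def test_constant_metric_flagged(synthetic_metric_table):
    results, cohort = synthetic_metric_table(seed=1)
    results["mean_iri"] = 1500.0
    res = compare_groups(results, cohort, "mean_iri", "control", "bvFTD",
                         n_boot=300, seed=0, condition="self_paced")
    assert res.adjusted_diff == pytest.approx(0.0, abs=1e-9)
    assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)
    assert "zero_variance_metric" in res.flags


def test_tiny_group_errors(synthetic_metric_table):
    results, cohort = synthetic_metric_table(n_cmp=1, seed=2)
    with pytest.raises(StatsError, match="fewer than 2"):
        compare_groups(results, cohort, "mean_iri", "control", "bvFTD",
                       n_boot=300, seed=0, condition="self_paced")


def test_unadjusted_equals_raw_mean_difference(synthetic_metric_table):
    results, cohort = synthetic_metric_table(seed=3)
    res = compare_groups(results, cohort, "mean_iri", "control", "bvFTD",
                         adjust=False, n_boot=300, seed=0,
                         condition="self_paced")
    raw = (results.loc[results.group == "bvFTD", "mean_iri"].mean()
           - results.loc[results.group == "control", "mean_iri"].mean())
    assert res.unadjusted_diff == pytest.approx(raw, rel=1e-9)


# ---------------------------------------------------------------------------
# drift-direction interaction


def _drift_tables(n=100, inflate_negative=1.0, seed=0):
    rng = np.random.default_rng(seed)
    groups = ["control"] * n + ["bvFTD"] * n
    drift = rng.normal(0, 80, 2 * n)
    absd = np.abs(drift).copy()
    patient_neg = (np.arange(2 * n) >= n) & (drift < 0)
    absd[patient_neg] *= inflate_negative
    results = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(2 * n)],
        "group": groups, "condition": "self_paced",
        "drift_ms": np.where(drift < 0, -absd, absd), "abs_drift_ms": absd,
        "rho1": rng.uniform(-0.5, 0.2, 2 * n), "mean_iri": 1500.0,
    })
    cohort = pd.DataFrame({
        "participant_id": results.participant_id, "group": groups,
        "age": rng.normal(64, 8, 2 * n).round(1),
        "gender": rng.choice(["M", "F"], 2 * n),
    })
    return results, cohort


def test_symmetric_drifts_show_no_interaction():
    results, cohort = _drift_tables(seed=4)
    res = drift_direction_interaction(results, cohort, ("control", "bvFTD"),
                                      n_boot=400, seed=0,
                                      condition="self_paced")
    assert res.ci_interaction[0] <= 0.0 <= res.ci_interaction[1]


def test_negative_drift_inflation_detected():
    results, cohort = _drift_tables(inflate_negative=2.5, seed=5)
    res = drift_direction_interaction(results, cohort, ("control", "bvFTD"),
                                      n_boot=400, seed=0,
                                      condition="self_paced")
    assert res.interaction > 0
    assert res.ci_interaction[0] > 0.0


def test_one_signed_group_errors():
    results, cohort = _drift_tables(seed=6)
    results.loc[results.group == "bvFTD", "drift_ms"] = \
        np.abs(results.loc[results.group == "bvFTD", "drift_ms"])
    with pytest.raises(StatsError, match="bvFTD.*negative"):
        drift_direction_interaction(results, cohort, ("control", "bvFTD"),
                                    n_boot=300, seed=0,
                                    condition="self_paced")


# ---------------------------------------------------------------------------
# associations


def test_independent_score_has_null_slope(synthetic_metric_table):
    results, cohort = synthetic_metric_table(shift=0.0, seed=7)
    res = association(results, cohort, "mean_iri", "digit_span_backwards",
                      ("control", "bvFTD"), with_interaction=False,
                      n_boot=400, seed=0, condition="self_paced")
    assert res.ci_pooled[0] <= 0.0 <= res.ci_pooled[1]


def test_shared_slope_recovered_and_interaction_null(synthetic_metric_table):
    """A +39 ms-per-point slope common to both groups is recovered."""
    results, cohort = synthetic_metric_table(n_ref=100, n_cmp=100, shift=0.0,
                                             sd_ref=60.0, sd_cmp=60.0, seed=8)
    results = results.merge(cohort[["participant_id", "digit_span_backwards"]],
                            on="participant_id")
    results["mean_iri"] += 39.0 * results.pop("digit_span_backwards")
    pooled = association(results, cohort, "mean_iri", "digit_span_backwards",
                         ("control", "bvFTD"), with_interaction=False,
                         n_boot=400, seed=0, condition="self_paced")
    assert pooled.pooled_slope == pytest.approx(39.0, abs=8.0)
    inter = association(results, cohort, "mean_iri", "digit_span_backwards",
                        ("control", "bvFTD"), with_interaction=True,
                        n_boot=400, seed=0, condition="self_paced")
    assert inter.ci_interaction[0] <= 0.0 <= inter.ci_interaction[1]
    assert inter.interaction == pytest.approx(
        inter.slope_patient - inter.slope_control, rel=1e-9)


def test_patient_only_slope_detected(synthetic_metric_table):
    results, cohort = synthetic_metric_table(n_ref=100, n_cmp=100, shift=0.0,
                                             sd_ref=40.0, sd_cmp=40.0, seed=9)
    results = results.merge(cohort[["participant_id", "digit_span_backwards"]],
                            on="participant_id")
    span = results.pop("digit_span_backwards")
    results.loc[results.group == "bvFTD", "mean_iri"] += \
        25.0 * span[results.group == "bvFTD"]
    res = association(results, cohort, "mean_iri", "digit_span_backwards",
                      ("control", "bvFTD"), with_interaction=True,
                      n_boot=400, seed=0, condition="self_paced")
    assert res.ci_interaction[0] > 0.0


def test_missing_scores_dropped_and_counted(synthetic_metric_table):
    results, cohort = synthetic_metric_table(seed=10)
    cohort.loc[cohort.index[:4], "digit_span_backwards"] = np.nan
    res = association(results, cohort, "mean_iri", "digit_span_backwards",
                      ("control", "bvFTD"), with_interaction=False,
                      n_boot=300, seed=0, condition="self_paced")
    assert res.n_dropped == 4 and res.n_used == len(results) - 4


def test_constant_score_errors(synthetic_metric_table):
    results, cohort = synthetic_metric_table(seed=11)
    cohort["digit_span_backwards"] = 6.0
    with pytest.raises(StatsError, match="constant"):
        association(results, cohort, "mean_iri", "digit_span_backwards",
                    ("control", "bvFTD"), n_boot=300, seed=0,
                    condition="self_paced")


# ---------------------------------------------------------------------------
# violation contingency test


def _brute_fisher_rx2(table):
    """Full enumeration oracle: sum of hypergeometric masses <= observed."""
    table = np.asarray(table)
    sizes = table.sum(axis=1)
    A, N = table[:, 0].sum(), sizes.sum()

    def prob(a):
        return np.prod([comb(n, x) for n, x in zip(sizes, a)]) / comb(N, A)

    p_obs = prob(table[:, 0])
    total = 0.0
    for a in itertools.product(*[range(n + 1) for n in sizes]):
        if sum(a) == A and prob(a) <= p_obs * (1 + 1e-9):
            total += prob(a)
    return total


@pytest.mark.parametrize("table", [
    [[1, 9], [8, 2]],
    [[3, 7], [9, 1]],
    [[2, 8], [5, 5], [9, 1]],
    [[4, 4], [4, 4], [4, 4]],
])
def test_fisher_rx2_matches_enumeration_oracle(table):
    p, method = fisher_exact_rx2(np.array(table))
    assert method == "enumeration"
    assert p == pytest.approx(_brute_fisher_rx2(table), rel=1e-9)


@pytest.mark.parametrize("table", [[[1, 9], [8, 2]], [[5, 5], [5, 5]],
                                   [[3, 7], [9, 1]]])
def test_fisher_2x2_matches_scipy(table):
    p, _ = fisher_exact_rx2(np.array(table))
    assert p == pytest.approx(fisher_exact(table).pvalue, rel=1e-9)


def test_fisher_monte_carlo_close_to_exact():
    table = np.array([[3, 7], [9, 1]])
    exact, _ = fisher_exact_rx2(table)
    mc, method = fisher_exact_rx2(table, seed=0, enumeration_limit=5)
    assert method == "monte_carlo"
    assert mc == pytest.approx(exact, abs=0.01)


def test_violation_test_counts_and_degenerate_cases(synthetic_metric_table):
    results, _ = synthetic_metric_table(seed=12)
    res = violation_test(results, ["control", "bvFTD"],
                         condition="self_paced")
    assert set(res.table.index) == {"control", "bvFTD"}
    assert res.table.to_numpy().sum() == len(results)
    assert 0.0 <= res.p_value <= 1.0

    results["rho1"] = -0.2    # nobody violates
    res = violation_test(results, ["control", "bvFTD"],
                         condition="self_paced")
    assert res.p_value == 1.0 and res.method == "degenerate"

    # identical proportions in duplicated balanced rows
    p, _ = fisher_exact_rx2(np.array([[4, 6], [4, 6]]))
    assert p == pytest.approx(1.0, rel=1e-9)


def test_violation_test_empty_group_errors(synthetic_metric_table):
    results, _ = synthetic_metric_table(seed=13)
    with pytest.raises(StatsError, match="empty group"):
        violation_test(results, ["control", "nonexistent"],
                       condition="self_paced")
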