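"""Fisher's exact, group comparisons, cutoff scan, KM, Cox and LOO CV."""
import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from immunogradient.cohort_stats import (
    compare_groups,
    cox_model,
    filter_cohort,
    fisher_exact_2x2,
    km_logrank,
    loo_cross_validate,
    optimal_cutoff,
)
from immunogradient.errors import DegenerateTableError, NoCutoffError, ParameterError
from immunogradient.synthetic import SimConfig, simulate_cohort


def fisher_enumeration_oracle(table):
    """Exact two-sided p by complete enumeration of tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    total = 0.0
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(aa, n, c1, r1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


@pytest.mark.parametrize(
    "table",
    [
        [[3, 5], [7, 2]],
        [[10, 10], [10, 10]],
        [[1, 20], [15, 4]],
        [[8, 0], [3, 9]],
        [[25, 30], [28, 22]],
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    _, p = fisher_exact_2x2(table)
    assert p == pytest.approx(fisher_enumeration_oracle(table), rel=1e-9)


def test_fisher_balanced_table_p_one_and_zero_margin():
    _, p = fisher_exact_2x2([[10, 10], [10, 10]])
    assert p == 1.0
    with pytest.raises(DegenerateTableError):
        fisher_exact_2x2([[0, 0], [5, 5]])


def test_filter_cohort_counts():
    df = pd.DataFrame({"case_id": range(10)})
    df["preoperative_treatment"] = [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
    df["mucinous"] = [0, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    remaining, summary = filter_cohort(df)
    assert summary["n_retrieved"] == 10
    assert summary["excluded_preoperative_treatment"] == 1
    assert summary["excluded_mucinous"] == 2
    assert summary["n_analyzed"] == 7 == len(remaining)


def test_compare_groups_identical_and_separated(rng):
    same = rng.normal(0, 1, 40)
    rep = compare_groups({"a": same, "b": same.copy()})
    assert rep["anova"]["F"] == pytest.approx(0.0, abs=1e-12)
    assert rep["pairwise"]["a|b"]["p_raw"] == pytest.approx(1.0)
    sep = compare_groups({"a": rng.normal(0, 1, 50), "b": rng.normal(2, 1, 50)})
    assert sep["pairwise"]["a|b"]["p_raw"] < 1e-6


def test_compare_groups_bonferroni_and_log_transform(rng):
    groups = {k: rng.lognormal(0, 1, 30) for k in "abc"}
    rep = compare_groups(groups, log_transform=True)
    k = 3
    for pair in rep["pairwise"].values():
        assert pair["p_bonferroni"] == pytest.approx(min(1.0, k * pair["p_raw"]))
    # log transform applied: recompute Welch on ln(x+1) by hand for one pair
    t, p = stats.ttest_ind(np.log(groups["a"] + 1), np.log(groups["b"] + 1), equal_var=False)
    assert rep["pairwise"]["a|b"]["p_raw"] == pytest.approx(p)


def test_compare_groups_degenerate_variance():
    rep = compare_groups({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0]})
    assert rep["degenerate_variance"]
    assert rep["anova"]["p"] == 1.0


def _two_cluster_cohort(rng, n=60):
    """Well-separated indicator clusters with sharply different survival."""
    risk = np.repeat([0, 1], n // 2)
    values = np.where(risk == 0, rng.normal(10, 0.5, n), rng.normal(0, 0.5, n))
    t = np.where(risk == 0, rng.exponential(100, n), rng.exponential(5, n))
    e = np.ones(n, int)
    return values, t, e


def test_optimal_cutoff_falls_between_clusters(rng):
    values, t, e = _two_cluster_cohort(rng)
    res = optimal_cutoff(values, t, e, indicator="x")
    assert 2.0 < res.cutoff < 8.0
    assert res.high_is_favorable
    assert res.exploratory


def test_optimal_cutoff_matches_exhaustive_oracle(rng):
    n = 50
    values = rng.normal(0, 1, n)
    t = rng.exponential(20, n)
    e = rng.binomial(1, 0.7, n)
    res = optimal_cutoff(values, t, e)
    # independent exhaustive scan
    distinct = np.unique(values)
    best_p, best_c = np.inf, None
    for c in (distinct[:-1] + distinct[1:]) / 2:
        hi = values > c
        if hi.sum() < 0.1 * n or (~hi).sum() < 0.1 * n:
            continue
        p = logrank_test(t[hi], t[~hi], e[hi], e[~hi]).p_value
        if p < best_p - 1e-15:
            best_p, best_c = p, c
    assert res.cutoff == pytest.approx(best_c)
    assert res.p_value == pytest.approx(best_p)


def test_constant_indicator_has_no_cutoff():
    with pytest.raises(NoCutoffError):
        optimal_cutoff(np.ones(30), np.arange(1, 31), np.ones(30, int))


def test_km_no_censoring_equals_empirical(rng):
    t = rng.exponential(30, 80)
    e = np.ones(80, int)
    out = km_logrank(np.zeros(80, int), t, e, t_months=20.0)
    emp = (t > 20.0).mean()
    assert out["strata"][0]["os_20m"] == pytest.approx(emp)


def test_logrank_zero_for_duplicated_group(rng):
    t = np.concatenate([rng.exponential(30, 50)] * 2)
    e = np.ones(100, int)
    g = np.repeat([0, 1], 50)
    out = km_logrank(g, t, e)
    assert out["logrank_statistic"] == pytest.approx(0.0, abs=1e-9)
    assert out["logrank_p"] == pytest.approx(1.0)


def test_logrank_detects_hr2_exponential(rng):
    n = 500
    t = np.concatenate([rng.exponential(40, n), rng.exponential(20, n)])
    e = np.ones(2 * n, int)
    g = np.repeat([0, 1], n)
    out = km_logrank(g, t, e)
    assert out["logrank_p"] < 1e-4


def _cox_df(rng, n=400, true_hr=0.3, censor=40.0):
    x = rng.binomial(1, 0.5, n)
    haz = 0.03 * true_hr**x
    t_ev = rng.exponential(1 / haz)
    c = rng.uniform(0, censor * 2, n)
    return pd.DataFrame(
        {"t": np.minimum(t_ev, c), "e": (t_ev <= c).astype(int), "x": x}
    )


def test_cox_recovers_true_hr(rng):
    df = _cox_df(rng)
    res = cox_model(df, "t", "e", ["x"])
    hr = res.terms.loc["x", "HR"]
    assert 0.2 <= hr <= 0.45
    assert res.terms.loc["x", "CI_lower"] <= hr <= res.terms.loc["x", "CI_upper"]
    assert res.lr_statistic > 0


def test_cox_parameter_recovery_across_replicates():
    """Mean estimated lnHR within 0.1 of ln 0.3 over 100 fixed-seed fits."""
    estimates = []
    for seed in range(100):
        df = _cox_df(np.random.default_rng(seed), n=300)
        res = cox_model(df, "t", "e", ["x"])
        estimates.append(np.log(res.terms.loc["x", "HR"]))
    assert abs(np.mean(estimates) - np.log(0.3)) < 0.1


def test_stepwise_rarely_selects_pure_noise():
    selected = 0
    n_rep = 200
    for seed in range(n_rep):
        rng = np.random.default_rng(10_000 + seed)
        df = _cox_df(rng, n=400, true_hr=1.0)
        df["noise"] = rng.normal(size=len(df))
        res = cox_model(df, "t", "e", ["noise"], stepwise=True)
        selected += "noise" in res.selected
    assert selected / n_rep <= 0.10


def test_stepwise_keeps_signal_drops_noise(rng):
    df = _cox_df(rng, n=400, true_hr=0.3)
    df["noise"] = rng.normal(size=len(df))
    res = cox_model(df, "t", "e", ["x", "noise"], stepwise=True)
    assert "x" in res.selected
    assert res.trace


def test_zero_variance_covariate_excluded(rng):
    df = _cox_df(rng, n=100)
    df["const"] = 1.0
    res = cox_model(df, "t", "e", ["x", "const"])
    assert "const" not in res.terms.index
    assert any("zero variance" in w for w in res.warnings)


def test_missing_covariate_rejected(rng):
    df = _cox_df(rng, n=50)
    df.loc[0, "x"] = np.nan
    with pytest.raises(ParameterError):
        cox_model(df, "t", "e", ["x"])


def test_loo_perfect_predictor_concordance(rng):
    # continuous, perfectly rank-predictive risk: time decreasing in x
    n = 40
    x = rng.uniform(0, 1, n)
    t = 50.0 * np.exp(-3 * x)
    df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x})
    out = loo_cross_validate(df, "t", "e", ["x"])
    assert out["completion_fraction"] == 1.0
    assert out["cv_concordance"] == pytest.approx(1.0)


def test_loo_noise_concordance_near_half_and_deterministic():
    rng = np.random.default_rng(3)
    n = 60
    df = pd.DataFrame(
        {"t": rng.exponential(20, n), "e": np.ones(n, int), "x": rng.normal(size=n)}
    )
    out1 = loo_cross_validate(df, "t", "e", ["x"])
    out2 = loo_cross_validate(df, "t", "e", ["x"])
    assert out1 == out2
    assert abs(out1["cv_concordance"] - 0.5) < 0.1
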