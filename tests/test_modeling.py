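"""Prediction models: AUC/DeLong, stepwise logistic, bootstrap, power."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enrichprs import (
    CpspPredictionModel,
    bootstrap_validate,
    compare_auc,
    delong_test,
    fit_stepwise_logistic,
    power_two_means,
    power_two_proportions,
    power_variant_or,
    probability_curve,
    proportion_or,
    roc_auc,
)
from enrichprs.modeling import PerfectSeparationError


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

def test_auc_perfect_and_anti_predictor():
    y = np.array([0, 0, 0, 1, 1])
    auc, (lo, hi) = roc_auc([0.1, 0.2, 0.3, 0.8, 0.9], y)
    assert auc == 1.0 and hi == 1.0
    auc, _ = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], y)
    assert auc == 0.0


def test_auc_null_scores_near_half():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 2000)
    auc, (lo, hi) = roc_auc(rng.normal(size=2000), y)
    assert abs(auc - 0.5) < 0.03
    assert lo < 0.5 < hi


def _pairwise_auc_oracle(scores, y):
    """Exhaustive comparison of every case-control pair, ties = 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(8))
def test_auc_equals_exhaustive_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 51))
    y = np.r_[np.ones(max(2, n // 3), dtype=int), np.zeros(n, dtype=int)]
    # coarse scores force ties
    scores = rng.integers(0, 6, size=len(y)).astype(float)
    auc, _ = roc_auc(scores, y)
    assert auc == pytest.approx(_pairwise_auc_oracle(scores, y), abs=1e-12)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], np.array([1, 1]))


# --------------------------------------------------------------------------
# DeLong comparison
# --------------------------------------------------------------------------

def test_identical_scores_compare_equal():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 100)
    s = rng.normal(size=100)
    diff, p = delong_test(y, s, s)
    assert diff == 0.0
    assert p == 1.0


def test_delong_detects_a_clearly_better_model():
    rng = np.random.default_rng(2)
    n = 400
    y = rng.integers(0, 2, n)
    good = y + rng.normal(0, 0.5, n)
    bad = rng.normal(size=n)
    diff, p = delong_test(y, good, bad)
    assert diff > 0.2
    assert p < 1e-6


def test_delong_null_pvalues_are_uniform():
    """Two independent null score vectors: the comparison p-value is
    U(0,1) across replicates (KS check)."""
    rng = np.random.default_rng(3)
    pvals = []
    for _ in range(500):
        y = rng.integers(0, 2, 120)
        if y.sum() in (0, 120):
            continue
        _, p = delong_test(y, rng.normal(size=120), rng.normal(size=120))
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_paired_comparison_rejects_mismatched_individuals():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({
        "individual_id": [f"S{i}" for i in range(80)],
        "cpsp": rng.integers(0, 2, 80),
        "x": rng.normal(size=80),
    })
    fit_a = CpspPredictionModel(df).fit(["x"])
    fit_b = CpspPredictionModel(df.iloc[::-1].reset_index(drop=True)).fit(["x"])
    with pytest.raises(ValueError, match="same individuals"):
        compare_auc(fit_a, fit_b)


def test_genetic_model_beats_clinical_when_prs_signal_planted():
    """Planted PRS effect at n = 300: the paired DeLong comparison is
    significant in at least 90% of 50 seeds."""
    wins = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n = 300
        casi = rng.normal(0, 1, n)
        prs = rng.normal(0, 1, n)
        eta = 0.35 * casi + 1.5 * prs - 0.3
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        if y.sum() in (0, n):
            continue
        df = pd.DataFrame({"individual_id": range(n), "cpsp": y.astype(int),
                           "casi": casi, "prs": prs})
        model = CpspPredictionModel(df)
        clinical = model.fit(["casi"])
        genetic = model.fit(["casi", "prs"])
        p = compare_auc(genetic, clinical)
        wins += (genetic.auc > clinical.auc) and (p < 0.05)
    assert wins >= 45


# --------------------------------------------------------------------------
# stepwise logistic
# --------------------------------------------------------------------------

def _clinical_frame(n=160, seed=0, casi_beta=0.25):
    rng = np.random.default_rng(seed)
    casi = rng.normal(28, 5, n)
    preop = np.clip(rng.normal(0.6, 1.2, n), 0, 10)
    eta = casi_beta * (casi - 28) - 0.4
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"individual_id": range(n), "cpsp": y,
                         "casi": casi, "preop_pain": preop})


def test_stepwise_keeps_the_real_predictor_and_drops_noise():
    df = _clinical_frame(seed=1)
    fit = fit_stepwise_logistic(df, ["casi", "preop_pain"])
    assert fit.terms == ["casi"]
    assert fit.odds_ratios["casi"] > 1
    assert fit.pvalues["casi"] < 0.05


def test_stepwise_null_candidates_yield_intercept_only():
    kept = 0
    for seed in range(40):
        df = _clinical_frame(seed=100 + seed, casi_beta=0.0)
        fit = fit_stepwise_logistic(df, ["casi", "preop_pain"])
        kept += len(fit.terms) == 0
    assert kept >= 32  # ~1 - (1 - 0.95^2) familywise entry chance


def test_stepwise_detects_perfect_separation():
    n = 40
    x = np.r_[np.zeros(20), np.ones(20)]
    df = pd.DataFrame({"individual_id": range(n), "cpsp": x.astype(int), "x": x})
    with pytest.raises(PerfectSeparationError):
        CpspPredictionModel(df).fit(["x"])


def test_model_summary_reports_or_equal_exp_beta():
    df = _clinical_frame(seed=5)
    fit = CpspPredictionModel(df).fit(["casi", "preop_pain"])
    summary = fit.summary().set_index("term")
    for term in ("casi", "preop_pain"):
        assert summary.at[term, "or"] == pytest.approx(np.exp(fit.params[term]))
    assert 0 <= summary.attrs["auc"] <= 1
    assert fit.intercept == pytest.approx(fit.params["const"])


# --------------------------------------------------------------------------
# probability curve
# --------------------------------------------------------------------------

def test_probability_curve_closed_form_crossing_and_monotonicity():
    rng = np.random.default_rng(7)
    n = 400
    casi = rng.normal(28, 5, n)
    prs = rng.normal(21, 4, n)
    eta = 0.2 * (casi - 28) + 0.8 * (prs - 21) - 0.4
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({"individual_id": range(n), "cpsp": y, "casi": casi, "prs": prs})
    fit = CpspPredictionModel(df).fit(["casi", "prs"])
    grid = np.linspace(5, 35, 601)
    curve, crossing = probability_curve(fit, "prs", grid, {"casi": 28.3})
    assert fit.params["prs"] > 0
    assert (np.diff(curve["probability"]) > 0).all()
    assert ((curve["ci_low"] <= curve["probability"])
            & (curve["probability"] <= curve["ci_high"])).all()
    # closed form matches a grid search for the 50% crossing
    expected = -(fit.intercept + fit.params["casi"] * 28.3) / fit.params["prs"]
    assert crossing == pytest.approx(expected)
    nearest = grid[np.argmin(np.abs(curve["probability"] - 0.5))]
    assert abs(nearest - crossing) <= (grid[1] - grid[0])
    # probability is exactly 0.5 where the linear predictor vanishes
    at_crossing, _ = probability_curve(fit, "prs", [crossing], {"casi": 28.3})
    assert at_crossing["probability"].iloc[0] == pytest.approx(0.5)


def test_probability_curve_requires_fixed_values_for_other_terms():
    df = _clinical_frame(seed=8)
    fit = CpspPredictionModel(df).fit(["casi", "preop_pain"])
    with pytest.raises(ValueError, match="fixed values"):
        probability_curve(fit, "casi", [25, 30], {})


# --------------------------------------------------------------------------
# bootstrap validation
# --------------------------------------------------------------------------

def test_bootstrap_bias_identity_and_determinism():
    df = _clinical_frame(seed=9)
    summary = bootstrap_validate(df, ["casi"], n_boot=200, seed=11)
    table = summary.table
    np.testing.assert_array_equal(
        table["corrected"].to_numpy(), (table["original"] - table["bias"]).to_numpy()
    )
    np.testing.assert_allclose(
        table["or_corrected"], np.exp(table["corrected"]), rtol=1e-12
    )
    again = bootstrap_validate(df, ["casi"], n_boot=200, seed=11)
    pd.testing.assert_frame_equal(summary.table, again.table)
    assert summary.n_boot == 200


def test_bootstrap_percentile_interval_covers_a_strong_effect():
    df = _clinical_frame(seed=12, casi_beta=0.4)
    summary = bootstrap_validate(df, ["casi"], n_boot=300, seed=1)
    row = summary.table.set_index("term").loc["casi"]
    assert row["ci_low"] < row["corrected"] < row["ci_high"]
    assert row["ci_low"] > 0  # effect clearly positive


# --------------------------------------------------------------------------
# power calculations
# --------------------------------------------------------------------------

def test_proportion_power_null_case_equals_alpha():
    assert power_two_proportions(0.3, 0.3, 500) == pytest.approx(0.05, abs=1e-9)
    assert power_two_means(0.0, 1.0, 50, 50) == pytest.approx(0.05, abs=1e-9)


def test_proportion_power_grows_to_one():
    assert power_two_proportions(0.05, 0.064, 200_000) > 0.999
    assert power_two_means(2.0, 0.01, 52, 79) > 0.999


def test_power_input_validation():
    with pytest.raises(ValueError):
        power_two_proportions(0.0, 0.5, 100)
    with pytest.raises(ValueError):
        power_two_means(1.0, -1.0, 10, 10)
    with pytest.raises(ValueError):
        proportion_or(1.0, 0.5)
    with pytest.raises(ValueError):
        power_variant_or(2.1, 0.4, n_reps=50)
    with pytest.raises(ValueError):
        power_variant_or(-1.0, 0.4)


def test_proportion_or_hand_arithmetic():
    assert proportion_or(0.5, 2 / 3) == pytest.approx(2.0)
    assert proportion_or(0.3, 0.3) == pytest.approx(1.0)


def test_proportion_power_matches_monte_carlo():
    """Closed form vs 20,000-rep simulation of the same z-test."""
    p0, p1, n = 0.05, 0.08, 1500
    rng = np.random.default_rng(0)
    x0 = rng.binomial(n, p0, 20_000) / n
    x1 = rng.binomial(n, p1, 20_000) / n
    pbar = (x0 + x1) / 2
    se0 = np.sqrt(2 * pbar * (1 - pbar) / n)
    z = (x1 - x0) / se0
    mc = (z > stats.norm.ppf(0.95)).mean()
    closed = power_two_proportions(p0, p1, n, one_sided=True)
    assert closed == pytest.approx(mc, abs=0.02)


def test_mean_power_matches_monte_carlo():
    diff, sd, n1, n2 = 1.0, 2.0, 40, 60
    rng = np.random.default_rng(1)
    m1 = rng.normal(diff, sd / np.sqrt(n1), 20_000)
    m2 = rng.normal(0, sd / np.sqrt(n2), 20_000)
    z = (m1 - m2) / (sd * np.sqrt(1 / n1 + 1 / n2))
    mc = (np.abs(z) > stats.norm.ppf(0.975)).mean()
    assert power_two_means(diff, sd, n1, n2) == pytest.approx(mc, abs=0.02)


def test_variant_power_null_or_rejects_at_alpha():
    power = power_variant_or(1.0, 0.4, 53, 78, n_reps=4000, seed=0)
    assert power == pytest.approx(0.05, abs=0.02)


def test_variant_power_strong_effect_near_one():
    assert power_variant_or(10.0, 0.4, 53, 78, n_reps=1000, seed=0) > 0.99


def test_variant_power_wald_matches_statsmodels_on_one_replicate():
    import statsmodels.api as sm
    from enrichprs.power import _logistic_wald_p

    rng = np.random.default_rng(5)
    g_case = rng.binomial(2, 0.55, 53)
    g_ctrl = rng.binomial(2, 0.40, 78)
    case_counts = np.array([[(g_case == k).sum() for k in range(3)]], dtype=float)
    ctrl_counts = np.array([[(g_ctrl == k).sum() for k in range(3)]], dtype=float)
    p_fast = _logistic_wald_p(case_counts, ctrl_counts)[0]
    g = np.r_[g_case, g_ctrl].astype(float)
    y = np.r_[np.ones(53), np.zeros(78)]
    res = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
    assert p_fast == pytest.approx(np.asarray(res.pvalues)[1], abs=1e-6)
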