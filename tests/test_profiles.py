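"""Risk coding, combined scores, Cox fits, interaction and PH diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from glrisk.cohort import ConfigurationError
from glrisk.profiles import (
    CoxFitError,
    LifestyleRule,
    RiskCoding,
    assign_risk_genotype,
    assign_risk_lifestyle,
    bh_adjust,
    combine_gene_lifestyle,
    cox_fit,
    interaction_test,
    joint_effect_table,
    schoenfeld_check,
    trend_test,
)


# ----------------------------------------------------------------------
# Risk coding
# ----------------------------------------------------------------------

def _coding_two_snps():
    """Non-obese-stratum style panel: two recessive risk homozygotes; both
    must be present for the binary G to flip."""
    return RiskCoding(
        snp_risk_sets={"rs_sall1": (2.0,), "rs_apoc1": (2.0,)},
        lifestyle_rules=(
            LifestyleRule("alcohol", 18.0, "ge"),
            LifestyleRule("ep_years", 10.0, "ge"),
            LifestyleRule("oc_years", 5.0, "lt"),
        ),
    )


def test_both_risk_genotypes_required_for_high_risk():
    geno = pd.DataFrame({"rs_sall1": [2, 2, 0, 1], "rs_apoc1": [2, 0, 2, 1]})
    count, G = assign_risk_genotype(geno, _coding_two_snps())
    np.testing.assert_array_equal(count, [2, 1, 1, 0])
    np.testing.assert_array_equal(G, [1, 0, 0, 0])


def test_four_snp_panel_requires_all_four():
    coding = RiskCoding(
        snp_risk_sets={f"s{i}": (2.0,) for i in range(4)},
        lifestyle_rules=(),
    )
    geno = pd.DataFrame({f"s{i}": [2, 2] for i in range(4)})
    geno.loc[1, "s3"] = 1  # three of four risk genotypes only
    count, G = assign_risk_genotype(geno, coding)
    np.testing.assert_array_equal(count, [4, 3])
    np.testing.assert_array_equal(G, [1, 0])


def test_lifestyle_risk_directions():
    cov = pd.DataFrame(
        {
            "alcohol": [20.0, 10.0, 18.0],
            "ep_years": [12.0, 0.0, 9.9],
            "oc_years": [6.0, 2.0, 5.0],  # short OC use (<5 y) is the risk side
        }
    )
    count, B = assign_risk_lifestyle(cov, _coding_two_snps())
    # subject 0: alcohol 20 (risk) + E+P 12 (risk) + OC 6 (no risk) = 2
    np.testing.assert_array_equal(count, [2, 1, 1])
    np.testing.assert_array_equal(B, [1, 1, 1])


def test_three_level_behavior_coding_caps_at_two():
    coding = RiskCoding(
        snp_risk_sets={},
        lifestyle_rules=(
            LifestyleRule("alcohol", 18.0, "ge"),
            LifestyleRule("ep_years", 10.0, "ge"),
            LifestyleRule("oc_years", 5.0, "lt"),
        ),
        behavior_levels=3,
    )
    cov = pd.DataFrame(
        {"alcohol": [20, 20, 0], "ep_years": [12, 12, 0], "oc_years": [1, 9, 9]}
    )
    _, B = assign_risk_lifestyle(cov, coding)
    np.testing.assert_array_equal(B, [2, 2, 0])


def test_combined_score_truth_table():
    G = np.array([0, 1, 0, 1])
    B = np.array([0, 0, 1, 1])
    np.testing.assert_array_equal(combine_gene_lifestyle(G, B), [0, 1, 1, 2])
    with pytest.raises(ConfigurationError):
        combine_gene_lifestyle(np.array([0, 2]), np.array([0, 1]))


# ----------------------------------------------------------------------
# Cox fitting
# ----------------------------------------------------------------------

def test_cox_matches_partial_likelihood_grid_oracle():
    """Eight subjects, no ties: the fitted coefficient maximizes the exact
    partial likelihood (checked by independent 1-D optimization)."""
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
    x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])

    def neg_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(e):
            risk_set = t >= t[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk_set])))
        return -ll

    opt = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    res = cox_fit(t, e, pd.DataFrame({"x": x}))
    beta_hat = float(res.summary.loc[res.summary["term"] == "x", "coef"].iloc[0])
    assert beta_hat == pytest.approx(opt.x, abs=1e-6)
    # Efron and Breslow coincide without ties
    res_b = cox_fit(t, e, pd.DataFrame({"x": x}), ties_method="breslow")
    beta_b = float(res_b.summary.loc[res_b.summary["term"] == "x", "coef"].iloc[0])
    assert beta_b == pytest.approx(opt.x, abs=1e-5)


def test_cox_null_covariate_hr_near_one():
    rng = np.random.default_rng(1)
    n = 5000
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(10, n)
    c = rng.uniform(5, 15, n)
    res = cox_fit(np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x}))
    assert 0.9 <= res.hr("x") <= 1.1


def test_cox_degenerate_inputs_rejected():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(CoxFitError):
        cox_fit(t, np.array([1, 0, 0, 0]), pd.DataFrame({"x": [1.0, 0, 1, 0]}))
    with pytest.raises(CoxFitError):  # constant column is inestimable
        cox_fit(t, np.array([1, 1, 0, 1]), pd.DataFrame({"x": [1.0, 1, 1, 1]}))


# ----------------------------------------------------------------------
# Benjamini-Hochberg
# ----------------------------------------------------------------------

def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_adjust([0.03]), [0.03])


def test_bh_hand_worked_example():
    """p*m/rank = (.04, .04, .04, .04) after the step-up minimum."""
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_adjusted_at_least_raw_and_monotone():
    rng = np.random.default_rng(2)
    p = rng.random(25)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


# ----------------------------------------------------------------------
# Joint effects, trend, interaction
# ----------------------------------------------------------------------

def _dose_response_data(seed=3, n=6000, beta=np.log(2)):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 2, n)
    B = rng.integers(0, 2, n)
    C = G + B
    lam = 0.01 * np.exp(beta * C)
    t = rng.exponential(1 / lam)
    c = rng.uniform(12, 20, n)
    return np.minimum(t, c), (t <= c).astype(int), C, G, B


def test_joint_effect_reference_is_one_and_counts_partition():
    time, event, C, G, B = _dose_response_data()
    strat = (np.random.default_rng(9).random(len(C)) < 0.3).astype(int)
    table = joint_effect_table(time, event, C, stratifier=strat)
    total = table[table["block"] == "total"]
    assert total.loc[total["level"] == 0, "hr"].iloc[0] == 1.0
    assert total["n"].sum() == len(C)
    for block in ("low_stratum", "high_stratum"):
        sub = table[table["block"] == block]
        assert sub["n"].sum() == (strat == (0 if block == "low_stratum" else 1)).sum()
    # BH-adjusted never below raw
    est = table.dropna(subset=["p"])
    assert np.all(est["p_bh"].to_numpy() >= est["p"].to_numpy() - 1e-15)


def test_dose_response_orders_hazard_ratios():
    time, event, C, *_ = _dose_response_data()
    table = joint_effect_table(time, event, C)
    hrs = table.set_index("level")["hr"]
    assert 1.0 < hrs[1] < hrs[2]
    assert table.attrs["p_trend"] < 1e-3


def test_trend_test_uses_linear_coding():
    time, event, C, *_ = _dose_response_data(seed=4, n=3000)
    p_linear = trend_test(time, event, C)
    p_scaled = trend_test(time, event, 2 * C)  # Wald p invariant to scaling
    assert p_linear == pytest.approx(p_scaled, rel=1e-6)


def test_multiplicative_generation_gives_null_product_term():
    rng = np.random.default_rng(5)
    n = 8000
    G = rng.integers(0, 2, n)
    E = rng.integers(0, 2, n)
    lam = 0.01 * np.exp(np.log(2) * G + np.log(2) * E)
    t = rng.exponential(1 / lam)
    c = rng.uniform(12, 20, n)
    res = interaction_test(np.minimum(t, c), (t <= c).astype(int), G, E)
    assert 0.85 <= res["hr_product"] <= 1.18


def test_additive_risk_generation_gives_null_reri():
    rng = np.random.default_rng(6)
    n = 20_000
    G = rng.integers(0, 2, n)
    E = rng.integers(0, 2, n)
    lam = 0.01 * (1.0 + 1.0 * G + 1.0 * E)  # additive hazards
    t = rng.exponential(1 / lam)
    c = rng.uniform(12, 20, n)
    res = interaction_test(np.minimum(t, c), (t <= c).astype(int), G, E)
    lo, hi = res["reri_ci"]
    assert lo < 0 < hi or abs(res["reri"]) < 0.3


def test_constant_exposure_rejected():
    time, event, C, G, _ = _dose_response_data(n=500)
    with pytest.raises(ConfigurationError):
        interaction_test(time, event, G, np.zeros_like(G))


# ----------------------------------------------------------------------
# Schoenfeld diagnostics
# ----------------------------------------------------------------------

def test_schoenfeld_residuals_sum_to_zero():
    rng = np.random.default_rng(7)
    n = 1000
    x = rng.normal(size=n)
    lam = 0.05 * np.exp(0.5 * x)
    t = rng.exponential(1 / lam)
    c = rng.uniform(5, 15, n)
    res = cox_fit(np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x}))
    raw = res.model.compute_residuals(res.data, "schoenfeld")
    # the score equation holds at the solver's convergence tolerance
    assert raw["x"].sum() == pytest.approx(0.0, abs=1e-3)
    summary, resid = schoenfeld_check(res)
    assert set(summary["term"]) == {"x"}
    assert {"event_time", "time_rank", "x"} <= set(resid.columns)


def test_time_decaying_effect_detected():
    """An effect that switches off after 5 years violates PH and should be
    flagged by the rho test at n = 5000."""
    rng = np.random.default_rng(8)
    n = 5000
    x = rng.integers(0, 2, n).astype(float)
    # piecewise-constant hazard: effect only before year 5
    lam1 = 0.08 * np.exp(1.2 * x)
    t1 = rng.exponential(1 / lam1)
    t2 = 5 + rng.exponential(1 / 0.08, n)
    t = np.where(t1 <= 5, t1, t2)
    c = rng.uniform(12, 20, n)
    res = cox_fit(np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x}))
    summary, _ = schoenfeld_check(res)
    assert summary.loc[0, "p"] < 0.01
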