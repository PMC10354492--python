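import math

import numpy as np
import pandas as pd
import pytest

import micsoc
from micsoc import (DegenerateDataError, SeparationError, build_set_level,
                    decision_frame, first_k_rounds, fit_bayes_glmm,
                    mediation_analysis, run_prediction_suite, simple_effects,
                    standardize, tabulate_steal_by_threshold)
from micsoc.bayes import bf_band, bf_display, categorize_bf, savage_dickey_bf


# ---------------------------------------------------------------------------
# standardization

def test_zscore_and_roundtrip(rng):
    frame = pd.DataFrame({"x": rng.normal(3, 2, 500), "y": rng.random(500)})
    z, scaler = standardize(frame, ["x"])
    assert abs(z["x_z"].mean()) < 1e-12
    assert z["x_z"].std(ddof=0) == pytest.approx(1.0)
    back = scaler.inverse(z)
    assert np.allclose(back["x"], frame["x"])


def test_constant_column_raises_named_error():
    frame = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
    with pytest.raises(DegenerateDataError, match="'x'"):
        standardize(frame, ["x"])


# ---------------------------------------------------------------------------
# Savage-Dickey and categories

def test_savage_dickey_identity_and_closed_forms():
    assert savage_dickey_bf(0.0, 1.0, 1.0) == pytest.approx(1.0)
    # frozen from the Gaussian density ratio phi(0;0,1)/phi(0;3,0.5)
    assert savage_dickey_bf(3.0, 0.5, 1.0) == pytest.approx(3.283e7, rel=1e-3)
    assert bf_display(savage_dickey_bf(3.0, 0.5, 1.0)) == "> 1000"
    # tight posterior at zero: evidence for the null, phi(0;0,1)/phi(0;0,0.1)
    assert savage_dickey_bf(0.0, 0.1, 1.0) == pytest.approx(0.1)


@pytest.mark.parametrize("bf, strength, direction", [
    (22.64, "strong", "effect"),
    (544.23, "extreme", "effect"),
    (45.70, "very strong", "effect"),
    (2.09, "anecdotal", "effect"),
    (8.82, "moderate", "effect"),
    (0.28, "moderate", "null"),
    (0.45, "anecdotal", "null"),
    (0.15, "moderate", "null"),
    (1.0, "none", "none"),
])
def test_bf_bands(bf, strength, direction):
    assert bf_band(bf) == (strength, direction)


def test_category_labels():
    assert categorize_bf(22.64) == "strong supporting evidence"
    assert categorize_bf(0.28) == "moderate evidence for null"
    assert categorize_bf(1.0) == "no evidence"


# ---------------------------------------------------------------------------
# GLMM fitter

def _logistic_frame(n, beta0, beta1, rng):
    x = (np.arange(n) % 2).astype(float)
    eta = beta0 + beta1 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"y": y, "x": x})


def test_prior_only_fit_gives_bf_one():
    frame = pd.DataFrame({"y": [], "x": []})
    fit = fit_bayes_glmm(frame, "y", ["x"])
    assert fit["x"].estimate == 0.0
    assert fit["x"].sd == 1.0
    assert fit["x"].bf == 1.0


def test_penalized_mode_matches_independent_optimizer(rng):
    """The Newton mode equals a direct Nelder-Mead maximization of the same
    N(0,1)-penalized Bernoulli log likelihood on a fixed 200-row frame."""
    from scipy.optimize import minimize

    frame = _logistic_frame(200, -0.5, 1.0, rng)
    fit = fit_bayes_glmm(frame, "y", ["x"])
    X = np.column_stack([np.ones(200), frame["x"]])
    y = frame["y"].to_numpy()

    def neg_penalized(beta):
        eta = X @ beta
        return -(np.sum(y * eta - np.logaddexp(0, eta)) - 0.5 * beta @ beta)

    res = minimize(neg_penalized, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    assert fit["(Intercept)"].estimate == pytest.approx(res.x[0], abs=1e-4)
    assert fit["x"].estimate == pytest.approx(res.x[1], abs=1e-4)


def test_flat_prior_limit_matches_maximum_likelihood(rng):
    """With prior sd -> infinity the penalized fit converges to the MLE
    (statsmodels Logit as the independent oracle)."""
    import statsmodels.api as sm

    frame = _logistic_frame(200, 0.3, -0.8, rng)
    fit = fit_bayes_glmm(frame, "y", ["x"], prior_sd=1e6)
    X = sm.add_constant(frame["x"].to_numpy())
    mle = sm.Logit(frame["y"].to_numpy(), X).fit(disp=0)
    assert fit["(Intercept)"].estimate == pytest.approx(mle.params[0], abs=1e-3)
    assert fit["x"].estimate == pytest.approx(mle.params[1], abs=1e-3)


def test_gaussian_family_matches_ols_in_flat_prior_limit(rng):
    import statsmodels.api as sm

    x = rng.normal(size=300)
    y = 1.0 + 0.5 * x + rng.normal(scale=0.8, size=300)
    frame = pd.DataFrame({"y": y, "x": x})
    fit = fit_bayes_glmm(frame, "y", ["x"], family="gaussian", prior_sd=1e6)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit["x"].estimate == pytest.approx(ols.params[1], abs=1e-3)
    assert fit.residual_sd == pytest.approx(np.std(ols.resid), rel=0.05)


def test_random_intercepts_shrink_toward_generative_sd(rng):
    n_groups, per = 100, 30
    u = rng.normal(0, 0.8, n_groups)
    g = np.repeat(np.arange(n_groups), per)
    eta = -0.5 + u[g]
    y = (rng.random(len(g)) < 1 / (1 + np.exp(-eta))).astype(float)
    frame = pd.DataFrame({"y": y, "g": g, "x": rng.normal(size=len(g))})
    fit = fit_bayes_glmm(frame, "y", ["x"], groups=["g"])
    assert 0.55 < fit.group_sds["g"] < 1.1
    assert abs(fit["x"].estimate) < 0.2


def test_constant_outcome_raises():
    frame = pd.DataFrame({"y": [1.0] * 10, "x": np.arange(10.0)})
    with pytest.raises(DegenerateDataError, match="'y'"):
        fit_bayes_glmm(frame, "y", ["x"])


def test_complete_separation_raises_naming_term(rng):
    x = np.repeat([0.0, 1.0], 50)
    y = x.copy()  # x separates y perfectly
    frame = pd.DataFrame({"y": y, "x": x})
    with pytest.raises(SeparationError, match="x"):
        fit_bayes_glmm(frame, "y", ["x"], prior_sd=1e6)


# ---------------------------------------------------------------------------
# descriptive odds ratios

def _tiny_log(counts):
    """Build a minimal dataset with given (below, steal) -> n counts."""
    rows = []
    for (below, steal), n in counts.items():
        for _ in range(n):
            rows.append({
                "set_id": 0, "session_seed": "0:0", "round_index": 1,
                "group_id": "A", "player_id": 0, "threshold_active": True,
                "punishment_level": "n/a", "inequality_condition": "n/a",
                "points_before": 50 if below else 150, "trust_rating": 5,
                "steal_likelihood_rating": None,
                "action": "steal" if steal else "work_alone",
                "steal_outcome": "success" if steal else "n/a",
                "delta_points": 0, "perturbation": 0,
                "points_after": 50 if below else 150,
                "below_threshold_flag": below, "active": True,
            })
    df = pd.DataFrame(rows)
    df["round_index"] = np.tile([1, 2], len(df) // 2 + 1)[: len(df)]
    return df


def test_cross_product_odds_ratio():
    df = _tiny_log({(True, True): 30, (True, False): 70,
                    (False, True): 10, (False, False): 90})
    table = tabulate_steal_by_threshold(df, 100)
    assert table.odds_ratio == pytest.approx((30 * 90) / (70 * 10), rel=1e-12)
    assert table.flagged is None


def test_equal_rates_give_or_one():
    df = _tiny_log({(True, True): 20, (True, False): 80,
                    (False, True): 20, (False, False): 80})
    assert tabulate_steal_by_threshold(df, 100).odds_ratio == pytest.approx(1.0)


def test_empty_cell_flags_undefined_or():
    df = _tiny_log({(True, True): 50, (False, True): 10, (False, False): 90})
    table = tabulate_steal_by_threshold(df, 100)
    assert table.odds_ratio is None
    assert "undefined" in table.flagged


# ---------------------------------------------------------------------------
# set-level frame, mediation, subsets

def test_set_level_counts_attempts_and_lags(study1_dataset):
    kept, _ = micsoc.apply_exclusions(study1_dataset)
    sl = build_set_level(kept)
    first = sl[sl["round_index"] == 1]
    assert first["n_stealers_lag"].isna().all()
    # cross-check one cell against the raw log (attempts, not successes)
    row = sl.iloc[5]
    sub = kept[(kept["set_id"] == row["set_id"])
               & (kept["round_index"] == row["round_index"])]
    assert row["n_stealers"] == (sub["action"] == "steal").sum()
    assert row["mean_trust"] == pytest.approx(sub["trust_rating"].mean())
    # lag matches the previous round's value
    prev = sl[(sl["set_id"] == row["set_id"])
              & (sl["round_index"] == row["round_index"] - 1)]
    assert row["n_below_lag"] == prev["n_below"].iloc[0]


def test_mediation_recovers_linear_path_structure():
    """A linear simulation with a = 0.5, b = -0.3, direct = -0.2 yields
    proportion mediated (a*b)/(a*b + direct) ~ 0.43."""
    rng = np.random.default_rng(77)
    n_sets, n_rounds = 40, 10
    rows = []
    for s in range(n_sets):
        set_fx = rng.normal(0, 0.1)
        for r in range(1, n_rounds + 1):
            below_lag = rng.normal()
            stealers_lag = 0.5 * below_lag + rng.normal(0, math.sqrt(1 - 0.25))
            trust = (-0.3 * stealers_lag - 0.2 * below_lag + set_fx
                     + rng.normal(0, 0.5))
            rows.append({"set_id": s, "round_index": r, "mean_trust": trust,
                         "n_stealers": 0, "n_below": 0, "threshold": 1.0,
                         "unequal": 0.0, "n_stealers_lag": stealers_lag,
                         "n_below_lag": below_lag})
    frame = pd.DataFrame(rows)
    med = mediation_analysis(frame, n_bootstrap=120,
                             rng=np.random.default_rng(5))
    assert med.a == pytest.approx(0.5, abs=0.07)
    assert med.indirect == pytest.approx(med.a * med.b)
    true_prop = (0.5 * -0.3) / (0.5 * -0.3 - 0.2)
    assert med.proportion_ab_direct == pytest.approx(true_prop, abs=0.12)
    lo, hi = med.ci["indirect"]
    assert lo <= med.indirect <= hi


def test_mediation_null_b_path(rng):
    rows = []
    for s in range(20):
        for r in range(1, 9):
            below_lag = rng.normal()
            rows.append({"set_id": s, "round_index": r,
                         "mean_trust": rng.normal(),
                         "n_stealers": 0, "n_below": 0, "threshold": 1.0,
                         "unequal": 0.0,
                         "n_stealers_lag": 0.5 * below_lag + rng.normal(),
                         "n_below_lag": below_lag})
    med = mediation_analysis(pd.DataFrame(rows), n_bootstrap=40,
                             rng=np.random.default_rng(8))
    assert abs(med.indirect) < 0.1


def test_mediation_needs_at_least_two_sets():
    frame = pd.DataFrame({
        "set_id": [0] * 5, "round_index": range(2, 7),
        "mean_trust": np.random.default_rng(0).normal(size=5),
        "n_stealers": 0, "n_below": 0, "threshold": 1.0, "unequal": 0.0,
        "n_stealers_lag": np.random.default_rng(1).normal(size=5),
        "n_below_lag": np.random.default_rng(2).normal(size=5),
    })
    with pytest.raises(DegenerateDataError):
        mediation_analysis(frame, n_bootstrap=5)


def test_first_k_rounds_subsets(study1_dataset):
    sub = first_k_rounds(study1_dataset, 4)
    assert set(sub["round_index"]) == {1, 2, 3, 4}
    all_real = first_k_rounds(study1_dataset, 99)
    assert len(all_real) == (study1_dataset["round_index"] >= 1).sum()
    assert (sub["round_index"] >= 1).all()
    with pytest.raises(ValueError):
        first_k_rounds(study1_dataset, 0)


# ---------------------------------------------------------------------------
# simple effects and suites

def test_simple_effects_null_interaction_gives_similar_strata(rng):
    n = 4000
    below = (np.arange(n) % 2).astype(float)
    thr = (np.arange(n) // 2 % 2).astype(float)
    eta = -1.5 + 0.8 * below  # no interaction
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    frame = pd.DataFrame({"steal": y, "below": below, "threshold": thr,
                          "round_z": rng.normal(size=n),
                          "player_id": np.arange(n) % 100,
                          "set_id": np.arange(n) % 10})
    se = simple_effects(frame, "steal", "below", "threshold")
    est0 = se["strata"][0]["below"].estimate
    est1 = se["strata"][1]["below"].estimate
    assert abs(est0 - est1) < 0.3
    assert abs(se["interaction"]["below_x_threshold"].estimate) < 0.3


def test_simple_effects_zero_event_stratum_errors(rng):
    frame = pd.DataFrame({
        "steal": [0.0] * 50 + [0.0, 1.0] * 25,
        "below": ([0.0, 1.0] * 25) * 2,
        "threshold": [0.0] * 50 + [1.0] * 50,
        "round_z": rng.normal(size=100),
        "player_id": np.arange(100) % 20, "set_id": np.arange(100) % 4,
    })
    with pytest.raises(DegenerateDataError):
        simple_effects(frame, "steal", "below", "threshold")


def test_suite_registers_expected_predictions(study2_dataset):
    kept, _ = micsoc.apply_exclusions(study2_dataset)
    table, _ = run_prediction_suite(2, kept, n_bootstrap=10)
    assert set(table["prediction"]) == {
        "P2.1", "P2.1_below_in_threshold", "P2.1_below_in_no_threshold",
        "P2.2", "P2.3"}


def test_study4_suite_covers_both_subsets():
    df = micsoc.run_study(4, 8, master_seed=19)
    kept, _ = micsoc.apply_exclusions(df)
    table, _ = run_prediction_suite(4, kept, n_bootstrap=10)
    for pid in ("P4.1", "P4.2", "P4.3", "P4.4", "P4.5", "P4.6"):
        subsets = set(table[table["prediction"] == pid]["subset"])
        assert subsets == {"all_rounds", "first_4"}


def test_decision_frame_uses_points_before(study1_dataset):
    d = decision_frame(study1_dataset, 100)
    assert ((d["points_before"] < 100) == (d["below"] == 1)).all()
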