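"""G-formula engine: decision rule, risk identities, nonparametric benchmark,
calibration checks, strategy simulation, subgroups."""

import warnings

import numpy as np
import pandas as pd
import pytest

import urate_gformula as ug
from urate_gformula.engine import (RiskCurve, baseline_frame,
                                   cumulative_risk_from_hazards,
                                   natural_course_validation,
                                   observed_risk_nonparametric,
                                   simulate_strategy, subgroup_analysis,
                                   threshold_decision)
from urate_gformula.models import ComponentModel, FittedModelSet


# -- threshold decision -----------------------------------------------------

@pytest.mark.parametrize("sua,tau,tx_prev,expected", [
    (7.0, 7, 0, 1),    # boundary inclusive: >= tau treats
    (6.9, 7, 0, 0),
    (3.0, 7, 1, 1),    # absorbing: once treated, always treated
    (12.0, 10, 0, 1),
    (9.99, 10, 0, 0),
])
def test_threshold_decision_boundary(sua, tau, tx_prev, expected):
    assert threshold_decision(sua, tau, tx_prev) == expected


def test_threshold_decision_vectorized():
    out = threshold_decision(np.array([5.0, 8.0, 2.0]), 7.0, np.array([0, 0, 1]))
    assert list(out) == [0, 1, 1]


# -- cumulative risk identity ----------------------------------------------

def _enumerate_risk(hazards):
    """Brute-force enumeration over all event/no-event paths."""
    risk = 0.0
    surv = 1.0
    for h in hazards:
        risk += surv * h
        surv *= 1 - h
    return risk


@pytest.mark.parametrize("h,expected", [
    ([0.1, 0.1], 0.19),
    ([], 0.0),
    ([0.2, 0.5], 0.6),
    ([1.0], 1.0),
])
def test_cumulative_risk_identity(h, expected):
    assert cumulative_risk_from_hazards(h) == pytest.approx(expected)
    assert _enumerate_risk(h) == pytest.approx(expected)


def test_cumulative_risk_rejects_invalid_hazards():
    with pytest.raises(ValueError):
        cumulative_risk_from_hazards([0.2, 1.5])
    with pytest.raises(ValueError):
        cumulative_risk_from_hazards([-0.1])


def test_risk_curve_must_be_monotone():
    with pytest.raises(ValueError, match="nondecreasing"):
        RiskCurve("x", np.array([0.1, 0.05]), 10)
    with pytest.raises(ValueError, match="0, 1"):
        RiskCurve("x", np.array([0.1, 1.2]), 10)


# -- nonparametric observed risk --------------------------------------------

def _hand_table(rows):
    """rows: (patient_id, last_k, event) with event in {'death','eskd',None}."""
    recs = []
    for pid, last_k, event in rows:
        for k in range(last_k + 1):
            recs.append({
                "patient_id": pid, "k": k,
                "event_death": int(event == "death" and k == last_k),
                "event_eskd": int(event == "eskd" and k == last_k),
                "censored": int(event is None and k == last_k),
            })
    return pd.DataFrame(recs)


def test_product_limit_matches_hand_computed_ten_patients():
    # 10 patients: deaths at k=0 (x2), k=2; censorings at k=1, k=3; rest to k=3
    rows = [(0, 0, "death"), (1, 0, "death"), (2, 2, "death"),
            (3, 1, None), (4, 3, None),
            (5, 3, None), (6, 3, None), (7, 3, None), (8, 3, None), (9, 3, None)]
    table = _hand_table(rows)
    rc = observed_risk_nonparametric(table, "death", 4)
    # hand product-limit: h0=2/10, h1=0/8, h2=1/7, h3=0/6
    expect = 1 - (1 - 2 / 10) * (1 - 0 / 8) * (1 - 1 / 7) * (1 - 0 / 6)
    assert rc.risk_at(4) == pytest.approx(expect)
    assert rc.risk_at(1) == pytest.approx(0.2)


def test_product_limit_matches_lifelines_kaplan_meier():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(5)
    rows = []
    for pid in range(120):
        last_k = int(rng.integers(0, 8))
        event = rng.choice(["death", None], p=[0.4, 0.6])
        rows.append((pid, last_k, event))
    table = _hand_table(rows)
    rc = observed_risk_nonparametric(table, "death", 8)
    km = lifelines.KaplanMeierFitter()
    durations = [r[1] + 1 for r in rows]            # event/censor at end of k
    observed = [r[2] == "death" for r in rows]
    km.fit(durations, observed)
    for k in (1, 4, 8):
        assert rc.risk_at(k) == pytest.approx(
            1 - km.survival_function_at_times(k).iloc[0], abs=1e-10)


def test_cumulative_incidence_matches_lifelines_aalen_johansen():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(6)
    rows = []
    for pid in range(150):
        last_k = int(rng.integers(0, 8))
        event = rng.choice(["eskd", "death", None], p=[0.3, 0.25, 0.45])
        rows.append((pid, last_k, event))
    table = _hand_table(rows)
    rc = observed_risk_nonparametric(table, "eskd", 8)
    aj = lifelines.AalenJohansenFitter(calculate_variance=False)
    durations = [r[1] + 1 for r in rows]
    codes = [{"eskd": 1, "death": 2, None: 0}[r[2]] for r in rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aj.fit(durations, codes, event_of_interest=1)
    for k in (2, 5, 8):
        expect = float(aj.cumulative_density_.loc[:k].iloc[-1, 0])
        assert rc.risk_at(k) == pytest.approx(expect, abs=1e-10)


def test_no_censoring_reduces_to_empirical_proportion():
    rows = [(i, 3, "death" if i < 4 else None) for i in range(10)]
    # make non-events survive to the end with no censoring before k=3
    table = _hand_table(rows)
    rc = observed_risk_nonparametric(table, "death", 4)
    assert rc.risk_at(4) == pytest.approx(0.4)


def test_empty_risk_set_raises():
    with pytest.raises(ValueError, match="empty"):
        observed_risk_nonparametric(pd.DataFrame(), "death")
    table = _hand_table([(0, 0, None), (1, 0, None)])
    with pytest.raises(ValueError, match="risk set"):
        observed_risk_nonparametric(table, "death", 3)


# -- calibration report -----------------------------------------------------

def test_natural_course_validation_identity_and_failure():
    base = RiskCurve("natural", np.linspace(0.01, 0.25, 44), 100)
    rep = natural_course_validation(base, RiskCurve("obs", base.risk_k.copy(), 100))
    assert rep["max_abs_diff"] == 0.0 and rep["calibrated"]
    shifted = RiskCurve("obs", np.clip(base.risk_k + np.linspace(0, 0.05, 44), 0, 1), 100)
    rep = natural_course_validation(base, shifted)
    assert not rep["calibrated"] and rep["max_abs_diff"] == pytest.approx(0.05)
    with pytest.raises(ValueError, match="length"):
        natural_course_validation(base, RiskCurve("obs", base.risk_k[:10], 100))


# -- strategy simulation ----------------------------------------------------

def _degenerate_model_set(outcome="death", K=5):
    """All-zero hazards and frozen covariates: flat zero risk curve."""
    terms = ["intercept"]
    comps = {}
    for name, family in (("sua", "gaussian"), ("scr", "gaussian"),
                         ("dm", "binomial"), ("htn", "binomial"),
                         ("dialysis", "binomial"), ("tx", "binomial"),
                         ("death", "binomial")):
        if family == "gaussian":
            comps[name] = ComponentModel(name, family, terms,
                                         coef=np.array([1.0]), scale=1e-9)
        else:
            comps[name] = ComponentModel(name, family, terms,
                                         coef=np.array([0.0]),
                                         degenerate_value=0.0)
    return FittedModelSet(outcome=outcome, components=comps,
                          order=list(comps), knots=np.array([0.0, 2.0, 4.0]),
                          n_intervals=K)


def _one_row_baseline():
    cols = {c: [1.0] for c in ["age", "male", "bmi", "bmi_missing", "dm0",
                               "htn0", "dyslip0", "sua0", "log_scr0",
                               "albumin0", "hgb0", "egfr0"]}
    cols["patient_id"] = [0]
    return pd.DataFrame(cols)


def test_zero_hazard_models_give_flat_zero_curve():
    ms = _degenerate_model_set()
    rc = simulate_strategy(ms, _one_row_baseline(),
                           ug.StrategySpec(kind="never"), mc_size=1, seed=0)
    assert np.all(rc.risk_k == 0.0)


def test_mc_size_must_be_positive():
    with pytest.raises(ValueError, match="mc_size"):
        simulate_strategy(_degenerate_model_set(), _one_row_baseline(),
                          ug.StrategySpec(kind="never"), mc_size=0, seed=0)


def test_natural_requires_tx_component():
    ms = _degenerate_model_set()
    del ms.components["tx"]
    with pytest.raises(ValueError, match="tx component"):
        simulate_strategy(ms, _one_row_baseline(),
                          ug.StrategySpec(kind="natural"), mc_size=2, seed=0)


def test_simulation_reproducible_under_seed(fitted_death, small_table):
    base = baseline_frame(small_table)
    s = ug.StrategySpec(kind="threshold", tau=8.0)
    r1 = simulate_strategy(fitted_death, base, s, mc_size=500, seed=12)
    r2 = simulate_strategy(fitted_death, base, s, mc_size=500, seed=12)
    assert np.array_equal(r1.risk_k, r2.risk_k)
    r3 = simulate_strategy(fitted_death, base, s, mc_size=500, seed=13)
    assert not np.array_equal(r1.risk_k, r3.risk_k)


def test_contrasts_reference_is_exact(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gf = ug.ParametricGFormula(outcome="death", mc_size=400, seed=2).fit(small_table)
        contrasts = gf.estimate_contrasts(horizons_years=(5, 22))
    ref = [c for c in contrasts if c.strategy == "natural"]
    assert all(c.rr == 1.0 and c.rd == 0.0 for c in ref)
    labels = {c.strategy for c in contrasts}
    assert labels == {"natural", "tau10", "tau9", "tau8", "tau7", "never"}
    for c in contrasts:
        if c.strategy != "natural":
            ref_c = next(r for r in ref if r.horizon_years == c.horizon_years)
            assert c.rd == pytest.approx(c.risk - ref_c.risk, abs=1e-9)
            assert c.rr > 0


def test_null_effect_strategies_agree_within_mc_error():
    cfg = ug.null_effect_config(n_patients=2500, seed=77)
    gen = ug.CohortGenerator(cfg)
    b = gen.sample_baseline()
    table = ug.trajectories_to_person_intervals(gen.simulate_trajectories(b), b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gf = ug.ParametricGFormula(outcome="death", mc_size=6000, seed=5).fit(table)
        r7 = gf.predict_risk_curve("tau7").risk_at(44)
        rn = gf.predict_risk_curve("never").risk_at(44)
    se = np.sqrt(2 * rn * (1 - rn) / 6000)
    assert abs(r7 - rn) < 3.5 * se


# -- subgroups --------------------------------------------------------------

def test_subgroup_strata_partition_cohort(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = subgroup_analysis(small_table, "egfr60", outcome="death",
                                mc_size=300, seed=1)
    assert len(res) == 2
    base = small_table[small_table["k"] == 0]
    n_lo = int((base["egfr0"] < 60).sum())
    n_hi = int((base["egfr0"] >= 60).sum())
    assert n_lo + n_hi == base["patient_id"].nunique()
    assert n_lo > 0 and n_hi > 0


def test_empty_stratum_skipped_with_warning(small_table):
    old = small_table[small_table["k"] == 0]["age"].min()
    assert old > 0
    aged = small_table.copy()
    aged["age"] = aged["age"].clip(lower=31.0)  # nobody under 30
    with pytest.warns(UserWarning, match="empty"), warnings.catch_warnings():
        warnings.simplefilter("always")
        res = subgroup_analysis(aged, "age30", outcome="death",
                                mc_size=200, seed=1)
    assert len(res) == 1


def test_unknown_stratifier_rejected(small_table):
    with pytest.raises(ValueError, match="stratifier"):
        subgroup_analysis(small_table, "sex", outcome="death")


def test_effect_modification_recovered_in_strata():
    """A generator whose protective treatment effect is concentrated in the
    low-eGFR stratum yields clearly larger never-treat excess risk in that
    stratum after per-stratum refit and resimulation."""
    cfg = ug.effect_modification_config(n_patients=6000, seed=88)
    gen = ug.CohortGenerator(cfg)
    b = gen.sample_baseline()
    table = ug.trajectories_to_person_intervals(gen.simulate_trajectories(b), b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = subgroup_analysis(table, "egfr60", outcome="death",
                                mc_size=4000, seed=3, horizons_years=(22,))
    rd = {name: next(c.rd for c in contrasts if c.strategy == "never")
          for name, contrasts in res.items()}
    assert rd["egfr0<60"] > rd["egfr0>=60"] + 0.5  # percentage points
    assert rd["egfr0<60"] > 1.0
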