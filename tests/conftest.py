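import warnings

import numpy as np
import pandas as pd
import pytest

import urate_gformula as ug

warnings.filterwarnings("ignore", message=".*divide by zero.*")


@pytest.fixture(scope="session")
def small_cfg():
    return ug.fully_observed_config(n_patients=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    gen = ug.CohortGenerator(small_cfg)
    baseline = gen.sample_baseline()
    traj = gen.simulate_trajectories(baseline)
    return gen, baseline, traj


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, baseline, traj = small_cohort
    return ug.trajectories_to_person_intervals(traj, baseline)


@pytest.fixture(scope="session")
def contaminated_raw():
    """Raw observed bundle with planted exclusion tags (n = 800)."""
    cfg = ug.small_config(n_patients=800, seed=19)
    cfg.observation_params.prior_ula_frac = 0.05
    cfg.observation_params.early_outcome_frac = 0.03
    gen = ug.CohortGenerator(cfg)
    baseline = gen.sample_baseline()
    traj = gen.simulate_trajectories(baseline)
    return cfg, gen.apply_observation_process(traj, baseline)


@pytest.fixture(scope="session")
def fitted_death(small_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ug.fit_model_set(small_table, outcome="death")


def tiny_raw_bundle():
    """Hand-built raw bundle with known eligibility outcomes.

    Patient 0: clean CKD (low eGFR) -> retained
    Patient 1: prior ULA episode starting day -10 -> excluded
    Patient 2: death at month 2 (day 61) -> excluded
    Patient 3: preserved eGFR, no albuminuria -> excluded (not CKD)
    Patient 4: ESKD at enrollment -> excluded
    """
    pat = pd.DataFrame({
        "patient_id": [0, 1, 2, 3, 4],
        "age": [60.0] * 5, "male": [1, 0, 1, 0, 1],
        "bmi": [24.0, np.nan, 22.0, 27.0, 25.0],
        "bmi_missing": [0, 1, 0, 0, 0],
        "dm0": [0, 0, 1, 0, 0], "htn0": [1, 0, 0, 0, 1],
        "dyslip0": [0] * 5,
        "scr0": [2.0, 2.0, 2.0, 0.8, 3.0],
        "log_scr0": np.log([2.0, 2.0, 2.0, 0.8, 3.0]),
        "sua0": [7.0, 6.0, 8.0, 5.0, 9.0],
        "albumin0": [4.0] * 5, "hgb0": [13.0] * 5,
        "egfr0": [30.0, 30.0, 30.0, 95.0, 20.0],
        "albuminuria": [0, 0, 0, 0, 0],
        "dm_onset_day": [np.nan] * 5, "htn_onset_day": [0.0, np.nan, np.nan, np.nan, 0.0],
        "dialysis_onset_day": [np.nan] * 5,
        "event_type": ["none", "none", "death", "none", "none"],
        "event_day": [np.nan, np.nan, 61.0, np.nan, np.nan],
        "censor_day": [2000.0, 2000.0, np.nan, 2000.0, 2000.0],
        "eskd_at_enroll": [0, 0, 0, 0, 1],
    })
    labs = pd.DataFrame({
        "patient_id": [0, 0, 0, 1, 2, 3, 4],
        "day": [0.0, 400.0, 950.0, 0.0, 0.0, 0.0, 0.0],
        "sua": [7.0, 7.5, 8.0, 6.0, 8.0, 5.0, 9.0],
        "scr": [2.0, 2.1, 2.3, 2.0, 2.0, 0.8, 3.0],
    })
    rx = pd.DataFrame({
        "patient_id": [1],
        "start_day": [-10.0],
        "end_day": [50.0],
    })
    return {"patients": pat, "labs": labs, "rx": rx}
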