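"""Synthetic CKD cohort generator with treatment-confounder feedback.

The generator is the ground-truth data-generating process for the whole
pipeline.  It produces:

* a baseline table (demographics, labs, comorbidities),
* factual or forced-strategy longitudinal trajectories in 6-month intervals,
* a raw "observed" dataset (day-stamped labs, prescription episodes, events,
  administrative censoring, optional contamination) for the preparation module,
* brute-force counterfactual risk curves for any strategy — the oracle against
  which the g-formula engine is validated.

Every component model uses exactly the families the fitting module assumes
(linear-Gaussian sUA, linear-Gaussian log sCr, logistic binaries), so on fully
observed data the fitted models are correctly specified.

Within an interval the update order is: (1) labs from lag-1 state and previous
treatment, (2) comorbidity flags, (3) treatment decision from current labs,
(4) death then ESKD drawn from the current state.  Death precludes ESKD.
Treatment, diabetes, hypertension and dialysis are absorbing.

Randomness: every (interval, variable) pair has its own deterministic
`SeedSequence`-derived stream, and patient *i* always consumes the *i*-th draw.
Growing ``n_patients`` therefore extends the cohort without reshuffling
earlier patients, and regeneration under a fixed seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import (DAYS_PER_INTERVAL, GeneratorConfig, StrategySpec)
from .egfr import compute_egfr

# stream identifiers: (domain, interval, variable)
_BASE, _DYN, _OBS, _ORACLE = 0, 1, 2, 3

BASELINE_COLUMNS = [
    "patient_id", "age", "male", "bmi", "bmi_missing", "dm0", "htn0",
    "dyslip0", "scr0", "log_scr0", "sua0", "albumin0", "hgb0", "egfr0",
    "albuminuria",
]


@dataclass
class TrajectorySet:
    """Long-format trajectories plus the strategy they were generated under."""

    data: pd.DataFrame
    strategy: str
    n_patients: int
    n_intervals: int

    def ever_treated(self) -> pd.Series:
        return self.data.groupby("patient_id")["tx"].max().astype(bool)


@dataclass
class RiskCurveTruth:
    """Oracle cumulative-risk curves (with per-horizon Monte Carlo SEs)."""

    strategy: str
    death: np.ndarray      # risk after k+1 intervals, k = 0..K-1
    eskd: np.ndarray
    death_se: np.ndarray
    eskd_se: np.ndarray
    n_sim: int

    def risk(self, outcome: str, horizon_k: int) -> float:
        curve = self.death if outcome == "death" else self.eskd
        if horizon_k == 0:
            return 0.0
        return float(curve[horizon_k - 1])

    def se(self, outcome: str, horizon_k: int) -> float:
        curve = self.death_se if outcome == "death" else self.eskd_se
        if horizon_k == 0:
            return 0.0
        return float(curve[horizon_k - 1])


class CohortGenerator:
    """Sampler for synthetic CKD cohorts under a :class:`GeneratorConfig`."""

    def __init__(self, config: GeneratorConfig):
        if not isinstance(config, GeneratorConfig):
            raise TypeError("config must be a GeneratorConfig")
        self.config = config

    # -- random streams ------------------------------------------------------
    def _rng(self, domain: int, k: int, var: int, seed: Optional[int] = None):
        seed = self.config.seed if seed is None else seed
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(domain, k, var))
        return np.random.default_rng(ss)

    # -- baseline ------------------------------------------------------------
    def sample_baseline(self, n: Optional[int] = None,
                        seed: Optional[int] = None) -> pd.DataFrame:
        """Draw the baseline table (one row per patient)."""
        cfg = self.config
        p = cfg.baseline_params
        n = cfg.n_patients if n is None else n
        if n == 0:
            return pd.DataFrame({c: pd.Series(dtype=float) for c in BASELINE_COLUMNS})

        def rng(var):
            return self._rng(_BASE, 0, var, seed)

        age = np.clip(rng(0).normal(p.age_mean, p.age_sd, n), p.age_min, p.age_max)
        male = (rng(1).random(n) < p.male_prop).astype(int)
        bmi = np.clip(rng(2).normal(p.bmi_mean, p.bmi_sd, n), 15.0, 45.0)
        bmi_missing = (rng(3).random(n) < p.bmi_missing_prop).astype(int)
        bmi = np.where(bmi_missing == 1, np.nan, bmi)
        dm0 = (rng(4).random(n) < p.dm_prev).astype(int)
        htn0 = (rng(5).random(n) < p.htn_prev).astype(int)
        dyslip0 = (rng(6).random(n) < p.dyslip_prev).astype(int)
        log_scr0 = rng(7).normal(p.log_scr_mean, p.log_scr_sd, n)
        sua0 = np.clip(rng(8).normal(p.sua_mean, p.sua_sd, n), p.sua_min, None)
        albumin0 = rng(9).normal(p.albumin_mean, p.albumin_sd, n)
        hgb0 = rng(10).normal(p.hgb_mean, p.hgb_sd, n)
        scr0 = np.exp(log_scr0)
        egfr0 = compute_egfr(scr0, age, male)
        low = egfr0 < 60.0
        u_alb = rng(11).random(n)
        albuminuria = np.where(
            low, u_alb < p.albuminuria_given_low_egfr,
            u_alb < p.albuminuria_given_preserved).astype(int)

        return pd.DataFrame({
            "patient_id": np.arange(n, dtype=int),
            "age": age, "male": male, "bmi": bmi, "bmi_missing": bmi_missing,
            "dm0": dm0, "htn0": htn0, "dyslip0": dyslip0,
            "scr0": scr0, "log_scr0": log_scr0, "sua0": sua0,
            "albumin0": albumin0, "hgb0": hgb0, "egfr0": egfr0,
            "albuminuria": albuminuria,
        })

    # -- core forward simulation --------------------------------------------
    def _forward(self, baseline: pd.DataFrame, strategy: StrategySpec,
                 collect_panels: bool, track_risk: bool,
                 seed: Optional[int] = None):
        """Simulate the covariate process for all patients over all intervals.

        Covariate dynamics do not depend on event occurrence, so the panel is
        simulated unconditionally; factual trajectories are obtained by drawing
        events on top and truncating, while counterfactual risks are obtained
        by accumulating the per-interval hazards analytically.
        """
        cfg = self.config
        dyn, rx, hz = cfg.dynamics_params, cfg.prescription_params, cfg.hazard_params
        n = len(baseline)
        K = cfg.n_intervals
        if strategy.kind not in ("natural", "threshold", "never"):
            raise ValueError(f"unknown strategy: {strategy.kind}")

        age = baseline["age"].to_numpy(float)
        setpoint = baseline["sua0"].to_numpy(float)
        log_scr0 = baseline["log_scr0"].to_numpy(float)
        low_egfr = (baseline["egfr0"].to_numpy(float) < 60.0)

        sua = baseline["sua0"].to_numpy(float).copy()
        logscr = log_scr0.copy()
        dm = baseline["dm0"].to_numpy(int).copy()
        htn = baseline["htn0"].to_numpy(int).copy()
        dial = np.zeros(n, dtype=int)
        tx = np.zeros(n, dtype=int)

        panels = {c: [] for c in ("sua", "logscr", "dm", "htn", "dialysis",
                                  "tx", "p_death", "p_eskd")} if collect_panels else None
        if track_risk:
            surv_net = np.ones(n)     # survival under the death hazard alone
            surv_both = np.ones(n)    # joint event-free survival
            cif_eskd = np.zeros(n)
            death_curve, eskd_curve = np.empty(K), np.empty(K)
            death_se, eskd_se = np.empty(K), np.empty(K)

        death_tx = hz.death_tx + hz.death_tx_low_egfr * low_egfr
        eskd_tx = hz.eskd_tx + hz.eskd_tx_low_egfr * low_egfr

        for k in range(K):
            if k > 0:
                rng = lambda var: self._rng(_DYN, k, var, seed)
                sua_prev, logscr_prev, tx_prev = sua, logscr, tx
                mean_sua = ((1.0 - dyn.sua_rho) * setpoint
                            + dyn.sua_rho * sua_prev
                            + dyn.sua_scr_coef * logscr_prev
                            + dyn.sua_tx_effect * tx_prev
                            + dyn.sua_quadratic * (sua_prev - 6.0) ** 2)
                sua = np.maximum(mean_sua + rng(0).normal(0.0, dyn.sua_sd, n),
                                 dyn.sua_floor)
                mean_logscr = ((1.0 - dyn.scr_rho) * log_scr0
                               + dyn.scr_rho * logscr_prev
                               + dyn.scr_drift
                               + dyn.scr_sua_coef * sua_prev)
                logscr = mean_logscr + rng(1).normal(0.0, dyn.scr_sd, n)
                p_dm = expit(dyn.dm_intercept + dyn.dm_age_coef * (age + 0.5 * k))
                dm = np.maximum(dm, (rng(2).random(n) < p_dm).astype(int))
                p_htn = expit(dyn.htn_intercept + dyn.htn_age_coef * (age + 0.5 * k))
                htn = np.maximum(htn, (rng(3).random(n) < p_htn).astype(int))
                p_dial = expit(dyn.dialysis_intercept
                               + dyn.dialysis_logscr_coef * logscr_prev)
                dial = np.maximum(dial, (rng(4).random(n) < p_dial).astype(int))
                tx = tx_prev.copy()

            # treatment decision from current-interval labs
            if strategy.kind == "never":
                pass  # tx stays 0
            elif strategy.kind == "threshold":
                tx = np.maximum(tx, (sua >= strategy.tau).astype(int))
            else:  # natural course: clinician initiation model
                p_tx = expit(rx.intercept + rx.sua_coef * sua + rx.time_coef * k)
                u = self._rng(_DYN, k, 5, seed).random(n)
                tx = np.maximum(tx, (u < p_tx).astype(int))

            # event hazards from current state
            age_k = age + 0.5 * k
            p_death = expit(hz.death_intercept + hz.death_age * age_k
                            + hz.death_sua * sua + hz.death_logscr * logscr
                            + hz.death_dialysis * dial + death_tx * tx)
            p_eskd = expit(hz.eskd_intercept + hz.eskd_age * age_k
                           + hz.eskd_sua * sua + hz.eskd_logscr * logscr
                           + eskd_tx * tx)

            if collect_panels:
                for name, arr in (("sua", sua), ("logscr", logscr), ("dm", dm),
                                  ("htn", htn), ("dialysis", dial), ("tx", tx),
                                  ("p_death", p_death), ("p_eskd", p_eskd)):
                    panels[name].append(arr.copy())
            if track_risk:
                cif_eskd = cif_eskd + surv_both * (1.0 - p_death) * p_eskd
                surv_both = surv_both * (1.0 - p_death) * (1.0 - p_eskd)
                surv_net = surv_net * (1.0 - p_death)
                v_d = 1.0 - surv_net
                death_curve[k] = v_d.mean()
                death_se[k] = v_d.std() / np.sqrt(n)
                eskd_curve[k] = cif_eskd.mean()
                eskd_se[k] = cif_eskd.std() / np.sqrt(n)

        out = {}
        if collect_panels:
            out["panels"] = {c: np.column_stack(v) for c, v in panels.items()}
        if track_risk:
            out["risk"] = RiskCurveTruth(strategy.label, death_curve, eskd_curve,
                                         death_se, eskd_se, n)
        return out

    # -- trajectories --------------------------------------------------------
    def simulate_trajectories(self, baseline: pd.DataFrame,
                              strategy: StrategySpec = StrategySpec(kind="natural"),
                              seed: Optional[int] = None) -> TrajectorySet:
        """Simulate factual (natural course) or forced-strategy trajectories.

        Events are drawn interval by interval; a trajectory ends at its first
        terminal event (death precedes and precludes ESKD within an interval).
        """
        cfg = self.config
        n, K = len(baseline), cfg.n_intervals
        if n == 0:
            cols = ["patient_id", "k", "sua", "scr", "dm", "htn", "dialysis",
                    "tx", "event_death", "event_eskd"]
            return TrajectorySet(pd.DataFrame({c: pd.Series(dtype=float) for c in cols}),
                                 strategy.label, 0, K)
        res = self._forward(baseline, strategy, collect_panels=True,
                            track_risk=False, seed=seed)
        panels = res["panels"]

        alive = np.ones(n, dtype=bool)
        end_k = np.full(n, K - 1, dtype=int)
        event = np.zeros((n, 2), dtype=int)  # columns: death, eskd
        for k in range(K):
            u_d = self._rng(_DYN, k, 6, seed).random(n)
            u_e = self._rng(_DYN, k, 7, seed).random(n)
            p_d = panels["p_death"][:, k]
            p_e = panels["p_eskd"][:, k]
            died = alive & (u_d < p_d)
            eskd = alive & ~died & (u_e < p_e)
            for ev, col in ((died, 0), (eskd, 1)):
                newly = ev
                event[newly, col] = 1
                end_k[newly] = k
            alive &= ~(died | eskd)

        ks = np.arange(K)
        keep = ks[None, :] <= end_k[:, None]          # (n, K) mask
        pid = np.repeat(baseline["patient_id"].to_numpy(int), end_k + 1)
        kk = np.concatenate([ks[: e + 1] for e in end_k])
        rows = {
            "patient_id": pid,
            "k": kk,
        }
        for name in ("sua", "logscr", "dm", "htn", "dialysis", "tx"):
            rows[name] = panels[name][keep]
        df = pd.DataFrame(rows)
        df["scr"] = np.exp(df.pop("logscr"))
        is_last = df["k"].to_numpy() == np.repeat(end_k, end_k + 1)
        df["event_death"] = (is_last & np.repeat(event[:, 0], end_k + 1).astype(bool)).astype(int)
        df["event_eskd"] = (is_last & np.repeat(event[:, 1], end_k + 1).astype(bool)).astype(int)
        df = df[["patient_id", "k", "sua", "scr", "dm", "htn", "dialysis",
                 "tx", "event_death", "event_eskd"]]
        return TrajectorySet(df, strategy.label, n, K)

    # -- observation process -------------------------------------------------
    def apply_observation_process(self, trajectories: TrajectorySet,
                                  baseline: pd.DataFrame,
                                  seed: Optional[int] = None) -> dict:
        """Overlay the observation layer on factual trajectories.

        Produces a raw bundle of three tables mimicking EMR extraction:

        * ``patients`` — baseline covariates, comorbidity onset days, the first
          observed event (type/day) or administrative censoring day, and
          contamination tags exercising the eligibility filters;
        * ``labs`` — day-stamped sUA/sCr measurements (one visit per measured
          interval; interval 0 is always measured);
        * ``rx`` — urate-lowering prescription episodes (start/end days).
        """
        cfg = self.config
        obs = cfg.observation_params
        n, K = trajectories.n_patients, cfg.n_intervals
        df = trajectories.data
        if trajectories.strategy != "natural":
            raise ValueError("observation process applies to natural-course trajectories")

        def rng(var, k=0):
            return self._rng(_OBS, k, var, seed)

        pat = baseline.copy().reset_index(drop=True)

        # administrative censoring from staggered enrollment
        u = rng(0).random(n)
        max_follow_days = (obs.followup_years - obs.enroll_span_years * u) * 365.25
        max_follow_days = np.minimum(max_follow_days, K * DAYS_PER_INTERVAL)
        admin_day = np.maximum(max_follow_days, 1.0)

        # event day drawn uniformly within the event interval
        last = df.groupby("patient_id").tail(1).set_index("patient_id")
        end_k = last["k"].reindex(pat["patient_id"]).to_numpy(int)
        ev_death = last["event_death"].reindex(pat["patient_id"]).to_numpy(int)
        ev_eskd = last["event_eskd"].reindex(pat["patient_id"]).to_numpy(int)
        u_day = rng(1).random(n)
        event_day = (end_k + u_day) * DAYS_PER_INTERVAL
        has_event = (ev_death + ev_eskd) > 0
        observed_event = has_event & (event_day <= admin_day)
        event_type = np.where(observed_event,
                              np.where(ev_death == 1, "death", "eskd"), "none")
        event_day_out = np.where(observed_event, event_day, np.nan)
        censor_day = np.where(observed_event, np.nan,
                              np.minimum(admin_day, (end_k + 1) * DAYS_PER_INTERVAL))

        # comorbidity onset days from the trajectory (first interval with flag 1)
        def onset_days(col, baseline_flag):
            g = df[df[col] == 1].groupby("patient_id")["k"].min()
            onset = g.reindex(pat["patient_id"]).to_numpy(float) * DAYS_PER_INTERVAL
            onset[pat[baseline_flag].to_numpy(int) == 1] = 0.0
            return onset

        pat["dm_onset_day"] = onset_days("dm", "dm0")
        pat["htn_onset_day"] = onset_days("htn", "htn0")
        g = df[df["dialysis"] == 1].groupby("patient_id")["k"].min()
        pat["dialysis_onset_day"] = g.reindex(pat["patient_id"]).to_numpy(float) * DAYS_PER_INTERVAL
        pat["event_type"] = event_type
        pat["event_day"] = event_day_out
        pat["censor_day"] = censor_day
        pat["eskd_at_enroll"] = 0

        # follow-up end in days (for labs / prescriptions)
        follow_end = np.where(observed_event, event_day, censor_day)

        # lab visits: interval 0 always measured, later intervals w.p. lab_measure_prob
        lab_frames = []
        for k in range(K):
            measured = np.ones(n, dtype=bool) if k == 0 else (
                rng(2, k).random(n) < obs.lab_measure_prob)
            day = (k + (0.0 if k == 0 else 0.5)) * DAYS_PER_INTERVAL
            day = np.full(n, day) if k == 0 else (
                (k + rng(3, k).random(n)) * DAYS_PER_INTERVAL)
            in_follow = (k <= end_k) & (day <= follow_end + 1e-9)
            idx = measured & in_follow
            if not idx.any():
                continue
            sub = df[df["k"] == k].set_index("patient_id")
            pids = pat.loc[idx, "patient_id"].to_numpy(int)
            lab_frames.append(pd.DataFrame({
                "patient_id": pids,
                "day": day[idx],
                "sua": sub["sua"].reindex(pids).to_numpy(float),
                "scr": sub["scr"].reindex(pids).to_numpy(float),
            }))
        labs = (pd.concat(lab_frames, ignore_index=True)
                .sort_values(["patient_id", "day"]).reset_index(drop=True)
                if lab_frames else
                pd.DataFrame(columns=["patient_id", "day", "sua", "scr"]))

        # prescription episodes for ever-treated patients
        first_tx = df[df["tx"] == 1].groupby("patient_id")["k"].min()
        rx_rows = []
        for pid, t0 in first_tx.items():
            i = int(pid)
            start = max(91.0, t0 * DAYS_PER_INTERVAL - 179.5)
            end = float(follow_end[i])
            if start < end:
                rx_rows.append((i, start, end))
        rx = pd.DataFrame(rx_rows, columns=["patient_id", "start_day", "end_day"])

        # contamination tags (exercise the eligibility filters)
        if obs.prior_ula_frac > 0:
            tag = rng(4).random(n) < obs.prior_ula_frac
            extra = pd.DataFrame({
                "patient_id": pat.loc[tag, "patient_id"].to_numpy(int),
                "start_day": -10.0, "end_day": 50.0})
            rx = pd.concat([rx, extra], ignore_index=True)
        if obs.early_outcome_frac > 0:
            tag = rng(5).random(n) < obs.early_outcome_frac
            pat.loc[tag, "event_type"] = "death"
            pat.loc[tag, "event_day"] = rng(6).random(tag.sum()) * 89.0
            pat.loc[tag, "censor_day"] = np.nan
        if obs.non_ckd_frac > 0:
            eligible = (pat["egfr0"] >= 60.0) & (pat["albuminuria"] == 1)
            tag = (rng(7).random(n) < obs.non_ckd_frac) & eligible.to_numpy()
            pat.loc[tag, "albuminuria"] = 0
        if obs.eskd_at_enroll_frac > 0:
            tag = rng(8).random(n) < obs.eskd_at_enroll_frac
            pat.loc[tag, "eskd_at_enroll"] = 1

        rx = rx.sort_values(["patient_id", "start_day"]).reset_index(drop=True)
        return {"patients": pat, "labs": labs, "rx": rx}

    # -- brute-force counterfactual truth ------------------------------------
    def true_risk_curves(self, strategy: StrategySpec,
                         n_sim: int = 100_000) -> RiskCurveTruth:
        """Oracle risk curves under a forced strategy.

        A large independent cohort is drawn from the baseline distribution and
        pushed through the true covariate process under the strategy; per-
        interval hazards are accumulated analytically (death: net risk
        1 - prod(1 - h_d); ESKD: cumulative incidence with death competing).
        """
        oracle_seed = int((self.config.seed + 1_000_003) % (2**31))
        baseline = self.sample_baseline(n=n_sim, seed=oracle_seed)
        res = self._forward(baseline, strategy, collect_panels=False,
                            track_risk=True, seed=oracle_seed)
        return res["risk"]

    def true_counterfactual_risk(self, strategy: StrategySpec, horizon_k: int,
                                 outcome: str = "death",
                                 n_sim: int = 100_000) -> float:
        """Cumulative ``outcome`` risk after ``horizon_k`` intervals under the
        forced strategy (the g-formula recovery target)."""
        if horizon_k > self.config.n_intervals:
            raise ValueError("horizon_k exceeds the simulated follow-up")
        if outcome not in ("death", "eskd"):
            raise ValueError("outcome must be 'death' or 'eskd'")
        if horizon_k == 0:
            return 0.0
        return self.true_risk_curves(strategy, n_sim=n_sim).risk(outcome, horizon_k)


# ---------------------------------------------------------------------------
# module-level wrappers (spec-facing operation names)
# ---------------------------------------------------------------------------

def sample_baseline(config: GeneratorConfig) -> pd.DataFrame:
    return CohortGenerator(config).sample_baseline()


def simulate_trajectories(config: GeneratorConfig, baseline: pd.DataFrame,
                          strategy: StrategySpec) -> TrajectorySet:
    return CohortGenerator(config).simulate_trajectories(baseline, strategy)


def apply_observation_process(trajectories: TrajectorySet,
                              config: GeneratorConfig,
                              baseline: pd.DataFrame) -> dict:
    return CohortGenerator(config).apply_observation_process(trajectories, baseline)


def true_counterfactual_risk(config: GeneratorConfig, strategy: StrategySpec,
                             horizon_k: int, outcome: str = "death",
                             n_sim: int = 100_000) -> float:
    return CohortGenerator(config).true_counterfactual_risk(
        strategy, horizon_k, outcome, n_sim=n_sim)


def trajectories_to_person_intervals(trajectories: TrajectorySet,
                                     baseline: pd.DataFrame) -> pd.DataFrame:
    """Convert uncensored trajectories directly into the analysis-ready
    person-interval layout (fully measured, no censoring).

    Used for correct-specification studies where the observation layer would
    only add noise; the column contract matches the preparation pipeline.
    """
    df = trajectories.data.merge(
        baseline[["patient_id", "age", "male", "bmi", "bmi_missing", "dyslip0",
                  "dm0", "htn0", "sua0", "log_scr0", "albumin0", "hgb0",
                  "egfr0"]],
        on="patient_id", how="left")
    bmi_med = float(np.nanmedian(baseline["bmi"])) if len(baseline) else 0.0
    df["bmi"] = df["bmi"].fillna(bmi_med)
    df["log_scr"] = np.log(df["scr"])
    df["egfr"] = compute_egfr(df["scr"].to_numpy(float),
                              (df["age"] + 0.5 * df["k"]).to_numpy(float),
                              df["male"].to_numpy(int))
    df["censored"] = 0
    df["measured_sua"] = 1
    df["measured_scr"] = 1
    return df
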