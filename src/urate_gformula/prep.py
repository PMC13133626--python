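"""Cohort preparation: from raw observed records to the analysis-ready
person-interval table.

Steps (in order): eligibility filters with an exclusion tally, derivation of
urate-lowering-agent (ULA) status from prescription episodes (>180 cumulative
days rule), restructuring of follow-up into 6-month intervals, last-
observation-carried-forward (LOCF) imputation of the time-varying labs, lab-gap
censoring (no sUA/sCr measurement over 24 months), and CKD-EPI eGFR derivation.

The pipeline is deterministic: identical input yields byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import DAYS_PER_INTERVAL
from .egfr import compute_egfr

logger = logging.getLogger(__name__)

EARLY_OUTCOME_DAYS = 90.0     # "outcome within 3 months" -> event day < 90
PRIOR_ULA_WINDOW = (-30.0, 90.0)
ULA_CUMULATIVE_DAYS = 180.0   # prescribed strictly beyond 180 cumulative days

ANALYSIS_COLUMNS = [
    "patient_id", "k", "sua", "scr", "log_scr", "egfr", "dm", "htn",
    "dialysis", "tx", "event_death", "event_eskd", "censored",
    "measured_sua", "measured_scr", "age", "male", "bmi", "bmi_missing",
    "dm0", "htn0", "dyslip0", "sua0", "log_scr0", "albumin0", "hgb0", "egfr0",
]


@dataclass
class ExclusionTally:
    """Patients removed by each eligibility rule (first matching rule counts)."""

    input_size: int = 0
    not_ckd: int = 0
    eskd_at_enrollment: int = 0
    early_outcome: int = 0
    prior_ula: int = 0
    retained: int = 0

    def as_dict(self) -> dict:
        return {
            "input_size": self.input_size, "not_ckd": self.not_ckd,
            "eskd_at_enrollment": self.eskd_at_enrollment,
            "early_outcome": self.early_outcome, "prior_ula": self.prior_ula,
            "retained": self.retained,
        }

    def check(self) -> None:
        removed = (self.not_ckd + self.eskd_at_enrollment
                   + self.early_outcome + self.prior_ula)
        if removed + self.retained != self.input_size:
            raise AssertionError("exclusion tally does not reconcile")


def apply_eligibility(raw: dict) -> tuple[dict, ExclusionTally]:
    """Apply the enrollment eligibility filters to a raw bundle.

    Retains patients meeting the CKD definition (baseline eGFR < 60 sustained,
    or the albuminuria kidney-damage marker); removes ESKD at enrollment,
    outcomes within 3 months, and ULA exposure in the [-30, +90] day window.
    """
    pat = raw["patients"]
    required = {"egfr0", "albuminuria", "eskd_at_enroll", "event_type", "event_day"}
    missing = required - set(pat.columns)
    if missing:
        raise ValueError(f"raw patients table missing columns: {sorted(missing)}")

    tally = ExclusionTally(input_size=len(pat))
    is_ckd = (pat["egfr0"] < 60.0) | (pat["albuminuria"] == 1)
    eskd0 = pat["eskd_at_enroll"] == 1
    early = (pat["event_type"] != "none") & (pat["event_day"] < EARLY_OUTCOME_DAYS)

    rx = raw["rx"]
    lo, hi = PRIOR_ULA_WINDOW
    in_window = rx[(rx["start_day"] <= hi) & (rx["end_day"] >= lo)]
    prior_ula_ids = set(in_window["patient_id"].astype(int))
    prior = pat["patient_id"].astype(int).isin(prior_ula_ids)

    drop_not_ckd = ~is_ckd
    drop_eskd0 = is_ckd & eskd0
    drop_early = is_ckd & ~eskd0 & early
    drop_prior = is_ckd & ~eskd0 & ~early & prior
    keep = is_ckd & ~eskd0 & ~early & ~prior

    tally.not_ckd = int(drop_not_ckd.sum())
    tally.eskd_at_enrollment = int(drop_eskd0.sum())
    tally.early_outcome = int(drop_early.sum())
    tally.prior_ula = int(drop_prior.sum())
    tally.retained = int(keep.sum())
    tally.check()

    kept_ids = set(pat.loc[keep, "patient_id"].astype(int))
    out = {
        "patients": pat[keep].reset_index(drop=True),
        "labs": raw["labs"][raw["labs"]["patient_id"].isin(kept_ids)].reset_index(drop=True),
        "rx": rx[rx["patient_id"].isin(kept_ids)].reset_index(drop=True),
    }
    logger.info("eligibility: %s", tally.as_dict())
    return out, tally


def merge_episodes(episodes) -> list[tuple[float, float]]:
    """Merge overlapping (start_day, end_day) prescription episodes."""
    eps = sorted((float(s), float(e)) for s, e in episodes)
    for s, e in eps:
        if e < s:
            raise ValueError(f"episode end {e} precedes start {s}")
    merged: list[list[float]] = []
    for s, e in eps:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_ula_status(episodes, n_intervals: int) -> np.ndarray:
    """Per-interval treatment flags from prescription episodes.

    A patient counts as "prescribed" from the first 6-month interval by whose
    end the cumulative covered days (from enrollment onward) strictly exceed
    180; the status is absorbing. Dosages are ignored.
    """
    merged = merge_episodes(episodes)
    flags = np.zeros(n_intervals, dtype=int)
    if not merged:
        return flags
    ends = (np.arange(n_intervals) + 1) * DAYS_PER_INTERVAL
    cum = np.zeros(n_intervals)
    for s, e in merged:
        s = max(s, 0.0)
        cum += np.clip(np.minimum(e, ends) - s, 0.0, None)
    flags[cum > ULA_CUMULATIVE_DAYS] = 1
    return np.maximum.accumulate(flags)


def discretize_intervals(raw: dict, n_intervals: int) -> pd.DataFrame:
    """Restructure day-stamped records into one row per patient per 6-month
    interval (interval k covers days [182.625*k, 182.625*(k+1))).

    Within-interval labs are summarized by the last measurement; the event is
    assigned to the interval containing its day; follow-up ends at the event
    or censoring interval. Labs are left missing (NaN) where unmeasured —
    imputation is a separate step.
    """
    pat = raw["patients"].reset_index(drop=True)
    labs, rx = raw["labs"], raw["rx"]
    n = len(pat)
    if n == 0:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS)

    end_day = pat["event_day"].fillna(pat["censor_day"]).to_numpy(float)
    end_k = np.clip(np.floor(end_day / DAYS_PER_INTERVAL).astype(int),
                    0, n_intervals - 1)
    has_death = (pat["event_type"] == "death").to_numpy()
    has_eskd = (pat["event_type"] == "eskd").to_numpy()

    counts = end_k + 1
    pid = np.repeat(pat["patient_id"].to_numpy(int), counts)
    kk = np.concatenate([np.arange(c) for c in counts])
    df = pd.DataFrame({"patient_id": pid, "k": kk})
    if df.duplicated(["patient_id", "k"]).any():
        raise ValueError("duplicate patient-interval keys")

    # last lab measurement within each interval
    lb = labs.copy()
    lb["k"] = np.floor(lb["day"].to_numpy(float) / DAYS_PER_INTERVAL).astype(int)
    lb = lb.sort_values(["patient_id", "k", "day"])
    last = lb.groupby(["patient_id", "k"], as_index=False).last()
    df = df.merge(last[["patient_id", "k", "sua", "scr"]],
                  on=["patient_id", "k"], how="left")
    df["measured_sua"] = df["sua"].notna().astype(int)
    df["measured_scr"] = df["scr"].notna().astype(int)

    # absorbing comorbidity flags from onset days
    for col, onset in (("dm", "dm_onset_day"), ("htn", "htn_onset_day"),
                       ("dialysis", "dialysis_onset_day")):
        onset_k = np.floor(pat[onset].to_numpy(float) / DAYS_PER_INTERVAL)
        df[col] = (df["k"].to_numpy() >= np.repeat(onset_k, counts)).astype(int)

    # treatment status from prescription episodes
    tx_flags = np.zeros(len(df), dtype=int)
    rx_by_pid = {int(p): g[["start_day", "end_day"]].to_numpy()
                 for p, g in rx.groupby("patient_id")}
    offset = 0
    for i in range(n):
        c = counts[i]
        eps = rx_by_pid.get(int(pat["patient_id"].iloc[i]))
        if eps is not None:
            tx_flags[offset:offset + c] = derive_ula_status(eps, n_intervals)[:c]
        offset += c
    df["tx"] = tx_flags

    is_last = df["k"].to_numpy() == np.repeat(end_k, counts)
    df["event_death"] = (is_last & np.repeat(has_death, counts)).astype(int)
    df["event_eskd"] = (is_last & np.repeat(has_eskd, counts)).astype(int)
    df["censored"] = (is_last & np.repeat(~(has_death | has_eskd), counts)).astype(int)

    # baseline covariates (median-imputed BMI with indicator)
    base_cols = ["patient_id", "age", "male", "bmi", "bmi_missing", "dm0",
                 "htn0", "dyslip0", "sua0", "log_scr0", "albumin0", "hgb0",
                 "egfr0"]
    base = pat[base_cols].copy()
    bmi_med = float(np.nanmedian(base["bmi"])) if base["bmi"].notna().any() else 0.0
    base["bmi"] = base["bmi"].fillna(bmi_med)
    df = df.merge(base, on="patient_id", how="left")
    return df


def locf_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing sUA/sCr by carrying the most recent observation forward;
    leading gaps are filled from the baseline labs. Idempotent."""
    df = table.sort_values(["patient_id", "k"]).reset_index(drop=True)
    g = df.groupby("patient_id")
    df["sua"] = g["sua"].ffill()
    df["scr"] = g["scr"].ffill()
    df["sua"] = df["sua"].fillna(df["sua0"])
    df["scr"] = df["scr"].fillna(np.exp(df["log_scr0"]))
    if df["sua"].isna().any() or df["scr"].isna().any():
        bad = df.loc[df["sua"].isna() | df["scr"].isna(), "patient_id"].unique()
        raise ValueError(f"no baseline or observed lab value for patients {bad[:5]}")
    return df


def apply_gap_censoring(table: pd.DataFrame, gap_intervals: int = 4,
                        rule: str = "both") -> pd.DataFrame:
    """Censor patients with no lab measurements over more than 24 months.

    ``rule='both'`` (default): a gap interval is one where *neither* sCr nor
    sUA was measured; ``'either'``: where at least one is unmeasured. A run of
    more than ``gap_intervals`` consecutive gap intervals censors the patient
    at the end of the ``gap_intervals``-th unmeasured interval; later rows are
    dropped (including any event beyond the censoring point).
    """
    df = table.sort_values(["patient_id", "k"]).reset_index(drop=True)
    if rule == "both":
        gap = ((df["measured_sua"] == 0) & (df["measured_scr"] == 0)).astype(int)
    elif rule == "either":
        gap = ((df["measured_sua"] == 0) | (df["measured_scr"] == 0)).astype(int)
    else:
        raise ValueError("rule must be 'both' or 'either'")

    pid = df["patient_id"]
    block = (gap == 0).groupby(pid).cumsum()
    run = gap.groupby([pid, block]).cumsum()

    breach = run == gap_intervals + 1
    first_breach = df.loc[breach].groupby("patient_id")["k"].min()
    cutoff = first_breach - 1  # end of the gap_intervals-th unmeasured interval
    cut = df["patient_id"].map(cutoff)

    n_before = len(df)
    keep = cut.isna() | (df["k"] <= cut)
    df = df.loc[keep].copy()
    at_cut = df["patient_id"].map(cutoff).notna() & (df["k"] == df["patient_id"].map(cutoff))
    df.loc[at_cut, ["event_death", "event_eskd"]] = 0
    df.loc[at_cut, "censored"] = 1
    # rows before a new censoring point cannot carry a terminal flag
    before_cut = df["patient_id"].map(cutoff).notna() & (df["k"] < df["patient_id"].map(cutoff))
    df.loc[before_cut, "censored"] = 0
    logger.info("gap censoring: dropped %d of %d rows", n_before - len(df), n_before)
    return df.reset_index(drop=True)


def finalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derived columns (log sCr, time-updated CKD-EPI eGFR) and column order."""
    df = table.copy()
    df["log_scr"] = np.log(df["scr"].to_numpy(float))
    df["egfr"] = compute_egfr(df["scr"].to_numpy(float),
                              (df["age"] + 0.5 * df["k"]).to_numpy(float),
                              df["male"].to_numpy(int))
    return df[ANALYSIS_COLUMNS]


class CohortPreprocessor(BaseEstimator, TransformerMixin):
    """End-to-end preparation transformer over a raw bundle.

    Parameters
    ----------
    n_intervals : follow-up length in 6-month intervals.
    gap_censoring : apply the 24-month lab-gap censoring rule.
    gap_intervals : gap length (intervals) beyond which censoring applies.
    gap_rule : 'both' (neither lab measured) or 'either'.

    After :meth:`fit`, ``exclusions_`` holds the eligibility tally.
    """

    def __init__(self, n_intervals: int = 44, gap_censoring: bool = True,
                 gap_intervals: int = 4, gap_rule: str = "both"):
        self.n_intervals = n_intervals
        self.gap_censoring = gap_censoring
        self.gap_intervals = gap_intervals
        self.gap_rule = gap_rule

    def fit(self, X: dict, y=None):
        _, self.exclusions_ = apply_eligibility(X)
        return self

    def transform(self, X: dict) -> pd.DataFrame:
        filtered, _ = apply_eligibility(X)
        table = discretize_intervals(filtered, self.n_intervals)
        table = locf_impute(table)
        if self.gap_censoring:
            table = apply_gap_censoring(table, self.gap_intervals, self.gap_rule)
        return finalize_table(table)

    def fit_transform(self, X: dict, y=None, **kwargs) -> pd.DataFrame:
        self.fit(X)
        return self.transform(X)
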