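"""Configuration objects for the synthetic CKD cohort generator and treatment strategies.

The generator emulates a hospital-based chronic kidney disease cohort followed in
6-month intervals: baseline demographics, labs and comorbidities; lag-1
autoregressive serum urate (sUA) and serum creatinine (sCr) dynamics with
treatment-confounder feedback (urate-lowering therapy lowers sUA, sUA accelerates
creatinine rise, both labs drive clinician prescribing and the event hazards); a
clinician treatment-initiation model; and discrete-time hazards for death and
end-stage kidney disease (ESKD).

All parameters live in one validated, serializable structure (`GeneratorConfig`)
so that every study condition is explicit and reproducible.
"""

from __future__ import annotations

import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

DAYS_PER_INTERVAL = 182.625  # 6 months
INTERVALS_PER_YEAR = 2


class BaselineParams(BaseModel):
    """Marginal baseline distributions of the cohort at enrollment."""

    age_mean: float = 51.02
    age_sd: float = Field(15.9, gt=0)
    age_min: float = 18.0
    age_max: float = 95.0
    male_prop: float = Field(0.493, ge=0.0, le=1.0)
    bmi_mean: float = 24.0
    bmi_sd: float = Field(3.8, gt=0)
    bmi_missing_prop: float = Field(0.31, ge=0.0, le=1.0)
    dm_prev: float = Field(0.2796, ge=0.0, le=1.0)
    htn_prev: float = Field(0.478, ge=0.0, le=1.0)
    dyslip_prev: float = Field(0.258, ge=0.0, le=1.0)
    # baseline serum creatinine on the log scale (median ~1.0 mg/dl, right skew)
    log_scr_mean: float = 0.0
    log_scr_sd: float = Field(0.45, gt=0)
    # baseline serum urate doubles as the patient's long-run set-point
    sua_mean: float = 5.97
    sua_sd: float = Field(2.0, gt=0)
    sua_min: float = Field(1.5, gt=0)
    albumin_mean: float = 4.10
    albumin_sd: float = Field(0.52, gt=0)
    hgb_mean: float = 13.3
    hgb_sd: float = Field(1.99, gt=0)
    # probability of the albuminuria marker among patients with preserved eGFR
    # (>=60); they qualify as CKD through kidney damage, not low eGFR
    albuminuria_given_preserved: float = Field(1.0, ge=0.0, le=1.0)
    albuminuria_given_low_egfr: float = Field(0.40, ge=0.0, le=1.0)


class DynamicsParams(BaseModel):
    """Lag-1 covariate dynamics (all models conditional on the previous interval).

    sUA_k   = (1-rho_u)*setpoint + rho_u*sUA_{k-1} + c_scr*log sCr_{k-1}
              + tx_effect*tx_{k-1} [+ quad*(sUA_{k-1}-6)^2] + N(0, sd_u), floored
    logsCr_k = (1-rho_c)*logsCr_0 + rho_c*logsCr_{k-1} + drift
              + c_sua*sUA_{k-1} + N(0, sd_c)

    With rho_u = 0.75 a per-interval treatment effect of -0.5 mg/dl accumulates to
    a steady-state reduction of -2.0 mg/dl, a typical on-therapy urate drop.
    """

    sua_rho: float = Field(0.75, ge=0.0, lt=1.0)
    sua_scr_coef: float = 0.30
    sua_tx_effect: float = -0.5
    sua_sd: float = Field(0.8, gt=0)
    sua_floor: float = Field(0.5, gt=0)
    sua_quadratic: float = 0.0  # mild misspecification switch
    scr_rho: float = Field(0.90, ge=0.0, lt=1.0)
    scr_drift: float = 0.001
    scr_sua_coef: float = 0.0035
    scr_sd: float = Field(0.08, gt=0)
    # per-interval incidence (log-odds) of the chronic comorbidity flags
    dm_intercept: float = -6.2
    dm_age_coef: float = 0.010
    htn_intercept: float = -5.6
    htn_age_coef: float = 0.012
    dialysis_intercept: float = -8.0
    dialysis_logscr_coef: float = 2.4


class PrescriptionParams(BaseModel):
    """Clinician urate-lowering-therapy initiation model (natural course).

    Per-interval log-odds of starting therapy among the not-yet-treated:
    logit p = intercept + sua_coef * sUA_k + time_coef * k.
    Coefficients are calibrated (scripts/tune_generator.py) so that the
    ever-treated fraction, the median sUA at initiation and the median time to
    initiation match the emulated cohort.
    """

    intercept: float = -10.3406
    sua_coef: float = 0.7802
    time_coef: float = -0.027


class HazardParams(BaseModel):
    """Discrete-time event hazards, conditional on current-interval state.

    logit h_death = death_intercept + death_age*(age + 0.5k) + death_sua*sUA_k
                    + death_logscr*logsCr_k + death_dialysis*dialysis_k
                    + death_tx*tx_k
    logit h_eskd  = eskd_intercept + eskd_age*(age + 0.5k) + eskd_sua*sUA_k
                    + eskd_logscr*logsCr_k + eskd_tx*tx_k
    Death is drawn first within an interval and precludes ESKD (competing event).
    Optional extra treatment effects in the low-eGFR stratum allow effect-
    modification studies.
    """

    death_intercept: float = -9.7837
    death_age: float = 0.062
    death_sua: float = 0.10
    death_logscr: float = 0.60
    death_dialysis: float = 0.30
    death_tx: float = -0.10
    eskd_intercept: float = -7.0815
    eskd_age: float = 0.010
    eskd_sua: float = 0.14
    eskd_logscr: float = 1.80
    eskd_tx: float = -0.05
    # additional log-hazard treatment effect for patients with baseline eGFR < 60
    death_tx_low_egfr: float = 0.0
    eskd_tx_low_egfr: float = 0.0


class ObservationParams(BaseModel):
    """Observation layer applied on top of the factual trajectories."""

    lab_measure_prob: float = Field(0.80, ge=0.0, le=1.0)
    # enrollment is uniform over this many calendar years before the data-lock
    # window closes; follow-up is capped at followup_years
    enroll_span_years: float = Field(18.0, ge=0.0)
    followup_years: float = Field(22.0, gt=0.0)
    prior_ula_frac: float = Field(0.0, ge=0.0, le=1.0)
    early_outcome_frac: float = Field(0.0, ge=0.0, le=1.0)
    non_ckd_frac: float = Field(0.0, ge=0.0, le=1.0)
    eskd_at_enroll_frac: float = Field(0.0, ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    """Complete specification of a synthetic cohort study."""

    n_patients: int = Field(27260, ge=0)
    n_intervals: int = Field(44, ge=1)
    seed: int = 20260101
    baseline_params: BaselineParams = BaselineParams()
    dynamics_params: DynamicsParams = DynamicsParams()
    prescription_params: PrescriptionParams = PrescriptionParams()
    hazard_params: HazardParams = HazardParams()
    observation_params: ObservationParams = ObservationParams()

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        return cls.model_validate_json(text)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls.model_validate(yaml.safe_load(text))

    def save(self, path) -> None:
        path = str(path)
        text = self.to_yaml() if path.endswith((".yml", ".yaml")) else self.to_json()
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "GeneratorConfig":
        path = str(path)
        with open(path) as fh:
            text = fh.read()
        if path.endswith((".yml", ".yaml")):
            return cls.from_yaml(text)
        return cls.from_json(text)


class StrategySpec(BaseModel):
    """A treatment strategy: natural course, threshold initiation, or never treat."""

    kind: Literal["natural", "threshold", "never"]
    tau: Optional[float] = None  # mg/dl, required iff kind == "threshold"

    @model_validator(mode="after")
    def _check_tau(self):
        if self.kind == "threshold":
            if self.tau is None:
                raise ValueError("threshold strategy requires tau")
            if self.tau not in (7.0, 8.0, 9.0, 10.0):
                raise ValueError("tau must be one of 7, 8, 9, 10 mg/dl")
        elif self.tau is not None:
            raise ValueError(f"{self.kind} strategy must not set tau")
        return self

    @property
    def label(self) -> str:
        if self.kind == "threshold":
            return f"tau{int(self.tau)}"
        return self.kind

    @classmethod
    def from_label(cls, label: str) -> "StrategySpec":
        label = label.strip().lower()
        if label in ("natural", "never"):
            return cls(kind=label)
        if label.startswith("tau"):
            return cls(kind="threshold", tau=float(label[3:]))
        raise ValueError(f"unknown strategy label: {label!r}")


NATURAL = StrategySpec(kind="natural")
NEVER = StrategySpec(kind="never")


def all_strategies() -> list[StrategySpec]:
    """The six strategies compared: natural course, tau 10/9/8/7, never treat."""
    return [
        NATURAL,
        StrategySpec(kind="threshold", tau=10.0),
        StrategySpec(kind="threshold", tau=9.0),
        StrategySpec(kind="threshold", tau=8.0),
        StrategySpec(kind="threshold", tau=7.0),
        NEVER,
    ]


# ---------------------------------------------------------------------------
# preset configurations used in tests and validation studies
# ---------------------------------------------------------------------------

def default_config(**overrides) -> GeneratorConfig:
    """The calibrated main-cohort configuration (n = 27 260, 44 intervals)."""
    return GeneratorConfig(**overrides)


def small_config(n_patients: int = 500, n_intervals: int = 44, seed: int = 7,
                 **overrides) -> GeneratorConfig:
    """A scaled-down cohort for unit tests."""
    return GeneratorConfig(n_patients=n_patients, n_intervals=n_intervals,
                           seed=seed, **overrides)


def fully_observed_config(**overrides) -> GeneratorConfig:
    """Default dynamics with every lab measured and no contamination.

    With complete measurement the fitted component models are correctly
    specified for the generator, so g-formula estimates should recover the
    brute-force counterfactual truth.
    """
    cfg = GeneratorConfig(**overrides)
    cfg.observation_params.lab_measure_prob = 1.0
    cfg.observation_params.prior_ula_frac = 0.0
    cfg.observation_params.early_outcome_frac = 0.0
    return cfg


def null_effect_config(**overrides) -> GeneratorConfig:
    """Treatment has no effect on labs or hazards: all strategies share one truth."""
    cfg = fully_observed_config(**overrides)
    cfg.dynamics_params.sua_tx_effect = 0.0
    cfg.hazard_params.death_tx = 0.0
    cfg.hazard_params.eskd_tx = 0.0
    return cfg


def confounded_config(**overrides) -> GeneratorConfig:
    """Strong confounding by indication: initiation is triggered sharply by the
    current urate level, the hazards depend strongly on urate, and the entire
    treatment benefit is mediated through the sUA reduction (no direct hazard
    effect). A lag-adjusted time-varying Cox model is biased toward harm here
    (its CI reaches the null despite a strongly protective truth) while the
    g-formula recovers the forced-strategy truth."""
    cfg = fully_observed_config(**overrides)
    cfg.hazard_params.death_tx = 0.0
    cfg.hazard_params.eskd_tx = 0.0
    cfg.hazard_params.death_sua = 0.30
    cfg.hazard_params.eskd_sua = 0.30
    cfg.dynamics_params.sua_sd = 1.3
    rx = cfg.prescription_params
    level_at_9 = rx.intercept + 9.0 * rx.sua_coef
    rx.sua_coef = 2.2
    rx.intercept = level_at_9 - 9.0 * rx.sua_coef
    return cfg


def effect_modification_config(**overrides) -> GeneratorConfig:
    """Protective treatment effect concentrated in the low-eGFR stratum."""
    cfg = fully_observed_config(**overrides)
    cfg.hazard_params.death_tx = -0.05
    cfg.hazard_params.eskd_tx = -0.05
    cfg.hazard_params.death_tx_low_egfr = -0.35
    cfg.hazard_params.eskd_tx_low_egfr = -0.35
    return cfg
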