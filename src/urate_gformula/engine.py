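"""Step 2 of the parametric g-formula: Monte Carlo standardization.

Pseudo-subjects are resampled from the analysis cohort's baseline rows and
their covariate histories simulated forward from the fitted component models;
at each interval the treatment rule of the strategy under study is applied
(natural course: draw from the fitted initiation model; threshold tau:
initiate once current sUA >= tau, absorbing; never: no treatment), and the
discrete-time hazards are accumulated into standardized cumulative risks
(for ESKD as a cumulative incidence with death as a competing event).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .config import StrategySpec, all_strategies
from .models import FittedModelSet, fit_model_set
from .spline import rcs_basis

logger = logging.getLogger(__name__)

BASELINE_STATE_COLS = ["age", "male", "bmi", "bmi_missing", "dm0", "htn0",
                       "dyslip0", "sua0", "log_scr0", "albumin0", "hgb0",
                       "egfr0"]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def threshold_decision(sua_k, tau: float, tx_prev):
    """Initiation rule: treat if already treated (absorbing) or sUA_k >= tau."""
    sua_k = np.asarray(sua_k, dtype=float)
    tx_prev = np.asarray(tx_prev, dtype=int)
    out = np.where((tx_prev == 1) | (sua_k >= tau), 1, 0)
    if out.ndim == 0:
        return int(out)
    return out


def cumulative_risk_from_hazards(h) -> float:
    """Discrete-time identity: risk = 1 - prod_j (1 - h_j); empty -> 0."""
    h = np.asarray(list(h), dtype=float)
    if h.size == 0:
        return 0.0
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hazards must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - h))


@dataclass
class RiskCurve:
    """Standardized cumulative risk after k+1 intervals, k = 0..K-1."""

    strategy: str
    risk_k: np.ndarray
    mc_size: int

    def __post_init__(self):
        r = np.asarray(self.risk_k, dtype=float)
        if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
            raise ValueError("risks must lie in [0, 1]")
        if np.any(np.diff(r) < -1e-9):
            raise ValueError("cumulative risk must be nondecreasing")
        self.risk_k = r

    def risk_at(self, horizon_k: int) -> float:
        if horizon_k == 0:
            return 0.0
        return float(self.risk_k[horizon_k - 1])

    @property
    def n_intervals(self) -> int:
        return len(self.risk_k)


@dataclass
class ContrastEstimate:
    """Per-strategy standardized risk and contrasts vs the natural course."""

    strategy: str
    horizon_years: float
    risk: float            # percent
    rr: float
    rd: float              # percentage points
    risk_ci: tuple = (None, None)
    rr_ci: tuple = (None, None)
    rd_ci: tuple = (None, None)


def baseline_frame(table: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with the baseline state used for standardization."""
    first = table[table["k"] == 0]
    return first[["patient_id"] + BASELINE_STATE_COLS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# forward simulation from fitted models
# ---------------------------------------------------------------------------

def _engine_rng(seed: int):
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))


def simulate_strategy(models: FittedModelSet, baseline: pd.DataFrame,
                      strategy: StrategySpec, mc_size: int, seed: int,
                      sua_floor: float = 0.5,
                      competing_death: bool = True) -> RiskCurve:
    """Simulate one strategy's standardized cumulative risk curve.

    ``baseline`` holds the analysis cohort's baseline rows; ``mc_size``
    pseudo-subjects are resampled from it with replacement under ``seed``.
    """
    if mc_size < 1:
        raise ValueError("mc_size must be >= 1")
    if strategy.kind == "natural" and "tx" not in models:
        raise ValueError("natural-course simulation requires a fitted tx component")
    K = models.n_intervals
    track_dialysis = "dialysis" in models
    outcome = models.outcome

    rng = _engine_rng(seed)
    idx = rng.integers(0, len(baseline), size=mc_size)
    base = baseline.iloc[idx].reset_index(drop=True)
    cols = {c: base[c].to_numpy(float) for c in BASELINE_STATE_COLS}
    cols["intercept"] = np.ones(mc_size)

    surv_net = np.ones(mc_size)
    surv_both = np.ones(mc_size)
    cif = np.zeros(mc_size)
    curve = np.empty(K)

    sua = cols["sua0"].copy()
    log_scr = cols["log_scr0"].copy()
    dm = cols["dm0"].astype(int).copy()
    htn = cols["htn0"].astype(int).copy()
    dial = np.zeros(mc_size, dtype=int)
    tx = np.zeros(mc_size, dtype=int)

    spline_all = rcs_basis(np.arange(K, dtype=float), models.knots)
    spline_names = [t for t in models["sua"].terms if t.startswith("k_rcs")]

    for k in range(K):
        for j, nm in enumerate(spline_names):
            cols[nm] = np.full(mc_size, spline_all[k, j])

        if k > 0:
            lag = {"sua_lag": sua, "log_scr_lag": log_scr, "dm_lag": dm,
                   "htn_lag": htn, "dialysis_lag": dial, "tx_lag": tx}
            cols.update({n: np.asarray(v, dtype=float) for n, v in lag.items()})
            comp = models["sua"]
            sua = comp.predict(cols) + rng.normal(
                0.0, comp.scale, mc_size)
            sua = np.maximum(sua, sua_floor)
            comp = models["scr"]
            log_scr = comp.predict(cols) + rng.normal(
                0.0, comp.scale, mc_size)
            p = models["dm"].predict(cols)
            dm = np.maximum(dm, (rng.random(mc_size) < p)
                            & (dm == 0)).astype(int)
            p = models["htn"].predict(cols)
            htn = np.maximum(htn, (rng.random(mc_size) < p)
                             & (htn == 0)).astype(int)
            if track_dialysis:
                p = models["dialysis"].predict(cols)
                dial = np.maximum(dial, (rng.random(mc_size) < p)
                                  & (dial == 0)).astype(int)

        cols["sua"] = sua
        cols["log_scr"] = log_scr
        cols["dm"] = dm.astype(float)
        cols["htn"] = htn.astype(float)
        cols["dialysis"] = dial.astype(float)

        # treatment decision from current-interval state
        if strategy.kind == "never":
            tx = np.zeros(mc_size, dtype=int)
        elif strategy.kind == "threshold":
            tx = threshold_decision(sua, strategy.tau, tx)
        else:
            p_tx = models["tx"].predict(cols)
            u = rng.random(mc_size)
            tx = np.maximum(tx, (u < p_tx).astype(int))
        cols["tx"] = tx.astype(float)

        if outcome == "death":
            h_d = models["death"].predict(cols)
            surv_net *= 1.0 - h_d
            curve[k] = 1.0 - surv_net.mean()
        else:
            h_d = models["death"].predict(cols)
            h_e = models["eskd"].predict(cols)
            if competing_death:
                cif = cif + surv_both * (1.0 - h_d) * h_e
                surv_both = surv_both * (1.0 - h_d) * (1.0 - h_e)
                curve[k] = cif.mean()
            else:
                surv_net *= 1.0 - h_e
                curve[k] = 1.0 - surv_net.mean()

    return RiskCurve(strategy.label, curve, mc_size)


# ---------------------------------------------------------------------------
# nonparametric observed risk and calibration
# ---------------------------------------------------------------------------

def observed_risk_nonparametric(table: pd.DataFrame, outcome: str = "death",
                                n_intervals: Optional[int] = None) -> RiskCurve:
    """Discrete-time product-limit cumulative risk from the observed data.

    Censoring decrements the risk set at the end of the interval. For death,
    ESKD leaves the risk set as censoring; for ESKD, death is a competing
    event and the curve is the Aalen-Johansen cumulative incidence.
    """
    if len(table) == 0:
        raise ValueError("empty person-interval table")
    K = n_intervals or int(table["k"].max()) + 1
    at_risk = table.groupby("k").size().reindex(range(K), fill_value=0).to_numpy(float)
    if np.any(at_risk == 0):
        k_bad = int(np.argmax(at_risk == 0))
        raise ValueError(f"empty risk set at interval {k_bad}")
    deaths = (table.groupby("k")["event_death"].sum()
              .reindex(range(K), fill_value=0).to_numpy(float))
    eskds = (table.groupby("k")["event_eskd"].sum()
             .reindex(range(K), fill_value=0).to_numpy(float))
    if outcome == "death":
        h = deaths / at_risk
        risk = 1.0 - np.cumprod(1.0 - h)
    elif outcome == "eskd":
        h_d, h_e = deaths / at_risk, eskds / at_risk
        surv = np.cumprod(1.0 - h_d - h_e)
        surv_prev = np.concatenate([[1.0], surv[:-1]])
        risk = np.cumsum(surv_prev * h_e)
    else:
        raise ValueError("outcome must be 'death' or 'eskd'")
    return RiskCurve(f"observed_{outcome}", risk, int(at_risk[0]))


def natural_course_validation(natural: RiskCurve, observed: RiskCurve,
                              tolerance: float = 0.02) -> dict:
    """Compare the simulated natural course against the observed risk curve."""
    if natural.n_intervals != observed.n_intervals:
        raise ValueError("risk curves have different lengths")
    diff = natural.risk_k - observed.risk_k
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(observed.risk_k > 0, diff / observed.risk_k, np.nan)
    report = {
        "abs_diff": diff,
        "rel_diff": rel,
        "max_abs_diff": float(np.max(np.abs(diff))),
        "tolerance": tolerance,
        "calibrated": bool(np.max(np.abs(diff)) <= tolerance),
    }
    return report


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ParametricGFormula(BaseEstimator):
    """Parametric g-formula estimator for threshold-based initiation strategies.

    Parameters
    ----------
    outcome : "death" or "eskd".
    mc_size : number of pseudo-subjects for Monte Carlo standardization.
    competing_death : for the ESKD analysis, accumulate a cumulative incidence
        with death as a competing event (default) or censor at death.
    covariates : baseline covariate names entering every component model.
    seed : default seed for the simulation streams.

    After :meth:`fit`: ``models_`` (the fitted component set), ``baseline_``
    (cohort baseline rows), ``n_intervals_``.
    """

    def __init__(self, outcome: str = "death", mc_size: int = 20000,
                 competing_death: bool = True, covariates=None,
                 sua_floor: float = 0.5, seed: int = 0):
        self.outcome = outcome
        self.mc_size = mc_size
        self.competing_death = competing_death
        self.covariates = covariates
        self.sua_floor = sua_floor
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.models_ = fit_model_set(X, outcome=self.outcome,
                                     covariates=self.covariates)
        self.baseline_ = baseline_frame(X)
        self.n_intervals_ = self.models_.n_intervals
        return self

    def predict_risk_curve(self, strategy, seed: Optional[int] = None,
                           mc_size: Optional[int] = None) -> RiskCurve:
        if isinstance(strategy, str):
            strategy = StrategySpec.from_label(strategy)
        return simulate_strategy(
            self.models_, self.baseline_, strategy,
            mc_size or self.mc_size, self.seed if seed is None else seed,
            sua_floor=self.sua_floor, competing_death=self.competing_death)

    def risk_curves(self, strategies=None, seed: Optional[int] = None) -> dict:
        strategies = strategies or all_strategies()
        return {s.label: self.predict_risk_curve(s, seed=seed) for s in strategies}

    def estimate_contrasts(self, horizons_years: Sequence[float] = (5, 10, 15, 22),
                           strategies=None, seed: Optional[int] = None,
                           curves: Optional[dict] = None) -> list:
        """Standardized risks with RR/RD versus the natural course."""
        strategies = strategies or all_strategies()
        curves = curves or self.risk_curves(strategies, seed=seed)
        if "natural" not in curves:
            raise ValueError("contrasts require the natural-course reference")
        ref = curves["natural"]
        out = []
        for s in strategies:
            c = curves[s.label]
            for hy in horizons_years:
                hk = int(round(2 * hy))
                hk = min(hk, c.n_intervals)
                r, r0 = c.risk_at(hk), ref.risk_at(hk)
                out.append(ContrastEstimate(
                    strategy=s.label, horizon_years=hy, risk=100.0 * r,
                    rr=1.0 if s.label == "natural" else r / r0,
                    rd=0.0 if s.label == "natural" else 100.0 * (r - r0)))
        return out


def run_all_strategies(table: pd.DataFrame, outcome: str = "death",
                       mc_size: int = 20000, seed: int = 0,
                       horizons_years: Sequence[float] = (5, 10, 15, 22),
                       competing_death: bool = True) -> list:
    """Fit and simulate all six strategies; contrasts vs the natural course."""
    gf = ParametricGFormula(outcome=outcome, mc_size=mc_size, seed=seed,
                            competing_death=competing_death).fit(table)
    return gf.estimate_contrasts(horizons_years=horizons_years)


def subgroup_analysis(table: pd.DataFrame, stratifier: str,
                      outcome: str = "death", mc_size: int = 5000,
                      seed: int = 0,
                      horizons_years: Sequence[float] = (22,)) -> dict:
    """Full refit and resimulation within each stratum of a baseline splitter.

    ``stratifier``: 'egfr60' (baseline eGFR < 60), 'age30' (age < 30) or
    'bmi25' (BMI < 25, after imputation). Empty strata are skipped with a
    warning; stratum sizes are logged.
    """
    splits = {
        "egfr60": ("egfr0", 60.0),
        "age30": ("age", 30.0),
        "bmi25": ("bmi", 25.0),
    }
    if stratifier not in splits:
        raise ValueError(f"unknown stratifier: {stratifier!r}")
    col, cut = splits[stratifier]
    base = table[table["k"] == 0]
    below_ids = set(base.loc[base[col] < cut, "patient_id"])
    results = {}
    for name, mask in ((f"{col}<{cut:g}", table["patient_id"].isin(below_ids)),
                       (f"{col}>={cut:g}", ~table["patient_id"].isin(below_ids))):
        sub = table[mask]
        n_pat = sub["patient_id"].nunique()
        logger.info("subgroup %s: %d patients", name, n_pat)
        if n_pat == 0:
            warnings.warn(f"stratum {name!r} is empty; skipped")
            continue
        results[name] = run_all_strategies(sub, outcome=outcome,
                                           mc_size=mc_size, seed=seed,
                                           horizons_years=horizons_years)
    return results
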