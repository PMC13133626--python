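"""Estimated glomerular filtration rate from the 2009 CKD-EPI creatinine equation.

eGFR = 141 * min(sCr/kappa, 1)^alpha * max(sCr/kappa, 1)^-1.209
       * 0.993^age * 1.018[female]

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411. The race
coefficient is fixed at 1 (East-Asian cohort; documented constant).
"""

from __future__ import annotations

import numpy as np

_KAPPA = {0: 0.7, 1: 0.9}       # 0 = female, 1 = male
_ALPHA = {0: -0.329, 1: -0.411}
_SEX_FACTOR = {0: 1.018, 1: 1.0}


def compute_egfr(scr, age, male):
    """2009 CKD-EPI creatinine eGFR in ml/min/1.73 m^2.

    Parameters
    ----------
    scr : serum creatinine, mg/dl (scalar or array, > 0)
    age : age in years (> 0)
    male : 1/True for male, 0/False for female

    Vectorized; raises ``ValueError`` on nonpositive creatinine or age.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    male = np.asarray(male).astype(int)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")

    kappa = np.where(male == 1, _KAPPA[1], _KAPPA[0])
    alpha = np.where(male == 1, _ALPHA[1], _ALPHA[0])
    sexf = np.where(male == 1, _SEX_FACTOR[1], _SEX_FACTOR[0])
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * sexf
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr
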