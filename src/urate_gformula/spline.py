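"""Restricted (natural) cubic spline basis for the interval-index time trend."""

from __future__ import annotations

import numpy as np


def rcs_knots(k_max: int) -> np.ndarray:
    """Default knot placement for a follow-up of ``k_max + 1`` intervals:
    boundary knots near the ends plus three interior knots."""
    qs = np.array([0.05, 0.275, 0.50, 0.725, 0.95])
    knots = np.unique(np.round(qs * k_max))
    if len(knots) < 3:  # very short follow-up: fall back to a linear term only
        knots = np.array([0.0, max(1.0, k_max / 2.0), float(max(2, k_max))])
    return knots.astype(float)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Harrell-style restricted cubic spline basis (linear beyond the boundary
    knots). With m knots the basis has m - 1 columns, the first being ``x``."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    m = len(t)
    if m < 3:
        return x.reshape(-1, 1)
    span = t[-1] - t[0]
    out = np.empty((x.shape[0], m - 1))
    out[:, 0] = x

    def dplus(u, knot):
        return np.clip(u - knot, 0.0, None) ** 3

    for j in range(m - 2):
        term = (
            dplus(x, t[j])
            - dplus(x, t[m - 2]) * (t[m - 1] - t[j]) / (t[m - 1] - t[m - 2])
            + dplus(x, t[m - 1]) * (t[m - 2] - t[j]) / (t[m - 1] - t[m - 2])
        )
        out[:, j + 1] = term / span**2
    return out
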