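"""Allometric scaling of mass-specific metabolic rate.

Across species the mass-specific rate q is believed to follow a power law
in body mass, q ∝ M^(−β) (equivalently B ∝ M^α with α = 1 − β; Kleiber's
law predicts β = 1/4).  The exponent is estimated by ordinary least squares
of log10 q on log10 M; β is minus the fitted slope.  No phylogenetic
correction is applied — the comparison is a plain cross-species regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class AllometryFit:
    beta: float  # q ∝ M^(−beta)
    standard_error: float
    intercept: float  # log10 q at log10 M = 0
    n: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "standard_error": self.standard_error,
            "intercept": self.intercept,
            "n": self.n,
        }


def fit_power_law(mass: Sequence[float], q: Sequence[float]) -> AllometryFit:
    """OLS fit of log10 q on log10 M; returns β = −slope with its SE."""
    mass = np.asarray(mass, dtype=float)
    q = np.asarray(q, dtype=float)
    if mass.shape != q.shape or mass.ndim != 1:
        raise ValueError("mass and q must be 1-D vectors of equal length")
    if mass.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(mass <= 0) or np.any(q <= 0):
        raise ValueError("mass and q must be strictly positive")
    log_m = np.log10(mass)
    if np.ptp(log_m) == 0.0:
        raise ValueError("mass has zero variance; slope undefined")
    fit = sps.linregress(log_m, np.log10(q))
    return AllometryFit(
        beta=-float(fit.slope),
        standard_error=float(fit.stderr),
        intercept=float(fit.intercept),
        n=mass.size,
    )
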