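"""Temperature correction of mass-specific metabolic rate.

Rates measured at different body/ambient temperatures T [°C] are rescaled
to a common reference X [°C] before cross-species comparison.  Two standard
corrections are provided:

* a Q10-style rescaling assuming a doubling of rate per 10 °C,
  ``q_X = q × 10⁻³ × 2^((X − T)/10)``.  The 10⁻³ prefactor is kept exactly
  as conventionally printed; it is a common positive factor, so it cannot
  affect any rank-based statistic downstream.
* a Boltzmann–Arrhenius rescaling,
  ``q_X = q × exp[−E/k (1/(X + 273.15) − 1/(T + 273.15))]``,
  with activation energy E [eV] (default 0.65, the literature average for
  enzyme-catalysed reactions, plausible range 0.4–0.8) and Boltzmann's
  constant k = 8.6173 × 10⁻⁵ eV/K.

Ectothermic vertebrates do not hold a body temperature near the reference
points used here, so they are excluded from temperature-corrected analyses,
as are organisms lacking a measured temperature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .traits import OrganismTrait

logger = logging.getLogger("oxilink.temperature")

BOLTZMANN_EV_PER_K = 8.6173e-5
_ABSOLUTE_ZERO_C = -273.15
ACTIVATION_ENERGY_RANGE = (0.4, 0.8)


@dataclass
class CorrectionParams:
    """Parameters of the Boltzmann–Arrhenius correction."""

    target_temperature: float = 25.0  # X, °C
    activation_energy: float = 0.65  # E, eV
    allow_energy_outside_range: bool = False

    def __post_init__(self) -> None:
        lo, hi = ACTIVATION_ENERGY_RANGE
        if not (lo <= self.activation_energy <= hi) and not self.allow_energy_outside_range:
            raise ValueError(
                f"activation energy {self.activation_energy} eV outside the plausible "
                f"range [{lo}, {hi}]; set allow_energy_outside_range=True to override"
            )


def q10_style_correct(
    q: float | None, temperature: float, target_temperature: float = 25.0
) -> float | None:
    """Q10-style correction ``q × 10⁻³ × 2^((X − T)/10)``.

    ``None`` propagates (the organism is simply dropped from the
    temperature-corrected analyses).
    """
    if q is None:
        return None
    if not q > 0:
        raise ValueError("mass-specific rate must be positive")
    if not math.isfinite(temperature):
        raise ValueError("temperature must be finite")
    return q * 1e-3 * 2.0 ** ((target_temperature - temperature) / 10.0)


def boltzmann_correct(
    q: float | None, temperature: float, params: CorrectionParams
) -> float | None:
    """Boltzmann–Arrhenius correction to ``params.target_temperature``."""
    if q is None:
        return None
    if not q > 0:
        raise ValueError("mass-specific rate must be positive")
    x, t = params.target_temperature, temperature
    if x <= _ABSOLUTE_ZERO_C or t <= _ABSOLUTE_ZERO_C:
        raise ValueError("temperatures must exceed absolute zero")
    exponent = -params.activation_energy / BOLTZMANN_EV_PER_K * (
        1.0 / (x - _ABSOLUTE_ZERO_C) - 1.0 / (t - _ABSOLUTE_ZERO_C)
    )
    return q * math.exp(exponent)


def filter_temperature_eligible(records: Sequence[OrganismTrait]) -> list[OrganismTrait]:
    """Drop ectothermic vertebrates and records without a temperature."""
    kept = []
    n_ecto = n_no_temp = 0
    for rec in records:
        if rec.taxon_group == "ectothermic_vertebrate":
            n_ecto += 1
            continue
        if rec.temperature is None:
            n_no_temp += 1
            logger.info("%s: no measurement temperature; dropped", rec.species)
            continue
        kept.append(rec)
    if n_ecto or n_no_temp:
        logger.info(
            "temperature filter: dropped %d ectothermic vertebrates and %d records "
            "lacking temperature; %d of %d retained",
            n_ecto,
            n_no_temp,
            len(kept),
            len(records),
        )
    return kept
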