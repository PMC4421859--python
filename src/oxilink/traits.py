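"""Ecological and physiological trait table handling.

One :class:`OrganismTrait` row holds a species' body mass M [g], metabolic
rate B [W], mass-specific metabolic rate q = B/M [W/g], measurement
temperature [°C], maximal lifespan [years], mode-of-life flags, and the
associated genome record.  To reduce redundancy and phylogenetic signal the
analysis works on genus means: species are averaged within a genus after
unit conversion, and one genome — the earliest completely sequenced — is
chosen to represent the genus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oxilink.traits")

TAXON_GROUPS = (
    "mammal",
    "bird",
    "ectothermic_vertebrate",
    "insect",
    "protozoan",
    "prokaryote",
)

#: documented trait-table header (missing values are empty fields)
TRAIT_COLUMNS = [
    "species",
    "genus",
    "taxon_group",
    "mass_g",
    "rate_W",
    "q_W_per_g",
    "temp_C",
    "lifespan_y",
    "volant",
    "fossorial",
    "foraging_env",
    "daily_activity",
    "genome_code",
    "genome_bp",
    "genome_year",
]


class UnitError(ValueError):
    """Raised for an unrecognised measurement unit."""


@dataclass
class OrganismTrait:
    species: str
    genus: str
    taxon_group: str
    body_mass: float  # g
    metabolic_rate: float | None = None  # W
    mass_specific_rate: float | None = None  # W/g
    temperature: float | None = None  # °C
    max_lifespan: float | None = None  # years
    volant: bool | None = None
    fossorial: bool | None = None
    foraging_env: str | None = None
    daily_activity: str | None = None
    genome_code: str | None = None
    genome_size: float | None = None  # bp
    genome_year: int | None = None

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"{self.species}: unknown taxon_group {self.taxon_group!r}; "
                f"expected one of {TAXON_GROUPS}"
            )
        if not self.body_mass > 0:
            raise ValueError(f"{self.species}: body_mass must be positive")
        for name in ("mass_specific_rate", "metabolic_rate", "max_lifespan"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.species}: {name} must be positive when present")


# ---------------------------------------------------------------------------
# unit conversion

_MASS_TO_G = {"g": 1.0, "kg": 1e3, "mg": 1e-3, "µg": 1e-6, "ug": 1e-6, "pg": 1e-12}
_RATE_TO_W = {"W": 1.0, "mW": 1e-3, "µW": 1e-6, "uW": 1e-6}
_CELSIUS_ZERO_K = 273.15


def convert_mass(value: float, unit: str) -> float:
    try:
        return value * _MASS_TO_G[unit]
    except KeyError:
        raise UnitError(f"unknown mass unit {unit!r}") from None


def convert_rate(value: float, unit: str) -> float:
    try:
        return value * _RATE_TO_W[unit]
    except KeyError:
        raise UnitError(f"unknown rate unit {unit!r}") from None


def convert_temperature(value: float, unit: str) -> float:
    if unit in ("C", "°C", "celsius"):
        return value
    if unit in ("K", "kelvin"):
        return value - _CELSIUS_ZERO_K
    raise UnitError(f"unknown temperature unit {unit!r}")


def convert_units(raw: Mapping[str, object]) -> OrganismTrait:
    """Build an :class:`OrganismTrait` from a raw record with unit strings.

    Recognised keys: ``species, genus, taxon_group``; measured fields with
    ``<field>_unit`` companions (``body_mass``, ``metabolic_rate``,
    ``temperature``); ``mass_specific_rate`` [W/g] and ``max_lifespan``
    [years] are taken as already in target units; the mode-of-life and
    genome fields pass through unchanged.
    """
    label = str(raw.get("species", "<record>"))

    def measured(key: str, converter) -> float | None:
        value = raw.get(key)
        if value is None:
            return None
        unit = raw.get(f"{key}_unit")
        if unit is None:
            raise UnitError(f"{label}: {key} given without a {key}_unit")
        try:
            return converter(float(value), str(unit))
        except UnitError as exc:
            raise UnitError(f"{label}: {exc}") from None

    passthrough = {
        k: raw.get(k)
        for k in (
            "mass_specific_rate",
            "max_lifespan",
            "volant",
            "fossorial",
            "foraging_env",
            "daily_activity",
            "genome_code",
            "genome_size",
            "genome_year",
        )
        if raw.get(k) is not None
    }
    return OrganismTrait(
        species=str(raw["species"]),
        genus=str(raw["genus"]),
        taxon_group=str(raw["taxon_group"]),
        body_mass=measured("body_mass", convert_mass),
        metabolic_rate=measured("metabolic_rate", convert_rate),
        temperature=measured("temperature", convert_temperature),
        **passthrough,
    )


def derive_mass_specific(metabolic_rate: float, body_mass: float) -> float:
    """q = B / M, watts per gram."""
    if not body_mass > 0:
        raise ValueError("body_mass must be positive")
    if not metabolic_rate > 0:
        raise ValueError("metabolic_rate must be positive")
    return metabolic_rate / body_mass


def ensure_mass_specific(record: OrganismTrait, rel_tol: float = 1e-6) -> OrganismTrait:
    """Fill q from B and M when absent; warn if a stored q disagrees."""
    if record.metabolic_rate is None:
        return record
    derived = derive_mass_specific(record.metabolic_rate, record.body_mass)
    if record.mass_specific_rate is None:
        return replace(record, mass_specific_rate=derived)
    if not math.isclose(record.mass_specific_rate, derived, rel_tol=rel_tol):
        logger.warning(
            "%s: stored q=%.6g conflicts with B/M=%.6g",
            record.species,
            record.mass_specific_rate,
            derived,
        )
    return record


# ---------------------------------------------------------------------------
# genus averaging and representative-genome selection

_MEAN_FIELDS = (
    "body_mass",
    "metabolic_rate",
    "mass_specific_rate",
    "temperature",
    "max_lifespan",
    "genome_size",
)
# temperature can be ≤ 0 °C, so it always averages arithmetically
_GEOMETRIC_OK = ("body_mass", "metabolic_rate", "mass_specific_rate", "max_lifespan", "genome_size")


def _mean_present(values: Sequence[float | None], geometric: bool) -> float | None:
    present = [v for v in values if v is not None]
    if not present:
        return None
    if geometric:
        return float(np.exp(np.mean(np.log(present))))
    return float(np.mean(present))


def _uniform_or_none(values: Sequence[object], genus: str, name: str):
    present = {v for v in values if v is not None}
    if len(present) == 1:
        return next(iter(present))
    if len(present) > 1:
        logger.warning("genus %s: conflicting %s values %s; set to missing", genus, name, present)
    return None


def select_representative(candidates: Sequence[tuple[str, int | None]]) -> str:
    """Pick a genus' representative genome: the earliest-completed one.

    Ties on year break lexicographically by genome code (logged).
    """
    dated = [(code, year) for code, year in candidates if year is not None]
    if not dated:
        raise ValueError("no candidate genome carries a completion year")
    earliest = min(year for _, year in dated)
    tied = sorted(code for code, year in dated if year == earliest)
    if len(tied) > 1:
        logger.info("representative tie at year %d among %s; chose %r", earliest, tied, tied[0])
    return tied[0]


def genus_average(records: Sequence[OrganismTrait], geometric: bool = False) -> list[OrganismTrait]:
    """Collapse species rows to one row per genus.

    Numeric fields are averaged over the members that possess them (a field
    is missing at genus level only when missing in every member); means are
    arithmetic by default, geometric optionally for the strictly positive
    quantities.  The taxon group must be uniform within a genus.  The genus
    genome is the representative (earliest-year) member's.
    """
    by_genus: dict[str, list[OrganismTrait]] = {}
    for rec in records:
        by_genus.setdefault(rec.genus, []).append(rec)

    out: list[OrganismTrait] = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        taxa = {m.taxon_group for m in members}
        if len(taxa) > 1:
            raise ValueError(f"genus {genus}: conflicting taxon groups {sorted(taxa)}")
        averaged = {
            name: _mean_present(
                [getattr(m, name) for m in members],
                geometric and name in _GEOMETRIC_OK,
            )
            for name in _MEAN_FIELDS
        }
        # q: average the members' own q when any has one, else derive from
        # the averaged B and M (the two paths differ; the one taken is logged)
        if averaged["mass_specific_rate"] is None and averaged["metabolic_rate"] is not None:
            averaged["mass_specific_rate"] = derive_mass_specific(
                averaged["metabolic_rate"], averaged["body_mass"]
            )
            logger.info("genus %s: q derived from averaged B and M", genus)

        candidates = [
            (m.genome_code, m.genome_year) for m in members if m.genome_code is not None
        ]
        genome_code = genome_year = genome_size = None
        if candidates:
            try:
                genome_code = select_representative(candidates)
                rep = next(m for m in members if m.genome_code == genome_code)
                genome_year = rep.genome_year
                genome_size = rep.genome_size
            except ValueError:
                if len(candidates) == 1:
                    rep = next(m for m in members if m.genome_code is not None)
                    genome_code, genome_year, genome_size = (
                        rep.genome_code,
                        rep.genome_year,
                        rep.genome_size,
                    )
        if genome_size is not None:
            averaged["genome_size"] = genome_size

        out.append(
            OrganismTrait(
                species=members[0].species if len(members) == 1 else f"{genus} spp.",
                genus=genus,
                taxon_group=members[0].taxon_group,
                volant=_uniform_or_none([m.volant for m in members], genus, "volant"),
                fossorial=_uniform_or_none([m.fossorial for m in members], genus, "fossorial"),
                foraging_env=_uniform_or_none(
                    [m.foraging_env for m in members], genus, "foraging_env"
                ),
                daily_activity=_uniform_or_none(
                    [m.daily_activity for m in members], genus, "daily_activity"
                ),
                genome_code=genome_code,
                genome_year=genome_year,
                **averaged,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_FIELD_BY_COLUMN = {
    "species": "species",
    "genus": "genus",
    "taxon_group": "taxon_group",
    "mass_g": "body_mass",
    "rate_W": "metabolic_rate",
    "q_W_per_g": "mass_specific_rate",
    "temp_C": "temperature",
    "lifespan_y": "max_lifespan",
    "volant": "volant",
    "fossorial": "fossorial",
    "foraging_env": "foraging_env",
    "daily_activity": "daily_activity",
    "genome_code": "genome_code",
    "genome_bp": "genome_size",
    "genome_year": "genome_year",
}
_BOOL_COLUMNS = ("volant", "fossorial")


def traits_to_frame(records: Iterable[OrganismTrait]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {col: getattr(rec, attr) for col, attr in _FIELD_BY_COLUMN.items()}
        rows.append(row)
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)


def write_trait_table(records: Sequence[OrganismTrait], path: str | Path) -> None:
    frame = traits_to_frame(records).copy()
    for col in _BOOL_COLUMNS:
        frame[col] = frame[col].map({True: 1, False: 0})
    sep = "," if str(path).endswith(".csv") else "\t"
    frame.to_csv(path, sep=sep, index=False)


def read_trait_table(path: str | Path) -> list[OrganismTrait]:
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trait table {path} lacks columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col, attr in _FIELD_BY_COLUMN.items():
            value = row[col]
            if pd.isna(value):
                kwargs[attr] = None
            elif col in _BOOL_COLUMNS:
                kwargs[attr] = bool(int(value))
            elif col == "genome_year":
                kwargs[attr] = int(value)
            else:
                kwargs[attr] = value
        records.append(OrganismTrait(**kwargs))
    return records
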