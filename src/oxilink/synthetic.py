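"""Synthetic organism panels with planted, known correlation structure.

The study design correlates functional gene content with mass-specific
metabolic rate q and maximal lifespan across a panel spanning prokaryotes
to mammals.  Since the underlying trait compilation and the licensed genome
annotations cannot be redistributed, this module generates panels with the
same statistical structure, plus on-disk KGML / ``.keg`` / FASTA / TSV
fixtures, so every pipeline stage runs without any download and every
planted effect is known exactly for recovery tests.

Planted structure (all on base-10 log scales unless noted):

* body mass M drawn per-genus log-uniform over a span covering ~19 orders
  of magnitude, with taxon labels assigned by mass-order strata;
* genome size increasing in log10 M with lognormal scatter (rank
  correlation ≈ 0.8);
* the oxic gene proportion increasing linearly in log10 M with Gaussian
  scatter;
* q = c·M^(−β)·exp-style oxic effect·lognormal noise, with β small
  (default 0.035);
* maximal lifespan, mammals and birds only, increasing in mass and
  *decreasing* in the oxic proportion;
* decoy functional categories whose proportions are pure noise,
  independent of every trait.

Gene-level annotations realise every category proportion exactly: the
target proportion is rounded to an integer gene count and the *realised*
proportion (count / total genes) is the one fed into the trait model, so a
round trip through the file writers and parsers reproduces the generator's
internal values bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .kegg_io import CategoryGeneMap, GeneLengthMap, GeneReactionMap, OxicReactionSet
from .profiles import OXIC_CATEGORY
from .traits import OrganismTrait, write_trait_table

logger = logging.getLogger("oxilink.synthetic")

#: synthetic oxic reaction list: 20 R numbers, each with a synthetic EC number
OXIC_R_NUMBERS = tuple(f"R{10 + 25 * i:05d}" for i in range(20))
OXIC_EC_NUMBERS = tuple(f"1.14.13.{i + 1}" for i in range(20))
#: reactions outside the oxic list, for non-oxic genes
_ANOXIC_R_NUMBERS = tuple(f"R{60000 + 25 * i:05d}" for i in range(20))

UNCLASSIFIED_CATEGORY = "Unclassified"

#: taxa in ascending body-mass order; genus masses are drawn log-uniform
#: over the panel span and taxa assigned by mass-order strata, so that
#: rank(mass) stays an affine function of log10 mass (no rank nonlinearity)
TAXON_STRATUM_ORDER = (
    "prokaryote",
    "protozoan",
    "insect",
    "ectothermic_vertebrate",
    "bird",
    "mammal",
)

#: taxa that carry a measurement temperature in the emulated compilation
_TAXA_WITH_TEMPERATURE = ("mammal", "ectothermic_vertebrate", "protozoan", "prokaryote")

_DEFAULT_TAXON_MIX = {
    "prokaryote": 59,
    "protozoan": 9,
    "insect": 5,
    "ectothermic_vertebrate": 4,
    "bird": 6,
    "mammal": 12,
}


def _normalised_mix(mix: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(mix.values()))
    if total <= 0:
        raise ValueError("taxon mix must have positive total weight")
    return {k: v / total for k, v in mix.items()}


@dataclass
class SyntheticPanelConfig:
    """All planted effect sizes, ranges and noise levels of a panel.

    Fully deterministic given ``seed``.  Defaults emulate the ~100-organism
    prokaryote-to-mammal study panel; :meth:`lifespan_study` gives the
    30-organism mammal/bird lifespan panel (23 mammals, 7 birds).
    """

    n_genera: int = 101
    species_per_genus: int = 1
    mass_log10_range: tuple[float, float] = (-13.0, 6.0)
    beta_true: float = 0.035
    rate_intercept_log10: float = -2.0  # log10 q [W/g] at M = 1 g, mean oxic content
    oxic_effect_on_rate: float = 2.9  # Δ log10 q per unit oxic proportion
    oxic_effect_on_lifespan: float = -2.5  # Δ log10 lifespan per unit oxic proportion
    mass_lifespan_exponent: float = 0.2
    lifespan_intercept_log10: float = 0.5  # log10 years at M = 1 g
    genome_size_mass_link: float = 0.163  # log10 bp per log10 g
    genome_intercept_log10: float = 6.4  # log10 bp at the low mass bound
    oxic_base: float = 0.12  # oxic proportion at mid mass range
    oxic_mass_slope: float = 0.002  # per log10 g
    sigma_rate: float = 0.3  # sd of log10 q noise
    sigma_lifespan: float = 0.15  # sd of log10 lifespan noise
    sigma_genome: float = 0.6  # sd of log10 genome-size noise
    sigma_oxic: float = 0.06  # sd of oxic-proportion noise (additive)
    temperature_range: tuple[float, float] = (2.0, 40.0)
    n_categories: int = 30  # decoy categories
    category_overlap_rate: float = 0.1  # fraction of category genes drawn from a shared pool
    taxon_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TAXON_MIX))
    genes_range: tuple[int, int] = (500, 20000)
    gene_length_log_mean: float = 6.8  # ln nt (median ≈ 900 nt)
    gene_length_log_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 0 or self.species_per_genus < 1:
            raise ValueError("n_genera must be ≥ 0 and species_per_genus ≥ 1")
        for name in ("mass_log10_range", "temperature_range", "genes_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")
        for name in ("sigma_rate", "sigma_lifespan", "sigma_genome", "sigma_oxic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not 0.0 <= self.category_overlap_rate <= 1.0:
            raise ValueError("category_overlap_rate must lie in [0, 1]")
        if self.oxic_effect_on_lifespan > 0:
            raise ValueError("oxic_effect_on_lifespan must be ≤ 0 (a longevity cost)")
        unknown = set(self.taxon_mix) - set(TAXON_STRATUM_ORDER)
        if unknown:
            raise ValueError(f"unknown taxa in taxon_mix: {sorted(unknown)}")

    @classmethod
    def lifespan_study(cls, seed: int = 0, **overrides) -> "SyntheticPanelConfig":
        """30-genus mammal/bird panel mirroring the lifespan sub-study."""
        kwargs = dict(
            n_genera=30,
            taxon_mix={"mammal": 23, "bird": 7},
            mass_log10_range=(0.5, 6.0),
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticPanelConfig":
        """Panel with no planted oxic effects (type-I calibration)."""
        kwargs = dict(oxic_effect_on_rate=0.0, oxic_effect_on_lifespan=0.0, seed=seed)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticPanelConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("mass_log10_range", "temperature_range", "genes_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


@dataclass
class OrganismAnnotation:
    gene_reactions: GeneReactionMap
    categories: CategoryGeneMap
    gene_lengths: GeneLengthMap


@dataclass
class PlantedTruth:
    """Record of every planted coefficient, for recovery tests."""

    coefficients: dict[str, float]
    oxic_category: str
    decoy_categories: list[str]
    per_organism: pd.DataFrame  # one row per organism: masses, realised proportions, ...
    category_proportions: pd.DataFrame  # organisms × (oxic + decoy) realised proportions


@dataclass
class SyntheticPanel:
    config: SyntheticPanelConfig
    traits: list[OrganismTrait]
    oxic_reactions: OxicReactionSet
    truth: PlantedTruth
    annotations: dict[str, OrganismAnnotation] | None = None

    def profile_matrix(self) -> pd.DataFrame:
        """Realised organisms × categories proportion matrix (in-memory path)."""
        return self.truth.category_proportions.copy()


def default_oxic_reaction_set() -> OxicReactionSet:
    return OxicReactionSet(r_numbers=set(OXIC_R_NUMBERS), ec_numbers=set(OXIC_EC_NUMBERS))


def _assign_taxa(log_masses: np.ndarray, mix: Mapping[str, float]) -> list[str]:
    """Assign taxa to genera by body-mass order.

    Target counts follow the mix fractions (largest-remainder rounding);
    the lightest stratum gets the lightest taxon in
    :data:`TAXON_STRATUM_ORDER`, and so on, keeping labels mass-consistent
    while the mass draw itself stays log-uniform.
    """
    n = log_masses.size
    fractions = _normalised_mix(mix)
    taxa = [t for t in TAXON_STRATUM_ORDER if t in fractions]
    raw = np.array([fractions[t] * n for t in taxa])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    for i in np.argsort(raw - np.floor(raw))[::-1][:remainder]:
        counts[i] += 1
    labels = [""] * n
    order = np.argsort(log_masses, kind="mergesort")
    pos = 0
    for taxon, count in zip(taxa, counts):
        for j in order[pos : pos + count]:
            labels[j] = taxon
        pos += count
    return labels


def generate_panel(
    config: SyntheticPanelConfig, with_annotations: bool = True
) -> SyntheticPanel:
    """Generate a full panel: traits, planted truth, and (optionally) the
    per-organism gene-level annotation maps.

    Trait values depend only on ``config`` (one random stream), never on
    whether annotations are materialised: category gene *counts* are exact
    integer roundings of the targets, and gene-set construction uses
    per-organism child streams.
    """
    rng = np.random.default_rng(config.seed)
    mass_lo, mass_hi = config.mass_log10_range
    mass_mid = 0.5 * (mass_lo + mass_hi)

    traits: list[OrganismTrait] = []
    annotations: dict[str, OrganismAnnotation] | None = {} if with_annotations else None
    rows = []
    cat_names = [f"Category {i + 1:02d}" for i in range(config.n_categories)]
    decoy_base = rng.uniform(0.01, 0.06, size=config.n_categories)
    cat_rows = {}

    genus_log_masses = rng.uniform(mass_lo, mass_hi, size=config.n_genera)
    genus_taxa = _assign_taxa(genus_log_masses, config.taxon_mix)

    idx = 0
    for g in range(config.n_genera):
        genus = f"Genus{g + 1:03d}"
        taxon = genus_taxa[g]
        genus_log_mass = float(genus_log_masses[g])
        for s in range(config.species_per_genus):
            idx += 1
            code = f"org{idx:03d}"
            log_mass = float(np.clip(genus_log_mass + rng.normal(0.0, 0.1), mass_lo, mass_hi))

            log_genome = (
                config.genome_intercept_log10
                + config.genome_size_mass_link * (log_mass - mass_lo)
                + rng.normal(0.0, config.sigma_genome)
            )
            log_genome = float(np.clip(log_genome, 5.5, 10.5))
            genome_size = int(round(10**log_genome))

            oxic_target = (
                config.oxic_base
                + config.oxic_mass_slope * (log_mass - mass_mid)
                + rng.normal(0.0, config.sigma_oxic)
            )
            if oxic_target > 1.0:
                raise ValueError(
                    f"{code}: infeasible oxic proportion {oxic_target:.3f} > 1; "
                    "check oxic_base / oxic_mass_slope"
                )
            oxic_target = float(np.clip(oxic_target, 0.005, 0.95))

            frac = np.clip((log_genome - 6.2) / (9.7 - 6.2), 0.0, 1.0)
            n_genes = int(round(config.genes_range[0] + frac * np.ptp(config.genes_range)))
            n_genes = max(n_genes, 50)
            oxic_count = max(1, int(round(oxic_target * n_genes)))
            oxic_real = oxic_count / n_genes

            log_q = (
                config.rate_intercept_log10
                - config.beta_true * log_mass
                + config.oxic_effect_on_rate * (oxic_real - config.oxic_base)
                + rng.normal(0.0, config.sigma_rate)
            )
            q = float(10**log_q)
            mass = float(10**log_mass)

            # decoy categories: pure noise, independent of every trait
            decoy_p = decoy_base * np.exp(rng.normal(0.0, 0.3, size=config.n_categories))
            decoy_counts = np.maximum(2, np.round(decoy_p * n_genes).astype(int))
            decoy_counts = np.minimum(decoy_counts, n_genes)
            decoy_real = decoy_counts / n_genes

            lifespan = None
            if taxon in ("mammal", "bird"):
                log_life = (
                    config.lifespan_intercept_log10
                    + config.mass_lifespan_exponent * log_mass
                    + config.oxic_effect_on_lifespan * (oxic_real - config.oxic_base)
                    + rng.normal(0.0, config.sigma_lifespan)
                )
                lifespan = float(10**log_life)

            if taxon == "mammal":
                temperature = float(rng.normal(38.5, 0.8))
                volant = bool(rng.random() < 3 / 23)
                fossorial = bool(rng.random() < 0.15)
            elif taxon in _TAXA_WITH_TEMPERATURE:
                temperature = float(rng.uniform(*config.temperature_range))
                volant, fossorial = None, None
            else:  # birds and insects lack temperature data in the compilation
                temperature = None
                volant = True if taxon == "bird" else None
                fossorial = False if taxon == "bird" else None
            if taxon in ("mammal", "bird"):
                foraging_env = str(rng.choice(["terrestrial", "aquatic", "aerial"]))
                daily_activity = str(rng.choice(["diurnal", "nocturnal"]))
            else:
                foraging_env = daily_activity = None

            traits.append(
                OrganismTrait(
                    species=f"{genus} species{s + 1}",
                    genus=genus,
                    taxon_group=taxon,
                    body_mass=mass,
                    metabolic_rate=q * mass,
                    mass_specific_rate=q,
                    temperature=temperature,
                    max_lifespan=lifespan,
                    volant=volant,
                    fossorial=fossorial,
                    foraging_env=foraging_env,
                    daily_activity=daily_activity,
                    genome_code=code,
                    genome_size=float(genome_size),
                    genome_year=int(rng.integers(1996, 2014)),
                )
            )
            rows.append(
                {
                    "organism": code,
                    "species": f"{genus} species{s + 1}",
                    "taxon_group": taxon,
                    "log10_mass": log_mass,
                    "genome_size": genome_size,
                    "n_genes": n_genes,
                    "oxic_target": oxic_target,
                    "oxic_count": oxic_count,
                    "oxic_proportion": oxic_real,
                }
            )
            cat_rows[code] = dict(zip(cat_names, decoy_real)) | {OXIC_CATEGORY: oxic_real}

            if annotations is not None:
                annotations[code] = _build_annotation(
                    code,
                    n_genes,
                    oxic_count,
                    decoy_counts,
                    cat_names,
                    config,
                    np.random.default_rng([config.seed & 0x7FFFFFFF, 1000 + idx]),
                )

    per_organism = pd.DataFrame(rows).set_index("organism") if rows else pd.DataFrame()
    category_proportions = (
        pd.DataFrame.from_dict(cat_rows, orient="index").sort_index().sort_index(axis=1)
        if cat_rows
        else pd.DataFrame()
    )
    category_proportions.index.name = "organism"
    truth = PlantedTruth(
        coefficients={
            "beta_true": config.beta_true,
            "oxic_effect_on_rate": config.oxic_effect_on_rate,
            "oxic_effect_on_lifespan": config.oxic_effect_on_lifespan,
            "mass_lifespan_exponent": config.mass_lifespan_exponent,
            "genome_size_mass_link": config.genome_size_mass_link,
        },
        oxic_category=OXIC_CATEGORY,
        decoy_categories=cat_names,
        per_organism=per_organism,
        category_proportions=category_proportions,
    )
    return SyntheticPanel(
        config=config,
        traits=traits,
        oxic_reactions=default_oxic_reaction_set(),
        truth=truth,
        annotations=annotations,
    )


def _build_annotation(
    code: str,
    n_genes: int,
    oxic_count: int,
    decoy_counts: np.ndarray,
    cat_names: list[str],
    config: SyntheticPanelConfig,
    rng: np.random.Generator,
) -> OrganismAnnotation:
    genes = np.array([f"g{i + 1:05d}" for i in range(n_genes)])

    # oxic genes: each linked to 1-2 oxic reactions; a sample of the others
    # carries non-oxic reactions so the pathway files are not oxic-only
    oxic_idx = rng.choice(n_genes, size=oxic_count, replace=False)
    pairs: dict[str, set[str]] = {}
    for i in oxic_idx:
        k = int(rng.integers(1, 3))
        pairs[genes[i]] = set(rng.choice(OXIC_R_NUMBERS, size=k, replace=False))
    non_oxic = np.setdiff1d(np.arange(n_genes), oxic_idx)
    n_extra = int(round(0.3 * non_oxic.size))
    for i in rng.choice(non_oxic, size=n_extra, replace=False):
        pairs[genes[i]] = {str(rng.choice(_ANOXIC_R_NUMBERS))}
    grm = GeneReactionMap(organism_code=code, pairs=pairs)

    # decoy categories: each draws part of its genes from a shared pool so a
    # controllable fraction of genes is multiply categorised
    perm = rng.permutation(n_genes)
    pool_size = int(round(config.category_overlap_rate * n_genes))
    pool, rest = perm[:pool_size], perm[pool_size:]
    categories: dict[str, set[str]] = {}
    covered: set[str] = set()
    for name, count in zip(cat_names, decoy_counts):
        k_pool = min(int(round(count * config.category_overlap_rate)), pool_size)
        k_rest = min(int(count) - k_pool, rest.size)
        chosen = np.concatenate(
            [
                rng.choice(pool, size=k_pool, replace=False) if k_pool else np.empty(0, int),
                rng.choice(rest, size=k_rest, replace=False) if k_rest else np.empty(0, int),
            ]
        )
        # top up from the pool if the rest ran short (tiny genomes only)
        if chosen.size < count:
            extra = np.setdiff1d(pool, chosen)
            chosen = np.concatenate([chosen, extra[: int(count) - chosen.size]])
        categories[name] = set(genes[chosen.astype(int)])
        covered |= categories[name]
    unclassified = set(genes) - covered
    if unclassified:
        categories[UNCLASSIFIED_CATEGORY] = unclassified
    cgm = CategoryGeneMap(organism_code=code, categories=categories, total_genes=n_genes)

    lengths = np.maximum(
        30,
        np.round(
            rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sigma, n_genes)
        ).astype(int),
    )
    glm = GeneLengthMap(organism_code=code, lengths=dict(zip(genes.tolist(), lengths.tolist())))
    return OrganismAnnotation(gene_reactions=grm, categories=cgm, gene_lengths=glm)


# ---------------------------------------------------------------------------
# fixture files


def _kgml_text(ann: OrganismAnnotation) -> str:
    code = ann.gene_reactions.organism_code
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:{code}00001" org="{code}" number="00001" title="Synthetic metabolic map">',
    ]
    for eid, gene in enumerate(sorted(ann.gene_reactions.pairs), start=1):
        rxns = " ".join(f"rn:{r}" for r in sorted(ann.gene_reactions.pairs[gene]))
        lines.append(
            f'  <entry id="{eid}" name="{code}:{gene}" type="gene" reaction="{rxns}"/>'
        )
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def _keg_text(ann: OrganismAnnotation) -> str:
    code = ann.categories.organism_code
    lines = [
        f"+C\t{code}",
        f"#DEFINITION  Synthetic functional hierarchy for {code}",
        "A<b>Synthetic annotation</b>",
    ]
    for name in sorted(ann.categories.categories):
        lines.append(f"B  {name}")
        for gene in sorted(ann.categories.categories[name]):
            lines.append(f"C    {gene}  synthetic protein")
    lines.append("!")
    return "\n".join(lines) + "\n"


def _fasta_text(ann: OrganismAnnotation, rng: np.random.Generator) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chunks = []
    for gene in sorted(ann.gene_lengths.lengths):
        n = ann.gene_lengths.lengths[gene]
        seq = alphabet[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
        chunks.append(f">{gene}\n")
        chunks.extend(seq[i : i + 70] + "\n" for i in range(0, n, 70))
    return "".join(chunks)


def _oxic_table_text(oxic: OxicReactionSet) -> str:
    rs = sorted(oxic.r_numbers)
    ecs = sorted(oxic.ec_numbers, key=lambda e: [int(x) if x.isdigit() else x for x in e.split(".")])
    lines = ["# synthetic oxic reaction list: R number <TAB> EC number"]
    for i in range(max(len(rs), len(ecs))):
        r = rs[i] if i < len(rs) else ""
        e = ecs[i] if i < len(ecs) else ""
        lines.append(f"{r}\t{e}")
    return "\n".join(lines) + "\n"


def write_fixture_files(
    panel: SyntheticPanel, directory: str | Path, overwrite: bool = False
) -> pd.DataFrame:
    """Write per-organism KGML/.keg/FASTA files plus the panel trait table
    and oxic list; returns (and writes) a manifest of paths with SHA-256
    checksums.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    if panel.annotations is None:
        raise ValueError("panel was generated without annotations; nothing to write")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True")
    directory.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    for i, code in enumerate(sorted(panel.annotations), start=1):
        ann = panel.annotations[code]
        seq_rng = np.random.default_rng([panel.config.seed & 0x7FFFFFFF, 2_000_000 + i])
        for name, text in (
            (f"{code}.kgml", _kgml_text(ann)),
            (f"{code}.keg", _keg_text(ann)),
            (f"{code}.fna", _fasta_text(ann, seq_rng)),
        ):
            path = directory / name
            path.write_text(text, encoding="utf-8")
            written.append(path)

    traits_path = directory / "traits.tsv"
    write_trait_table(panel.traits, traits_path)
    written.append(traits_path)
    oxic_path = directory / "oxic_reactions.tsv"
    oxic_path.write_text(_oxic_table_text(panel.oxic_reactions), encoding="utf-8")
    written.append(oxic_path)

    manifest = pd.DataFrame(
        {
            "path": [p.name for p in written],
            "sha256": [hashlib.sha256(p.read_bytes()).hexdigest() for p in written],
            "bytes": [p.stat().st_size for p in written],
        }
    )
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest
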