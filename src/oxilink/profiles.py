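"""Per-organism functional profiles.

An organism's *functional profile* records, for every functional category,
the number of its genes in the category, that count divided by the total
gene count (the proportion actually used in all downstream correlations),
and optionally the summed nucleotide length of the category's genes (the
"functional genome size").  Oxic metabolism — genes linked to at least one
reaction that occurs in the presence of oxygen — is exposed as a
pseudo-category alongside the hierarchy categories so the screen can rank
it uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kegg_io import CategoryGeneMap, GeneLengthMap, GeneReactionMap, OxicReactionSet

logger = logging.getLogger("oxilink.profiles")

#: name under which the oxic gene set appears among the categories
OXIC_CATEGORY = "Oxic metabolism"


@dataclass
class CategoryRecord:
    gene_count: int
    proportion: float
    nucleotides: int | None = None
    nucleotides_complete: bool = True


@dataclass
class FunctionalProfile:
    organism_code: str
    total_genes: int
    categories: dict[str, CategoryRecord] = field(default_factory=dict)
    oxic_gene_count: int = 0

    @property
    def oxic_proportion(self) -> float:
        return self.oxic_gene_count / self.total_genes


def call_oxic_genes(
    grm: GeneReactionMap,
    oxic: OxicReactionSet,
    gene_ec: Mapping[str, set[str]] | None = None,
    use_ec_fallback: bool = False,
) -> set[str]:
    """Genes associated with at least one oxic reaction.

    A single oxic reaction suffices for membership.  Matching is on R
    numbers from the gene→reaction map; optionally, genes with EC
    annotations (``gene_ec``) can additionally be matched against the oxic
    EC list (off by default — the operational rule is R-number based).
    """
    called = {g for g, rxns in grm.pairs.items() if rxns & oxic.r_numbers}
    if use_ec_fallback and gene_ec:
        if not oxic.ec_numbers:
            logger.warning("EC fallback requested but oxic list has no EC numbers")
        for gene, ecs in gene_ec.items():
            if set(ecs) & oxic.ec_numbers:
                called.add(gene)
    return called


def compute_profile(
    cgm: CategoryGeneMap,
    oxic_genes: set[str],
    lengths: GeneLengthMap | None = None,
    include_oxic_category: bool = True,
) -> FunctionalProfile:
    """Build a :class:`FunctionalProfile` from category and oxic gene sets.

    Every proportion shares the denominator ``cgm.total_genes``.  Oxic genes
    outside the annotation universe (e.g. present in pathway XML but missing
    from the hierarchy file) are excluded from the oxic count, with a
    warning, so the oxic set stays a subset of the universe.
    """
    if cgm.total_genes <= 0:
        raise ValueError("total_genes must be positive")
    universe = cgm.universe
    outside = oxic_genes - universe
    if outside:
        logger.warning(
            "%s: %d oxic genes absent from the category universe; excluded",
            cgm.organism_code,
            len(outside),
        )
    oxic_in = oxic_genes & universe

    profile = FunctionalProfile(
        organism_code=cgm.organism_code,
        total_genes=cgm.total_genes,
        oxic_gene_count=len(oxic_in),
    )

    def record(genes: set[str]) -> CategoryRecord:
        rec = CategoryRecord(gene_count=len(genes), proportion=len(genes) / cgm.total_genes)
        if lengths is not None:
            missing = [g for g in genes if g not in lengths.lengths]
            if missing:
                logger.warning(
                    "%s: %d genes lack length data; nucleotide total incomplete",
                    cgm.organism_code,
                    len(missing),
                )
                rec.nucleotides_complete = False
            rec.nucleotides = sum(lengths.lengths[g] for g in genes if g in lengths.lengths)
        return rec

    for name, genes in cgm.categories.items():
        profile.categories[name] = record(genes)
    if include_oxic_category:
        profile.categories[OXIC_CATEGORY] = record(oxic_in)
    return profile


# ---------------------------------------------------------------------------
# tabular output


def profiles_to_long_frame(profiles: Iterable[FunctionalProfile]) -> pd.DataFrame:
    """One row per (organism, category) with count, proportion, nucleotides."""
    rows = []
    for p in profiles:
        for name, rec in p.categories.items():
            rows.append(
                {
                    "organism": p.organism_code,
                    "category": name,
                    "gene_count": rec.gene_count,
                    "proportion": rec.proportion,
                    "total_genes": p.total_genes,
                    "nucleotides": rec.nucleotides,
                    "nucleotides_complete": rec.nucleotides_complete,
                }
            )
    return pd.DataFrame(rows)


def profiles_to_matrix(profiles: Sequence[FunctionalProfile]) -> pd.DataFrame:
    """Wide organisms × categories matrix of proportions (absent → 0.0)."""
    data = {p.organism_code: {k: r.proportion for k, r in p.categories.items()} for p in profiles}
    mat = pd.DataFrame.from_dict(data, orient="index").fillna(0.0)
    mat.index.name = "organism"
    return mat.sort_index().sort_index(axis=1)


def write_profiles_tsv(profiles: Sequence[FunctionalProfile], directory: str | Path) -> dict[str, Path]:
    """Write long-format and wide-matrix TSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    long_path = directory / "profiles_long.tsv"
    matrix_path = directory / "profiles_matrix.tsv"
    profiles_to_long_frame(profiles).to_csv(long_path, sep="\t", index=False)
    profiles_to_matrix(profiles).to_csv(matrix_path, sep="\t")
    return {"long": long_path, "matrix": matrix_path}


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="organism")
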