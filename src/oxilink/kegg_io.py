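"""Readers for KEGG-style annotation files.

Three file kinds feed the analysis: KGML pathway XML carrying gene→reaction
relations, BRITE ``.keg`` hierarchy files carrying functional category→gene
relations, and plain nucleotide FASTA for gene lengths.  A fourth reader
loads the curated list of oxic reactions (reactions that occur in the
presence of oxygen), keyed by KEGG reaction ("R") numbers and/or Enzyme
Commission (EC) numbers.

All identifiers are normalised on ingest: ``rn:`` / ``ec:`` prefixes and the
organism-code prefix are stripped, reaction identifiers must match
``R`` + five digits, and gene identifier case is preserved.
"""

from __future__ import annotations

import io
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("oxilink.kegg_io")

R_NUMBER_RE = re.compile(r"^R\d{5}$")
EC_NUMBER_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:[\w-]+)$")
_TAG_RE = re.compile(r"<[^>]+>")


class KGMLParseError(ValueError):
    """Raised when a KGML document cannot be parsed."""


class BriteFormatError(ValueError):
    """Raised when a ``.keg`` file lacks the expected hierarchy structure."""


@dataclass
class GeneReactionMap:
    """Gene → reaction-identifier sets for one organism."""

    organism_code: str
    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CategoryGeneMap:
    """Functional category → gene sets for one organism.

    ``total_genes`` is the proportion denominator: by default the number of
    distinct genes appearing anywhere in the hierarchy file, or the size of a
    genome-wide gene list when one is supplied (genes may be annotated in the
    genome yet absent from the hierarchy).
    """

    organism_code: str
    categories: dict[str, set[str]]
    total_genes: int

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.categories.values():
            out |= genes
        return out


@dataclass
class OxicReactionSet:
    """Curated oxic reactions as R numbers and/or EC numbers."""

    r_numbers: set[str] = field(default_factory=set)
    ec_numbers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.r_numbers and not self.ec_numbers:
            raise ValueError("oxic reaction set must contain at least one R or EC number")


@dataclass
class GeneLengthMap:
    """Gene → nucleotide length (nt) for one organism."""

    organism_code: str
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        bad = [g for g, n in self.lengths.items() if n < 1]
        if bad:
            raise ValueError(f"non-positive gene lengths for: {sorted(bad)[:5]}")


# ---------------------------------------------------------------------------
# identifier normalisation


def _strip_prefix(token: str, organism_code: str | None = None) -> str:
    """Strip ``rn:`` / ``ec:`` / organism-code prefixes from an identifier."""
    if ":" in token:
        prefix, rest = token.split(":", 1)
        if prefix in ("rn", "ec") or (organism_code is not None and prefix == organism_code):
            return rest
    return token


def _normalise_reactions(tokens: Iterable[str], context: str) -> set[str]:
    out: set[str] = set()
    for tok in tokens:
        tok = _strip_prefix(tok.strip())
        if not tok:
            continue
        if R_NUMBER_RE.match(tok):
            out.add(tok)
        else:
            logger.warning("skipping unparseable reaction token %r in %s", tok, context)
    return out


# ---------------------------------------------------------------------------
# KGML


def parse_kgml(xml_text: str, organism_code: str, source: str = "<string>") -> GeneReactionMap:
    """Parse one KGML pathway document into a :class:`GeneReactionMap`.

    Both encodings of the gene–reaction relation found across KGML versions
    are accepted: a ``reaction`` attribute directly on ``<entry type="gene">``
    elements, and separate ``<reaction>`` elements linked to the entry by id.
    Space-separated multi-valued ``name``/``reaction`` attributes are split.
    Genes that appear with no reaction are kept with an empty set.
    """
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed KGML XML in {source}: {exc}") from exc

    reactions_by_id: dict[str, list[str]] = {}
    for rx in root.iter("reaction"):
        rid = rx.get("id")
        if rid is not None:
            reactions_by_id.setdefault(rid, []).extend(rx.get("name", "").split())

    pairs: dict[str, set[str]] = {}
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            continue
        genes = [_strip_prefix(tok, organism_code) for tok in entry.get("name", "").split()]
        tokens = entry.get("reaction", "").split()
        eid = entry.get("id")
        if eid is not None and eid in reactions_by_id:
            tokens.extend(reactions_by_id[eid])
        rxns = _normalise_reactions(tokens, source)
        for gene in genes:
            if not gene:
                continue
            pairs.setdefault(gene, set()).update(rxns)
    return GeneReactionMap(organism_code=organism_code, pairs=pairs)


def merge_gene_reaction_maps(maps: Sequence[GeneReactionMap]) -> GeneReactionMap:
    """Union gene→reaction sets across pathway files of one organism.

    Set union is commutative, so the result is invariant under file order.
    """
    if not maps:
        raise ValueError("no maps to merge")
    codes = {m.organism_code for m in maps}
    if len(codes) > 1:
        raise ValueError(f"cannot merge maps from different organisms: {sorted(codes)}")
    merged: dict[str, set[str]] = {}
    for m in maps:
        for gene, rxns in m.pairs.items():
            merged.setdefault(gene, set()).update(rxns)
    return GeneReactionMap(organism_code=maps[0].organism_code, pairs=merged)


def read_kgml_files(paths: Iterable[str | Path], organism_code: str) -> GeneReactionMap:
    maps = [
        parse_kgml(Path(p).read_text(encoding="utf-8"), organism_code, source=str(p))
        for p in paths
    ]
    return merge_gene_reaction_maps(maps)


# ---------------------------------------------------------------------------
# BRITE .keg


def parse_brite_keg(
    keg_text: str,
    organism_code: str,
    level: int = 2,
    genome_genes: Iterable[str] | None = None,
) -> CategoryGeneMap:
    """Parse a BRITE ``.keg`` hierarchy into category → gene sets.

    Every content line of a ``.keg`` file starts with a single capital letter
    giving its hierarchy depth (A = 1, B = 2, ...).  Gene lines sit at the
    deepest letter present in the file; ``level`` selects which heading tier
    defines the categories (default 2 = the broad "B" tier, e.g. Energy
    metabolism).  A gene nested under several level headings is counted in
    each.  HTML markup and leading numeric accession tokens in headings are
    stripped.
    """
    level_letter = chr(ord("A") + level - 1)
    lines = []
    for raw in keg_text.splitlines():
        if not raw or raw[0] in "#+!%":
            continue
        letter = raw[0]
        if not ("A" <= letter <= "Z"):
            continue
        lines.append((letter, raw[1:].strip()))

    if not lines:
        raise BriteFormatError("no hierarchy lines found in .keg input")
    letters = sorted({letter for letter, _ in lines})
    if level_letter not in letters:
        raise BriteFormatError(f"no level-{level} ({level_letter!r}) headings found")
    gene_letter = letters[-1]
    if gene_letter <= level_letter:
        raise BriteFormatError(
            f"no gene lines below level {level}: deepest tier is {gene_letter!r}"
        )

    categories: dict[str, set[str]] = {}
    universe: set[str] = set()
    current: str | None = None
    for letter, content in lines:
        if letter == level_letter:
            name = _TAG_RE.sub("", content).strip()
            name = re.sub(r"^\d{4,}\s+", "", name)
            if name:
                current = name
                categories.setdefault(current, set())
            else:
                current = None
        elif letter == gene_letter:
            if not content:
                continue
            gene = _strip_prefix(content.split()[0], organism_code)
            if current is None:
                logger.warning("gene line %r outside any level-%d heading; skipped", gene, level)
                continue
            categories[current].add(gene)
            universe.add(gene)

    if genome_genes is not None:
        total = len(set(genome_genes) | universe)
    else:
        total = len(universe)
    if total == 0:
        raise BriteFormatError("hierarchy contains headings but zero genes")
    return CategoryGeneMap(organism_code=organism_code, categories=categories, total_genes=total)


def read_brite_file(
    path: str | Path,
    organism_code: str,
    level: int = 2,
    genome_genes: Iterable[str] | None = None,
) -> CategoryGeneMap:
    return parse_brite_keg(
        Path(path).read_text(encoding="utf-8"), organism_code, level=level, genome_genes=genome_genes
    )


# ---------------------------------------------------------------------------
# oxic reaction list


def load_oxic_reactions(table_text: str) -> OxicReactionSet:
    """Load a delimited oxic-reaction table into normalised, deduplicated sets.

    Each row lists an R number and/or an EC number in any column; field
    separators may be tabs, commas, semicolons or runs of spaces.  Rows
    carrying neither identifier are skipped with a warning.
    """
    r_numbers: set[str] = set()
    ec_numbers: set[str] = set()
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        found = False
        for tok in re.split(r"[\t,;\s]+", line):
            tok = _strip_prefix(tok)
            if R_NUMBER_RE.match(tok):
                r_numbers.add(tok)
                found = True
            elif EC_NUMBER_RE.match(tok):
                ec_numbers.add(tok)
                found = True
        if not found:
            logger.warning("oxic list line %d has neither R nor EC number: %r", lineno, line)
    return OxicReactionSet(r_numbers=r_numbers, ec_numbers=ec_numbers)


def read_oxic_file(path: str | Path) -> OxicReactionSet:
    return load_oxic_reactions(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# gene lengths from FASTA


def read_gene_lengths(fasta_text: str, organism_code: str) -> GeneLengthMap:
    """Count nucleotides per gene from a FASTA of gene sequences.

    The first whitespace-separated header token is the gene identifier
    (organism-code prefix stripped).  Duplicate identifiers and empty
    sequences are errors — both indicate a corrupted export.
    """
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(io.StringIO(fasta_text), "fasta"):
        gene = _strip_prefix(record.id, organism_code)
        if gene in lengths:
            raise ValueError(f"duplicate gene identifier {gene!r} in FASTA")
        n = len(record.seq)
        if n == 0:
            raise ValueError(f"empty sequence for gene {gene!r}")
        lengths[gene] = n
    return GeneLengthMap(organism_code=organism_code, lengths=lengths)


def read_fasta_file(path: str | Path, organism_code: str) -> GeneLengthMap:
    return read_gene_lengths(Path(path).read_text(encoding="utf-8"), organism_code)
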