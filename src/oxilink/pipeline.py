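"""End-to-end analysis: ingest → profile → correct → correlate → report.

The analysis plan mirrors the comparative study design:

1. unit-convert and genus-average the trait table, choosing the
   earliest-sequenced genome as each genus' representative;
2. join trait rows to functional profiles by genome code;
3. estimate the allometric exponent β of q ∝ M^(−β);
4. correlate q with genome size and with the oxic gene proportion, simple
   and body-mass-controlled (partial), and screen every functional category;
5. repeat the q correlations on temperature-corrected rates at each target
   temperature (ectothermic vertebrates and organisms without a measured
   temperature excluded);
6. correlate maximal lifespan (mammals/birds) with the oxic proportion,
   genome size and every category, mass-controlled, with volant /
   non-volant subgroups.

Every result carries its sample size; the provenance block records the
organism counts surviving each filtering step.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allometry import fit_power_law
from .profiles import OXIC_CATEGORY
from .rank_stats import (
    correlation_screen,
    partial_spearman,
    spearman,
    subgroup_partial,
)
from .temperature import CorrectionParams, boltzmann_correct, q10_style_correct
from .traits import OrganismTrait, ensure_mass_specific, genus_average, traits_to_frame

logger = logging.getLogger("oxilink.pipeline")


@dataclass
class AnalysisOptions:
    alpha: float = 0.05
    target_temperatures: tuple[float, ...] = (25.0, 10.0)
    correction_method: str = "q10_style"  # or "boltzmann"
    activation_energy: float = 0.65
    genus_level: bool = True
    geometric_mean: bool = False

    def __post_init__(self) -> None:
        if self.correction_method not in ("q10_style", "boltzmann"):
            raise ValueError(f"unknown correction method {self.correction_method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _safe(fn, *args, **kwargs) -> dict:
    """Compute a correlation, degrading to an error record when the inputs
    are degenerate (e.g. rank-tied at tiny n) instead of aborting the run."""
    try:
        return fn(*args, **kwargs).to_dict()
    except ValueError as exc:
        logger.warning("%s unavailable: %s", fn.__name__, exc)
        return {"error": str(exc), "n": len(args[0])}


def build_analysis_frame(
    traits: Sequence[OrganismTrait],
    profile_matrix: pd.DataFrame,
    options: AnalysisOptions,
) -> tuple[pd.DataFrame, list[str], dict[str, int]]:
    """Genus-average the traits and join them to the profile matrix.

    Returns the joined frame (one row per analysis unit), the list of
    category columns, and the filtering provenance counts.
    """
    provenance = {"n_species_input": len(traits)}
    records = [ensure_mass_specific(t) for t in traits]
    if options.genus_level:
        records = genus_average(records, geometric=options.geometric_mean)
    provenance["n_analysis_rows"] = len(records)

    frame = traits_to_frame(records)
    joined = frame[frame["genome_code"].isin(profile_matrix.index)].copy()
    provenance["n_joined"] = len(joined)
    if len(joined) < len(frame):
        logger.warning("%d rows lack a functional profile; dropped", len(frame) - len(joined))

    categories = [c for c in profile_matrix.columns]
    profile_part = profile_matrix.loc[joined["genome_code"]].reset_index(drop=True)
    joined = pd.concat([joined.reset_index(drop=True), profile_part], axis=1)
    joined["oxic_proportion"] = joined[OXIC_CATEGORY]
    return joined, categories, provenance


def _corrected_rate(q: float | None, temperature: float, target: float, options: AnalysisOptions):
    if options.correction_method == "boltzmann":
        params = CorrectionParams(
            target_temperature=target, activation_energy=options.activation_energy
        )
        return boltzmann_correct(q, temperature, params)
    return q10_style_correct(q, temperature, target)


def run_metabolic_analysis(
    frame: pd.DataFrame, categories: Sequence[str], options: AnalysisOptions
) -> dict:
    """Rate-side analyses: allometry, genome size, oxic proportion, the
    category screen, and the temperature-corrected variants."""
    core = frame.dropna(subset=["q_W_per_g", "mass_g"]).copy()
    if len(core) < 4:
        raise ValueError(f"only {len(core)} rows with q and mass; need at least 4")
    if len(core) < 8:
        logger.warning("n=%d is low-powered; interpret with caution", len(core))
    q = core["q_W_per_g"].to_numpy(float)
    mass = core["mass_g"].to_numpy(float)

    out: dict = {
        "n": int(len(core)),
        "allometry": fit_power_law(mass, q).to_dict(),
        "q_vs_mass": _safe(spearman, q, mass),
    }

    genome = core.dropna(subset=["genome_bp"])
    if len(genome) >= 4:
        gq = genome["q_W_per_g"].to_numpy(float)
        gm = genome["mass_g"].to_numpy(float)
        gs = genome["genome_bp"].to_numpy(float)
        out["genome_size"] = {
            "q_vs_genome": _safe(spearman, gq, gs),
            "mass_vs_genome": _safe(spearman, gm, gs),
            "q_vs_genome_given_mass": _safe(
                partial_spearman, gq, gs, gm, control_name="body_mass"
            ),
            "q_vs_mass_given_genome": _safe(
                partial_spearman, gq, gm, gs, control_name="genome_size"
            ),
        }

    oxic = core["oxic_proportion"].to_numpy(float)
    out["oxic"] = {
        "q_vs_oxic": _safe(spearman, q, oxic),
        "oxic_vs_mass": _safe(spearman, oxic, mass),
        "q_vs_oxic_given_mass": _safe(
            partial_spearman, q, oxic, mass, control_name="body_mass"
        ),
        "q_vs_mass_given_oxic": _safe(
            partial_spearman, q, mass, oxic, control_name="oxic_proportion"
        ),
    }

    screen_rows = correlation_screen(
        core[list(categories)], q, mass, alpha=options.alpha, keep_all=True
    )
    out["screen"] = [row.to_dict() for row in screen_rows if row.partial.p < options.alpha]
    out["screen_all"] = [row.to_dict() for row in screen_rows]
    return out


def run_temperature_variants(
    frame: pd.DataFrame, options: AnalysisOptions
) -> tuple[dict, dict[str, int]]:
    """Oxic/genome correlations against temperature-corrected rates."""
    eligible = frame[
        (frame["taxon_group"] != "ectothermic_vertebrate") & frame["temp_C"].notna()
    ].dropna(subset=["q_W_per_g", "mass_g"])
    provenance = {"n_temperature_eligible": int(len(eligible))}
    variants: dict = {}
    if len(eligible) < 4:
        logger.warning("only %d temperature-eligible rows; variants skipped", len(eligible))
        return variants, provenance

    mass = eligible["mass_g"].to_numpy(float)
    oxic = eligible["oxic_proportion"].to_numpy(float)
    for target in options.target_temperatures:
        qx = np.array(
            [
                _corrected_rate(row.q_W_per_g, row.temp_C, target, options)
                for row in eligible.itertuples()
            ]
        )
        entry = {
            "method": options.correction_method,
            "n": int(len(eligible)),
            "qx_vs_oxic": _safe(spearman, qx, oxic),
            "qx_vs_oxic_given_mass": _safe(
                partial_spearman, qx, oxic, mass, control_name="body_mass"
            ),
            "qx_vs_mass_given_oxic": _safe(
                partial_spearman, qx, mass, oxic, control_name="oxic_proportion"
            ),
        }
        genome = eligible.dropna(subset=["genome_bp"])
        if len(genome) >= 4:
            qg = np.array(
                [
                    _corrected_rate(row.q_W_per_g, row.temp_C, target, options)
                    for row in genome.itertuples()
                ]
            )
            entry["qx_vs_genome"] = _safe(spearman, qg, genome["genome_bp"])
            entry["qx_vs_genome_given_mass"] = _safe(
                partial_spearman, qg, genome["genome_bp"], genome["mass_g"],
                control_name="body_mass",
            )
        variants[f"{target:g}C"] = entry
    return variants, provenance


def run_lifespan_analysis(
    frame: pd.DataFrame, categories: Sequence[str], options: AnalysisOptions
) -> dict:
    """Lifespan-side analyses on the organisms (mammals/birds) with a
    maximal-lifespan record."""
    life = frame.dropna(subset=["lifespan_y", "mass_g", "oxic_proportion"]).copy()
    if len(life) < 4:
        raise ValueError(f"only {len(life)} rows with lifespan; need at least 4")
    span = life["lifespan_y"].to_numpy(float)
    mass = life["mass_g"].to_numpy(float)
    oxic = life["oxic_proportion"].to_numpy(float)

    out: dict = {
        "n": int(len(life)),
        "lifespan_vs_oxic": spearman(span, oxic).to_dict(),
        "lifespan_vs_mass": spearman(span, mass).to_dict(),
        "lifespan_vs_oxic_given_mass": partial_spearman(
            span, oxic, mass, control_name="body_mass"
        ).to_dict(),
        "lifespan_vs_mass_given_oxic": partial_spearman(
            span, mass, oxic, control_name="oxic_proportion"
        ).to_dict(),
    }

    genome = life.dropna(subset=["genome_bp"])
    if len(genome) >= 4:
        out["lifespan_vs_genome_given_mass"] = partial_spearman(
            genome["lifespan_y"], genome["genome_bp"], genome["mass_g"], control_name="body_mass"
        ).to_dict()

    per_category = {}
    for cat in categories:
        values = life[cat].to_numpy(float)
        if np.ptp(values) == 0.0:
            continue
        try:
            per_category[str(cat)] = partial_spearman(
                span, values, mass, control_name="body_mass"
            ).to_dict()
        except ValueError as exc:
            logger.warning("lifespan partial for %r skipped: %s", cat, exc)
    out["category_partials"] = per_category

    if life["volant"].notna().any():
        groups = subgroup_partial(
            life, "oxic_proportion", "lifespan_y", "mass_g", group_by="volant"
        )
        out["by_volancy"] = {
            ("volant" if level else "non_volant"): res.to_dict() for level, res in groups.items()
        }
    return out


def run_full_analysis(
    traits: Sequence[OrganismTrait],
    profile_matrix: pd.DataFrame,
    options: AnalysisOptions | None = None,
    seed: int | None = None,
) -> dict:
    """The complete report: metabolic, temperature, lifespan analyses plus
    filtering provenance."""
    options = options or AnalysisOptions()
    frame, categories, provenance = build_analysis_frame(traits, profile_matrix, options)

    report: dict = {"provenance": provenance}
    report["metabolic"] = run_metabolic_analysis(frame, categories, options)
    variants, temp_prov = run_temperature_variants(frame, options)
    report["temperature_variants"] = variants
    provenance.update(temp_prov)

    n_lifespan = int(frame["lifespan_y"].notna().sum())
    provenance["n_lifespan"] = n_lifespan
    if n_lifespan >= 4:
        try:
            report["lifespan"] = run_lifespan_analysis(frame, categories, options)
        except ValueError as exc:
            logger.warning("lifespan analysis skipped: %s", exc)
            report["lifespan"] = None
    else:
        report["lifespan"] = None

    provenance["config_hash"] = options.config_hash()
    if seed is not None:
        provenance["seed"] = seed
    return report


# ---------------------------------------------------------------------------
# serialisation


def write_report(report: dict, directory: str | Path) -> dict[str, Path]:
    """Serialise the report as JSON plus a screen TSV (the Table-1 analogue)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    paths = {"report": json_path}
    screen = report.get("metabolic", {}).get("screen_all")
    if screen:
        rows = pd.DataFrame(
            [
                {
                    "category": row["category"],
                    "r_s": row["simple"]["r"],
                    "p": row["simple"]["p"],
                    "r_s_partial": row["partial"]["r"],
                    "p_partial": row["partial"]["p"],
                    "q_value_bh": row["q_value"],
                    "n": row["partial"]["n"],
                }
                for row in screen
            ]
        )
        screen_path = directory / "screen.tsv"
        rows.to_csv(screen_path, sep="\t", index=False)
        paths["screen"] = screen_path
    return paths
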