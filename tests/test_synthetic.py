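"""Synthetic panel generator: determinism, planted structure, fixtures."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from oxilink.allometry import fit_power_law
from oxilink.kegg_io import read_brite_file, read_fasta_file, read_kgml_files, read_oxic_file
from oxilink.profiles import call_oxic_genes, compute_profile
from oxilink.rank_stats import spearman
from oxilink.synthetic import (
    SyntheticPanelConfig,
    generate_panel,
    write_fixture_files,
)


class TestConfig:
    def test_defaults_emulate_the_study_panel(self):
        config = SyntheticPanelConfig()
        assert config.n_genera == 101
        assert config.beta_true == 0.035
        assert config.mass_log10_range == (-13.0, 6.0)

    def test_lifespan_study_is_mammal_bird_thirty(self):
        config = SyntheticPanelConfig.lifespan_study(seed=3)
        panel = generate_panel(config, with_annotations=False)
        taxa = [t.taxon_group for t in panel.traits]
        assert len(taxa) == 30
        assert taxa.count("mammal") == 23 and taxa.count("bird") == 7
        assert all(t.max_lifespan is not None for t in panel.traits)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mass_log10_range": (5.0, -5.0)},
            {"sigma_rate": -0.1},
            {"category_overlap_rate": 1.5},
            {"oxic_effect_on_lifespan": 2.0},
            {"taxon_mix": {"dragon": 1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticPanelConfig(**kwargs)

    def test_infeasible_oxic_proportion_is_error(self):
        config = SyntheticPanelConfig(n_genera=5, oxic_base=1.5, sigma_oxic=0.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_panel(config, with_annotations=False)

    def test_yaml_round_trip(self, tmp_path):
        config = SyntheticPanelConfig(n_genera=12, seed=5, genes_range=(80, 200))
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert SyntheticPanelConfig.from_yaml(path) == config


class TestDeterminism:
    def test_identical_seeds_give_identical_panels(self):
        config = SyntheticPanelConfig(n_genera=10, genes_range=(60, 120), seed=9)
        a = generate_panel(config)
        b = generate_panel(config)
        pd.testing.assert_frame_equal(a.truth.per_organism, b.truth.per_organism)
        pd.testing.assert_frame_equal(a.truth.category_proportions, b.truth.category_proportions)
        assert a.traits == b.traits
        for code in a.annotations:
            assert a.annotations[code].gene_reactions.pairs == b.annotations[code].gene_reactions.pairs
            assert a.annotations[code].categories.categories == b.annotations[code].categories.categories

    def test_fixture_files_byte_identical_across_runs(self, tmp_path):
        config = SyntheticPanelConfig(n_genera=3, n_categories=4, genes_range=(60, 120), seed=13)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        m1 = write_fixture_files(generate_panel(config), d1)
        m2 = write_fixture_files(generate_panel(config), d2)
        assert m1["sha256"].tolist() == m2["sha256"].tolist()
        for name in m1["path"]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False)

    def test_annotation_flag_does_not_change_traits(self):
        config = SyntheticPanelConfig(n_genera=8, genes_range=(60, 120), seed=3)
        with_ann = generate_panel(config, with_annotations=True)
        without = generate_panel(config, with_annotations=False)
        assert with_ann.traits == without.traits


class TestPlantedStructure:
    def test_noiseless_panel_is_exact_power_law(self):
        config = SyntheticPanelConfig(
            n_genera=40,
            sigma_rate=0.0,
            sigma_oxic=0.0,
            sigma_genome=0.0,
            sigma_lifespan=0.0,
            oxic_effect_on_rate=0.0,
            oxic_effect_on_lifespan=0.0,
            beta_true=0.12,
            seed=1,
        )
        panel = generate_panel(config, with_annotations=False)
        mass = np.array([t.body_mass for t in panel.traits])
        q = np.array([t.mass_specific_rate for t in panel.traits])
        fit = fit_power_law(mass, q)
        assert fit.beta == pytest.approx(0.12, abs=1e-10)

    def test_planted_correlations_positive_across_seeds(self):
        positives_mg = positives_qox = 0
        n_seeds = 40
        for seed in range(n_seeds):
            panel = generate_panel(SyntheticPanelConfig(seed=seed), with_annotations=False)
            mass = np.array([t.body_mass for t in panel.traits])
            genome = np.array([t.genome_size for t in panel.traits])
            q = np.array([t.mass_specific_rate for t in panel.traits])
            oxic = panel.truth.per_organism["oxic_proportion"].to_numpy()
            positives_mg += spearman(mass, genome).r > 0
            positives_qox += spearman(q, oxic).r > 0
        assert positives_mg == n_seeds
        assert positives_qox == n_seeds

    def test_lifespan_only_for_mammals_and_birds(self, medium_panel):
        for t in medium_panel.traits:
            if t.taxon_group in ("mammal", "bird"):
                assert t.max_lifespan is not None
            else:
                assert t.max_lifespan is None

    def test_temperature_availability_mirrors_study(self, medium_panel):
        for t in medium_panel.traits:
            if t.taxon_group in ("bird", "insect"):
                assert t.temperature is None
            else:
                assert t.temperature is not None


class TestFixtureFiles:
    def test_manifest_counts_three_per_organism_plus_two(self, small_panel, tmp_path):
        manifest = write_fixture_files(small_panel, tmp_path / "fx")
        assert len(manifest) == 3 * len(small_panel.traits) + 2

    def test_empty_panel_writes_only_panel_level_files(self, tmp_path):
        panel = generate_panel(SyntheticPanelConfig(n_genera=0, seed=0))
        manifest = write_fixture_files(panel, tmp_path / "empty")
        assert manifest["path"].tolist() == ["traits.tsv", "oxic_reactions.tsv"]

    def test_refuses_nonempty_directory_without_overwrite(self, small_panel, tmp_path):
        target = tmp_path / "fx"
        target.mkdir()
        (target / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture_files(small_panel, target)
        write_fixture_files(small_panel, target, overwrite=True)

    def test_round_trip_reproduces_every_planted_proportion(self, small_panel, tmp_path):
        directory = tmp_path / "fx"
        write_fixture_files(small_panel, directory)
        oxic = read_oxic_file(directory / "oxic_reactions.tsv")
        truth = small_panel.truth.category_proportions
        for code in truth.index:
            grm = read_kgml_files([directory / f"{code}.kgml"], code)
            glm = read_fasta_file(directory / f"{code}.fna", code)
            cgm = read_brite_file(directory / f"{code}.keg", code)
            oxic_genes = call_oxic_genes(grm, oxic)
            profile = compute_profile(cgm, oxic_genes, lengths=glm)
            # exact equality: realised integer counts over the same denominator
            for category in truth.columns:
                assert profile.categories[category].proportion == truth.loc[code, category]
            # gene lengths survive the FASTA round trip exactly
            assert glm.lengths == small_panel.annotations[code].gene_lengths.lengths

    def test_round_trip_reproduces_gene_reaction_maps(self, small_panel, tmp_path):
        directory = tmp_path / "fx2"
        write_fixture_files(small_panel, directory)
        for code, ann in small_panel.annotations.items():
            grm = read_kgml_files([directory / f"{code}.kgml"], code)
            assert grm.pairs == ann.gene_reactions.pairs
            cgm = read_brite_file(directory / f"{code}.keg", code)
            assert cgm.categories == ann.categories.categories
            assert cgm.total_genes == ann.categories.total_genes


def test_category_overlap_present_in_annotations(small_panel):
    for ann in small_panel.annotations.values():
        sizes = sum(len(v) for v in ann.categories.categories.values())
        assert sizes >= ann.categories.total_genes  # overlap or full cover
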