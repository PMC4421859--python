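"""Rank statistics: Spearman, partial Spearman, the category screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from oxilink.profiles import OXIC_CATEGORY
from oxilink.rank_stats import (
    correlation_screen,
    format_p,
    partial_spearman,
    rank_transform,
    spearman,
    subgroup_partial,
)


def precision_matrix_partial(x, y, z):
    """Independent oracle: invert the 3x3 rank-correlation matrix."""
    ranks = np.vstack([rank_transform(x), rank_transform(y), rank_transform(z)])
    corr = np.corrcoef(ranks)
    prec = np.linalg.inv(corr)
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


def enumerate_permutation_p(x, y):
    """Independent oracle: exhaustive two-sided permutation p for Spearman."""
    r_obs = sps.spearmanr(x, y).statistic
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(sps.spearmanr(x, perm).statistic) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


class TestRankTransform:
    def test_strictly_increasing(self):
        assert rank_transform([10, 20, 30]).tolist() == [1, 2, 3]

    def test_average_ties(self):
        assert rank_transform([5, 5, 7]).tolist() == [1.5, 1.5, 3]

    @given(st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=40))
    def test_matches_scipy_rankdata(self, values):
        assert np.allclose(rank_transform(values), sps.rankdata(values))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([1.0, np.nan, 2.0])


class TestSpearman:
    def test_monotone_gives_plus_one(self):
        assert spearman([1, 2, 3, 4], [2, 4, 6, 8]).r == 1.0

    def test_reversal_gives_minus_one(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).r == -1.0

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_scipy_at_n30(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x, y = rng.normal(size=(2, 30))
            mine = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert mine.r == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_n_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for n in (6, 7):
            x, y = rng.normal(size=(2, n))
            assert spearman(x, y).p == pytest.approx(enumerate_permutation_p(x, y), abs=1e-12)

    def test_ties_handled_with_average_ranks(self):
        x = [1, 2, 2, 3, 5, 5, 5, 8, 9, 10, 11, 12]
        y = [3, 3, 1, 4, 4, 6, 7, 7, 9, 9, 12, 11]
        ref = sps.spearmanr(x, y)
        mine = spearman(x, y)
        assert mine.r == pytest.approx(ref.statistic, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(size=12)
        y = rng.lognormal(size=12)
        base = spearman(x, y)
        assert spearman(y, x).r == pytest.approx(base.r, abs=1e-12)
        assert spearman(np.log(x), y**3).r == pytest.approx(base.r, abs=1e-12)


class TestPartialSpearman:
    def test_identical_variables_give_one(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert partial_spearman(x, x, [2.0, 7.0, 1.0, 8.0, 2.5]).r == 1.0

    def test_reduces_to_simple_when_controller_uncorrelated(self):
        # find a z whose ranks are exactly uncorrelated with both x and y
        x = np.arange(8, dtype=float)
        y = np.array([0, 2, 1, 3, 5, 4, 7, 6], dtype=float)
        z = None
        for perm in itertools.permutations(range(8)):
            cand = np.array(perm, dtype=float)
            if (
                abs(sps.spearmanr(x, cand).statistic) < 1e-12
                and abs(sps.spearmanr(y, cand).statistic) < 1e-12
            ):
                z = cand
                break
        assert z is not None
        assert partial_spearman(x, y, z).r == pytest.approx(spearman(x, y).r, abs=1e-12)

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            x, y, z = rng.normal(size=(3, 30))
            assert partial_spearman(x, y, z).r == pytest.approx(
                precision_matrix_partial(x, y, z), abs=1e-10
            )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x, y, z = rng.normal(size=(3, 40))
        frame = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(frame, x="x", y="y", covar="z", method="spearman")
        mine = partial_spearman(x, y, z)
        assert mine.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_controller_is_error(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="degenerate"):
            partial_spearman(x, [5.0, 1.0, 4.0, 2.0, 3.0], x)

    def test_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(8)
        x, y, z = rng.normal(size=(3, 15))
        assert partial_spearman(x, y, z).r == pytest.approx(
            partial_spearman(y, x, z).r, abs=1e-12
        )

    def test_invariant_under_monotone_transforms_of_all_arguments(self):
        rng = np.random.default_rng(12)
        x, y, z = rng.lognormal(size=(3, 20))
        base = partial_spearman(x, y, z).r
        assert partial_spearman(np.log(x), y**3, np.sqrt(z)).r == pytest.approx(
            base, abs=1e-12
        )

    def test_needs_four_observations(self):
        with pytest.raises(ValueError, match="4"):
            partial_spearman([1, 2, 3], [3, 1, 2], [2, 3, 1])


class TestCorrelationScreen:
    def test_category_identical_to_rate_ranks_first(self):
        rng = np.random.default_rng(2)
        n = 30
        q = rng.lognormal(size=n)
        mass = rng.lognormal(size=n)
        matrix = pd.DataFrame(
            {"Echo": q.copy(), "Noise1": rng.normal(size=n), "Noise2": rng.normal(size=n)}
        )
        rows = correlation_screen(matrix, q, mass)
        assert rows[0].category == "Echo"
        assert rows[0].simple.r == 1.0

    def test_constant_category_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        n = 20
        matrix = pd.DataFrame({"Flat": np.ones(n), "Var": rng.normal(size=n)})
        with caplog.at_level("WARNING"):
            rows = correlation_screen(matrix, rng.normal(size=n), rng.lognormal(size=n), keep_all=True)
        assert [r.category for r in rows] == ["Var"]
        assert "Flat" in caplog.text

    def test_rows_sorted_by_partial_descending(self, medium_panel):
        q = np.array([t.mass_specific_rate for t in medium_panel.traits])
        mass = np.array([t.body_mass for t in medium_panel.traits])
        rows = correlation_screen(medium_panel.profile_matrix(), q, mass, keep_all=True)
        partials = [r.partial.r for r in rows]
        assert partials == sorted(partials, reverse=True)
        assert all(r.q_value is not None for r in rows)

    def test_too_few_organisms_is_error(self):
        matrix = pd.DataFrame({"A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="4"):
            correlation_screen(matrix, [1, 2, 3], [1, 2, 3])


class TestSubgroupPartial:
    def _frame(self, rng, n, flag):
        mass = rng.lognormal(size=n)
        oxic = rng.normal(0.1, 0.02, size=n)
        life = np.exp(0.2 * np.log(mass) - 8.0 * oxic + rng.normal(0, 0.1, size=n))
        return pd.DataFrame(
            {"oxic": oxic, "life": life, "mass": mass, "volant": flag}
        )

    def test_planted_negative_effect_recovered_in_both_groups(self):
        rng = np.random.default_rng(33)
        frame = pd.concat(
            [self._frame(rng, 10, True), self._frame(rng, 20, False)], ignore_index=True
        )
        results = subgroup_partial(frame, "oxic", "life", "mass", group_by="volant")
        assert set(results) == {True, False}
        assert results[True].n == 10 and results[False].n == 20
        assert results[True].r < 0 and results[False].r < 0

    def test_small_group_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(34)
        frame = pd.concat(
            [self._frame(rng, 3, True), self._frame(rng, 12, False)], ignore_index=True
        )
        with caplog.at_level("WARNING"):
            results = subgroup_partial(frame, "oxic", "life", "mass", group_by="volant")
        assert set(results) == {False}

    def test_constant_flag_equals_ungrouped_analysis(self):
        rng = np.random.default_rng(35)
        frame = self._frame(rng, 15, False)
        results = subgroup_partial(frame, "oxic", "life", "mass", group_by="volant")
        assert set(results) == {False}
        direct = partial_spearman(frame["oxic"], frame["life"], frame["mass"])
        assert results[False].r == pytest.approx(direct.r, abs=1e-12)


def test_p_value_formatting_floor():
    assert format_p(1e-20) == "< 2.2e-16"
    assert format_p(0.0321) == "0.0321"
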