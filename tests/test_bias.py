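"""Coverage-bias propagation: theoretical/relative abundance, dissimilarity, ANOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from pnaprimers.bias import (
    MockCommunity,
    RelativeAbundanceWarning,
    anova_one_way,
    anova_two_way_no_rep,
    measurements_to_frame,
    pairwise_dissimilarity_matrix,
    percent_dissimilarity,
    relative_abundance,
    theoretical_abundance,
)
from pnaprimers.synth import hypothetical_pna_community, silva132_coverage_table


@pytest.fixture(scope="module")
def worked_example():
    """Published coverage fractions applied to the hypothetical community."""
    cov = silva132_coverage_table()
    community = hypothetical_pna_community()
    return cov, community, theoretical_abundance(cov, community)


class TestTheoreticalAbundance:
    def test_published_anaob_product(self, worked_example):
        _, _, measurements = worked_example
        m = next(m for m in measurements
                 if m.pair_name == "1055f-1392r" and m.group_label == "AnAOB")
        assert m.measured == pytest.approx(0.830 * 4.00e9)  # 3.32e9 copies/mL

    def test_zero_and_full_coverage_limits(self):
        cov = pd.DataFrame({"G": [0.0, 1.0]}, index=["a", "b"])
        out = theoretical_abundance(cov, MockCommunity({"G": 5e8}))
        assert [m.measured for m in out] == [0.0, 5e8]

    def test_linearity_in_community_scale(self, worked_example):
        cov, community, measurements = worked_example
        scaled = theoretical_abundance(cov, community.scaled(2.5))
        for a, b in zip(measurements, scaled):
            assert b.measured == pytest.approx(2.5 * a.measured)

    def test_measured_never_exceeds_truth(self, worked_example):
        _, _, measurements = worked_example
        assert all(m.measured <= m.true_abundance for m in measurements)

    def test_missing_community_entry_is_keyed_error(self):
        cov = pd.DataFrame({"Unknown": [0.5]}, index=["a"])
        with pytest.raises(KeyError, match="Unknown"):
            theoretical_abundance(cov, MockCommunity({"G": 1.0}))


class TestRelativeAbundance:
    def test_published_anaob_fraction(self, worked_example):
        _, _, measurements = worked_example
        rel = relative_abundance(measurements)
        assert rel.loc["1055f-1392r", "AnAOB"] == pytest.approx(0.746, abs=5e-4)

    def test_zero_group_measurement_gives_zero_fraction(self, worked_example):
        _, _, measurements = worked_example
        rel = relative_abundance(measurements)
        assert rel.loc["338f-518r", "AnAOB"] == 0.0

    def test_group_coverage_above_eub_warns_and_exceeds_one(self):
        cov = pd.DataFrame({"EUB": [0.4], "G": [0.9]}, index=["p"])
        out = theoretical_abundance(cov, MockCommunity({"EUB": 1e9, "G": 1e9}))
        with pytest.warns(RelativeAbundanceWarning, match="exceeds 1"):
            rel = relative_abundance(out)
        assert rel.loc["p", "G"] == pytest.approx(2.25)

    def test_zero_eub_measurement_flagged_not_dropped(self):
        cov = pd.DataFrame({"EUB": [0.0], "G": [0.5]}, index=["p"])
        out = theoretical_abundance(cov, MockCommunity({"EUB": 1e9, "G": 1e9}))
        with pytest.warns(RelativeAbundanceWarning, match="undefined"):
            rel = relative_abundance(out)
        assert "p" in rel.index and np.isnan(rel.loc["p", "G"])

    def test_invariant_to_whole_community_rescaling(self, worked_example):
        """Relative data cannot see absolute change: the reason the analysis
        cautions against EUB normalization for dynamics."""
        cov, community, measurements = worked_example
        rel1 = relative_abundance(measurements)
        rel2 = relative_abundance(theoretical_abundance(cov, community.scaled(7.0)))
        pd.testing.assert_frame_equal(rel1, rel2)


class TestPercentDissimilarity:
    def test_hand_computed_eub_example(self):
        # |4.45 - 7.00| / (4.45 + 7.00) x 100
        assert percent_dissimilarity([4.45e9], [7.00e9]) == pytest.approx(22.27, abs=0.005)

    def test_identical_vectors_give_zero(self):
        assert percent_dissimilarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports_give_hundred(self):
        assert percent_dissimilarity([1, 0], [0, 1]) == 100.0

    def test_all_zero_vectors_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_dissimilarity([0.0, 0.0], [0.0, 0.0])

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=8),
        st.data(),
    )
    def test_properties(self, x, data):
        y = data.draw(st.lists(st.floats(0, 1e6, allow_nan=False),
                               min_size=len(x), max_size=len(x)))
        if sum(x) + sum(y) == 0:
            return
        d = percent_dissimilarity(x, y)
        assert 0.0 <= d <= 100.0
        assert d == percent_dissimilarity(y, x)  # symmetry
        assert percent_dissimilarity(x, x) == 0.0 if sum(x) else True
        # scale invariance
        c = 3.7
        assert percent_dissimilarity([c * v for v in x], [c * v for v in y]) == pytest.approx(d)
        # agreement with the scipy implementation
        assert d == pytest.approx(scipy.spatial.distance.braycurtis(x, y) * 100)


class TestPairwiseDissimilarity:
    def test_three_pairs_give_three_combinations(self):
        sample = {"s": {"a": [1.0], "b": [2.0], "c": [3.0]}}
        results = pairwise_dissimilarity_matrix(sample)
        assert len(results) == 3
        assert {(r.pair_x, r.pair_y) for r in results} == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_duplicated_vectors_all_zero(self):
        sample = {"s": {"a": [1.0, 2.0], "b": [1.0, 2.0]}}
        assert all(r.dissimilarity_pct == 0.0 for r in pairwise_dissimilarity_matrix(sample))

    def test_single_pair_yields_empty_not_error(self):
        assert pairwise_dissimilarity_matrix({"s": {"a": [1.0]}}) == []

    def test_entries_match_elementwise_calls(self):
        rng = np.random.default_rng(3)
        sample = {"s": {f"p{i}": rng.uniform(1, 10, size=3).tolist() for i in range(4)}}
        for r in pairwise_dissimilarity_matrix(sample):
            assert r.dissimilarity_pct == percent_dissimilarity(
                sample["s"][r.pair_x], sample["s"][r.pair_y])


def _statsmodels_two_way(table: pd.DataFrame):
    """Independent oracle: additive OLS fit + anova_lm."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = table.stack().rename("value").reset_index()
    long.columns = ["row", "col", "value"]
    model = smf.ols("value ~ C(row) + C(col)", data=long).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    return (
        (tab.loc["C(row)", "F"], tab.loc["C(row)", "PR(>F)"]),
        (tab.loc["C(col)", "F"], tab.loc["C(col)", "PR(>F)"]),
    )


class TestTwoWayAnova:
    def test_identical_rows_have_zero_row_effect(self):
        table = pd.DataFrame([[1.0, 2.0, 3.0]] * 3)
        row, col = anova_two_way_no_rep(table)
        assert row.F == pytest.approx(0.0, abs=1e-25)
        assert row.p_value == pytest.approx(1.0)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.uniform(0, 10, size=(2, 3)))
        row, col = anova_two_way_no_rep(table)
        (f_a, p_a), (f_b, p_b) = _statsmodels_two_way(table)
        assert row.F == pytest.approx(f_a)
        assert row.p_value == pytest.approx(p_a)
        assert col.F == pytest.approx(f_b)
        assert col.p_value == pytest.approx(p_b)
        assert row.df == (1, 2) and col.df == (2, 2)

    def test_textbook_block_design_matches_hand_calculation(self):
        # 2 treatments x 3 blocks, values [[4, 6, 8], [6, 10, 12]]:
        # grand mean 23/3; SS_rows = 50/3, SS_cols = 76/3, SS_res = 4/3,
        # so F_row = (50/3)/(2/3) = 25 and F_col = (38/3)/(2/3) = 19.
        table = pd.DataFrame([[4.0, 6.0, 8.0], [6.0, 10.0, 12.0]])
        row, col = anova_two_way_no_rep(table)
        assert row.F == pytest.approx(25.0)
        assert col.F == pytest.approx(19.0)

    def test_worked_example_reaches_significance(self, worked_example):
        _, _, measurements = worked_example
        table = measurements_to_frame(measurements)
        row, col = anova_two_way_no_rep(table)
        assert min(row.p_value, col.p_value) < 0.01

    def test_permuting_levels_leaves_f_unchanged(self, worked_example):
        _, _, measurements = worked_example
        table = measurements_to_frame(measurements)
        row, col = anova_two_way_no_rep(table)
        shuffled = table.iloc[::-1, ::-1]
        row2, col2 = anova_two_way_no_rep(shuffled)
        assert row2.F == pytest.approx(row.F)
        assert col2.F == pytest.approx(col.F)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            anova_two_way_no_rep(table)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            anova_two_way_no_rep(pd.DataFrame([[1.0, 2.0]]))


class TestOneWayAnova:
    def test_identical_constant_groups_flagged_degenerate(self):
        res = anova_one_way([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert np.isnan(res.F) and res.p_value == 1.0

    def test_zero_within_variance_distinct_means(self):
        res = anova_one_way([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.F) and res.p_value == 0.0

    def test_two_groups_equal_t_squared(self):
        rng = np.random.default_rng(8)
        g1, g2 = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        res = anova_one_way([g1, g2])
        t = scipy.stats.ttest_ind(g1, g2)
        assert res.F == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)
        assert res.df == (1, 20)

    def test_power_against_twofold_primer_effect(self):
        """Triplicates with a 2-fold primer effect at 5% CV almost always
        reach p < 0.01: the design that flags primer choice as significant."""
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            base = 1e9
            g1 = base * rng.lognormal(0, 0.05, size=3)
            g2 = 2 * base * rng.lognormal(0, 0.05, size=3)
            if anova_one_way([g1, g2]).p_value < 0.01:
                hits += 1
        assert hits >= 0.95 * n_runs

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            anova_one_way([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="2 groups"):
            anova_one_way([[1.0, 2.0]])


def test_mock_community_rejects_negative():
    with pytest.raises(ValueError, match="negative"):
        MockCommunity({"EUB": -1.0})
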