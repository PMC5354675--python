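"""Welch/BH differential expression, DEG partition, immune DEG values, log-rank."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from melafidelity.datamodel_io import ScoreTable, SurvivalRecord
from melafidelity.immune_divergence import (
    correlate_genes_with_scores,
    differential_expression,
    immune_deg_values,
    partition_degs,
    select_top_degs,
    survival_logrank,
)
from tests.conftest import make_matrix


def welch_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Brute-force Welch t and two-sided p from the textbook formulas."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * special.stdtr(df, -abs(t))
    return t, p


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Hand step-up Benjamini-Hochberg: adj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj_sorted[i] = running
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


class TestDifferentialExpression:
    def test_hand_welch_on_three_vs_three(self):
        lines = make_matrix([[1.0, 2.0, 3.0]])
        tumours = make_matrix([[4.0, 5.0, 6.0]])
        table = differential_expression(lines, tumours)
        t, p = welch_oracle(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert table["t_statistic"].iloc[0] == pytest.approx(t, abs=1e-12)
        assert table["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))

    def test_identical_groups_give_null_statistics(self):
        lines = make_matrix(np.tile([[2.0], [5.0]], (1, 3)))
        tumours = make_matrix(np.tile([[2.0], [5.0]], (1, 4)))
        table = differential_expression(lines, tumours)
        assert (table["t_statistic"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()
        assert (table["adjusted_p"] == 1.0).all()

    def test_matches_oracles_on_random_matrix(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(50, 8)), rng.normal(size=(50, 12))
        table = differential_expression(make_matrix(a), make_matrix(b))
        for i, gene in enumerate(table.index):
            t, p = welch_oracle(a[i], b[i])
            assert table.at[gene, "t_statistic"] == pytest.approx(t, abs=1e-10)
            assert table.at[gene, "p_value"] == pytest.approx(p, abs=1e-10)
        np.testing.assert_allclose(
            table["adjusted_p"], bh_oracle(table["p_value"].to_numpy()), atol=1e-12
        )

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError):
            differential_expression(make_matrix([[1.0]]), make_matrix([[1.0, 2.0]]))


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        adj = bh_oracle(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        from statsmodels.stats.multitest import multipletests

        _, got, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(got, adj, atol=1e-15)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_statsmodels_agrees_with_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        _, got, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(got, bh_oracle(p), atol=1e-12)


class TestSelectTopDegs:
    @staticmethod
    def fake_table(m, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        genes = [f"G{i:05d}" for i in range(m)]
        table = pd.DataFrame(
            {"p_value": p, "adjusted_p": bh_oracle(p), "t_statistic": rng.normal(size=m)},
            index=genes,
        )
        order = sorted(
            genes,
            key=lambda g: (table.at[g, "adjusted_p"], table.at[g, "p_value"],
                           -abs(table.at[g, "t_statistic"]), g),
        )
        table["rank"] = pd.Series(range(1, m + 1), index=order)
        return table

    def test_five_percent_of_full_universe(self):
        table = self.fake_table(20460)
        assert len(select_top_degs(table, 0.05)) == 1023

    def test_small_table(self):
        assert len(select_top_degs(self.fake_table(100), 0.05)) == 5

    def test_tie_break_is_deterministic(self):
        genes = ["B", "A", "C", "D"]
        table = pd.DataFrame(
            {"p_value": 0.5, "adjusted_p": 0.5, "t_statistic": 1.0}, index=genes
        )
        table["rank"] = pd.Series(
            range(1, 5), index=sorted(genes)
        )
        assert select_top_degs(table, 0.5) == ["A", "B"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_top_degs(pd.DataFrame())


class TestGeneScoreCorrelation:
    def test_exact_correlations(self):
        tumours = make_matrix(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 2.0, 3.0, 4.0], [5, 5, 5, 5]],
            genes=["same", "neg", "mixed", "flat"],
        )
        score = ScoreTable("Immune", pd.Series([1.0, 2.0, 3.0, 4.0], index=tumours.samples))
        out = correlate_genes_with_scores(tumours, ["same", "neg", "flat"], score)
        assert out.at["same", "r"] == pytest.approx(1.0)
        assert out.at["neg", "r"] == pytest.approx(-1.0)
        assert out.at["flat", "r"] == 0.0 and bool(out.at["flat", "degenerate"])

    def test_hand_pearson_four_points(self):
        tumours = make_matrix([[1.0, 2.0, 3.0, 4.0]], genes=["g"])
        score = ScoreTable("Immune", pd.Series([1.0, 3.0, 2.0, 4.0], index=tumours.samples))
        out = correlate_genes_with_scores(tumours, ["g"], score)
        assert out.at["g", "r"] == pytest.approx(0.8)

    def test_needs_three_tumours(self):
        tumours = make_matrix([[1.0, 2.0]])
        score = ScoreTable("Immune", pd.Series([1.0, 2.0], index=tumours.samples))
        with pytest.raises(ValueError):
            correlate_genes_with_scores(tumours, ["G0"], score)


class TestPartition:
    def test_immune_label(self):
        out = partition_degs(pd.Series({"g": 0.5}), pd.Series({"g": 0.1}))
        assert out.at["g", "label"] == "IMMUNE"

    def test_threshold_is_strict(self):
        out = partition_degs(pd.Series({"g": 0.4}), pd.Series({"g": 0.0}))
        assert out.at["g", "label"] == "NEITHER"

    def test_immune_precedence_on_double_hit(self):
        out = partition_degs(pd.Series({"g": 0.6}), pd.Series({"g": 0.6}))
        assert out.at["g", "label"] == "IMMUNE"

    def test_stromal_and_neither(self):
        out = partition_degs(
            pd.Series({"a": 0.1, "b": -0.2}), pd.Series({"a": 0.7, "b": 0.3})
        )
        assert out["label"].tolist() == ["STROMAL", "NEITHER"]


class TestImmuneDegValues:
    def test_tumour_at_cohort_mean_scores_zero(self):
        tumours = make_matrix([[1.0, 2.0, 3.0]], genes=["g"])
        values = immune_deg_values(tumours, ["g"])
        assert values.values.iloc[1] == pytest.approx(0.0)

    def test_sums_z_rows(self):
        tumours = make_matrix([[0.0, 2.0], [0.0, 2.0]], genes=["g1", "g2"])
        values = immune_deg_values(tumours, ["g1", "g2"])
        np.testing.assert_allclose(values.values, [-np.sqrt(2), np.sqrt(2)])

    def test_zero_sd_gene_contributes_zero(self):
        tumours = make_matrix([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]], genes=["flat", "g"])
        both = immune_deg_values(tumours, ["flat", "g"])
        alone = immune_deg_values(tumours, ["g"])
        np.testing.assert_allclose(both.values, alone.values)

    def test_values_sum_to_zero(self):
        rng = np.random.default_rng(2)
        tumours = make_matrix(rng.normal(size=(6, 9)))
        values = immune_deg_values(tumours, list(tumours.genes))
        assert abs(values.values.sum()) < 1e-9

    def test_z_rows_standardized(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 7))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)
        tumours = make_matrix(x)
        np.testing.assert_allclose(
            immune_deg_values(tumours, list(tumours.genes)).values, z.sum(axis=0), atol=1e-9
        )

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            immune_deg_values(make_matrix([[1.0, 2.0]]), [])


class TestSurvivalLogrank:
    def test_two_subject_hand_computation(self):
        # HIGH dies at t=1 (O-E = 1 - 0.5), LOW at t=2; variance 0.25 -> chi2 = 1
        values = ScoreTable("v", pd.Series({"A": 2.0, "B": 1.0}))
        survival = [SurvivalRecord("A", 1.0, True), SurvivalRecord("B", 2.0, True)]
        res = survival_logrank(values, survival)
        assert res.chi_square == pytest.approx(1.0)
        assert res.groups.to_dict() == {"A": "HIGH", "B": "LOW"}

    def test_identical_groups_are_null(self):
        values = ScoreTable("v", pd.Series({"A": 2.0, "B": 2.0, "C": 1.0, "D": 1.0}))
        survival = [
            SurvivalRecord("A", 5.0, True),
            SurvivalRecord("B", 9.0, False),
            SurvivalRecord("C", 5.0, True),
            SurvivalRecord("D", 9.0, False),
        ]
        res = survival_logrank(values, survival)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_censored_is_chi_square_zero(self):
        values = ScoreTable("v", pd.Series({"A": 2.0, "B": 1.0, "C": 0.0}))
        survival = [SurvivalRecord(s, 10.0, False) for s in "ABC"]
        res = survival_logrank(values, survival)
        assert res.chi_square == 0.0 and res.p_value == 1.0 and res.n_events == 0

    def test_median_ties_go_low(self):
        values = ScoreTable("v", pd.Series({"A": 1.0, "B": 2.0, "C": 2.0, "D": 3.0}))
        survival = [SurvivalRecord(s, 10.0, True) for s in "ABCD"]
        res = survival_logrank(values, survival)
        assert res.groups.to_dict() == {"A": "LOW", "B": "LOW", "C": "LOW", "D": "HIGH"}

    def test_horizon_censors_late_events(self):
        values = ScoreTable("v", pd.Series({"A": 2.0, "B": 1.0, "C": 3.0, "D": 0.0}))
        survival = [
            SurvivalRecord("A", 200.0, True),
            SurvivalRecord("B", 200.0, True),
            SurvivalRecord("C", 50.0, False),
            SurvivalRecord("D", 60.0, False),
        ]
        res = survival_logrank(values, survival, horizon=120.0)
        assert res.n_events == 0

    def test_restricts_to_shared_samples(self):
        values = ScoreTable("v", pd.Series({"A": 2.0, "B": 1.0, "Z": 99.0}))
        survival = [SurvivalRecord("A", 1.0, True), SurvivalRecord("B", 2.0, True)]
        res = survival_logrank(values, survival)
        assert set(res.groups.index) == {"A", "B"}
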