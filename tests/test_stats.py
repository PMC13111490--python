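import numpy as np
import pandas as pd
import pytest

from comanet import (
    control_aggregate,
    fisher_exact_2x2,
    kendall_tau,
    kruskal_wallis,
    run_group_analysis,
    wilcoxon_rank_sum,
)
from comanet.network import ParameterError
from comanet.stats import UndefinedStatistic, holm_adjust


def tidy(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "scan_index", "metric", "value"]
    )


class TestAggregate:
    def test_repeat_scans_averaged(self):
        t = tidy(
            [("c1", "Control", i, "clustering", v) for i, v in enumerate((0.2, 0.3, 0.4), 1)]
        )
        out = control_aggregate(t)
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(0.3)

    def test_single_scan_untouched(self):
        t = tidy([("p1", "No AR", 1, "degree", 12.5)])
        out = control_aggregate(t)
        assert out["value"].iloc[0] == 12.5

    def test_four_controls_three_scans_give_four_rows(self):
        rows = [
            (f"c{p}", "Control", s, "efficiency", 0.5 + 0.01 * p)
            for p in range(4)
            for s in (1, 2, 3)
        ]
        assert len(control_aggregate(tidy(rows))) == 4


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        res = kruskal_wallis([1, 2], [3, 4], [5, 6])
        assert res.statistic == pytest.approx(4.5714, abs=1e-4)
        assert res.df == 2

    def test_symmetric_ranks_not_significant(self):
        res = kruskal_wallis([1, 4], [2, 3])
        assert res.p_value > 0.5

    def test_df_tracks_group_count(self):
        assert kruskal_wallis([1, 2], [3, 4], [5, 6]).df == 2
        assert kruskal_wallis([1, 2], [3, 4], [5, 6], [7, 8]).df == 3

    def test_identical_values_undefined(self):
        with pytest.raises(UndefinedStatistic):
            kruskal_wallis([1.0, 1.0], [1.0, 1.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1, 7) for m in (0, 0.5, 1)]
        h1 = kruskal_wallis(*groups).statistic
        h2 = kruskal_wallis(*[np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)


class TestWilcoxon:
    def test_exact_enumeration(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], method="exact")
        assert res.p_value == pytest.approx(1 / 3)

    def test_approximate_with_continuity(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], method="approximate")
        assert res.p_value == pytest.approx(0.2453, abs=1e-4)

    def test_identical_single_values_give_p_one(self):
        res = wilcoxon_rank_sum([5.0], [5.0], method="approximate")
        assert res.p_value == pytest.approx(1.0)

    def test_rank_sum_statistic_reported(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4], method="approximate")
        assert res.statistic == 3.0  # ranks 1+2

    def test_exact_and_approximate_agree_within_008(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            m, n = rng.integers(3, 9, 2)
            x = rng.normal(0, 1, m)
            y = rng.normal(rng.uniform(-1, 1), 1, n)
            pe = wilcoxon_rank_sum(x, y, method="exact").p_value
            pa = wilcoxon_rank_sum(x, y, method="approximate").p_value
            assert abs(pe - pa) < 0.08

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([], [1.0])


class TestKendall:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)

    def test_tied_x_example(self):
        res = kendall_tau([1, 1, 2, 2], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-0.8165, abs=1e-4)

    def test_antisymmetry_under_reversed_coding(self):
        x = [0, 0, 1, 1, 2, 2]
        y = [5, 4, 6, 2, 1, 3]
        t1 = kendall_tau(x, y).statistic
        t2 = kendall_tau([2 - v for v in x], y).statistic
        assert t1 == pytest.approx(-t2)

    def test_all_tied_codes_undefined(self):
        with pytest.raises(UndefinedStatistic):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestFisher:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ([[2, 8], [6, 2]], 0.054),   # sex, male: AR 2/10 vs No AR 6/8
            ([[3, 7], [5, 3]], 0.34),    # primary cardiac aetiology
            ([[5, 5], [0, 8]], 0.036),   # research-only MRI
        ],
    )
    def test_reproduces_printed_cohort_pvalues(self, table, printed):
        res = fisher_exact_2x2(np.array(table))
        assert round(res.p_value, len(str(printed).split(".")[1])) == printed

    def test_transpose_invariance(self):
        t = np.array([[3, 7], [5, 3]])
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            fisher_exact_2x2(t.T).p_value
        )

    def test_zero_margin_degenerate(self):
        res = fisher_exact_2x2(np.array([[0, 0], [5, 8]]))
        assert res.p_value == 1.0
        assert res.extra["degenerate"]

    def test_rejects_bad_tables(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2(np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(ParameterError):
            fisher_exact_2x2(np.array([[-1, 2], [3, 4]]))


class TestGroupAnalysis:
    @staticmethod
    def cohort_table(groups, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n, shift in groups:
            for i in range(n):
                rows.append((f"{g}{i}", g, 1, "degree", rng.normal(10 - shift, 1)))
                rows.append((f"{g}{i}", g, 1, "efficiency", rng.normal(0.5 - 0.05 * shift, 0.02)))
        return tidy(rows)

    def test_short_design_counts(self):
        t = self.cohort_table([("Control", 4, 0), ("AR", 6, 1), ("No AR", 6, 2)])
        out = run_group_analysis(t, design="short")
        per_metric = out.groupby("metric").size()
        assert (per_metric == 5).all()  # omnibus + 3 pairs + trend

    def test_long_design_counts_and_pooling(self):
        t = self.cohort_table(
            [("Control", 4, 0), ("EMCS", 3, 1), ("AR'", 5, 2), ("No AR", 6, 3)]
        )
        out = run_group_analysis(t, design="long")
        assert (out.groupby("metric").size() == 8).all()  # omnibus + 6 pairs + trend
        short = run_group_analysis(t, design="short")  # EMCS + AR' pool into AR
        assert (short.groupby("metric").size() == 5).all()

    def test_severity_gradient_yields_negative_trend(self):
        t = self.cohort_table(
            [("Control", 6, 0), ("EMCS", 6, 2), ("AR'", 6, 4), ("No AR", 6, 6)], seed=3
        )
        out = run_group_analysis(t, design="long")
        trends = out[out["comparison"] == "ordered trend"]
        assert (trends["statistic"] < 0).all()
        assert (trends["p"] < 0.05).all()

    def test_missing_group_is_design_error(self):
        t = self.cohort_table([("Control", 4, 0), ("No AR", 6, 2)])
        with pytest.raises(ParameterError):
            run_group_analysis(t, design="short")

    def test_holm_flag_adds_adjusted_column(self):
        t = self.cohort_table([("Control", 4, 0), ("AR", 6, 1), ("No AR", 6, 2)])
        out = run_group_analysis(t, design="short", holm=True)
        wil = out[out["method"].str.startswith("wilcoxon")]
        assert (wil["p_holm"] >= wil["p"] - 1e-12).all()


def test_holm_adjustment_properties():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = holm_adjust(p)
    assert (adj >= p).all() and (adj <= 1).all()
    assert adj[np.argsort(p)][0] == pytest.approx(0.04)  # 4 * 0.01


def test_type_one_error_rate_controlled():
    # null simulations: all groups from one distribution; rejection rate at
    # alpha = 0.05 should sit near the nominal level
    rng = np.random.default_rng(2024)
    rejections = 0
    n_sim = 500
    for _ in range(n_sim):
        groups = [rng.normal(0, 1, 8) for _ in range(3)]
        if kruskal_wallis(*groups).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07
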