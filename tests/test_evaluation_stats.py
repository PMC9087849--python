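import math

import numpy as np
import pytest
from scipy import stats

from bollcount import evaluation_stats as es
from bollcount.types import GroundTruthRecord, ValidationError


def records(counts, genotypes=None):
    genotypes = genotypes or ["G"] * len(counts)
    return [
        GroundTruthRecord(f"p{i}", g, int(c))
        for i, (c, g) in enumerate(zip(counts, genotypes))
    ]


class TestRegressCounts:
    def test_identity_prediction(self):
        truth = records([100, 200, 300, 150])
        pred = {r.plot_id: r.boll_count for r in truth}
        rep = es.regress_counts(pred, truth)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.nrmse == pytest.approx(0.0)
        assert rep.mape_pct == pytest.approx(0.0)
        assert rep.outlier_ids == []

    def test_hand_evaluated_errors(self):
        truth = records([100, 200, 300])
        pred = {"p0": 110, "p1": 180, "p2": 330}
        rep = es.regress_counts(pred, truth)
        assert rep.mape_pct == pytest.approx(10.0)
        assert rep.nrmse == pytest.approx(math.sqrt((100 + 400 + 900) / 3) / 200)
        assert rep.mean_gt == pytest.approx(200.0)

    def test_ols_residuals_mean_zero(self, rng):
        truth = records(rng.integers(50, 400, 30))
        pred = {
            r.plot_id: r.boll_count * 0.9 + rng.normal(0, 10) for r in truth
        }
        rep = es.regress_counts(pred, truth)
        assert abs(rep.residuals.mean()) < 1e-9

    def test_nrmse_times_range_is_rmse(self, rng):
        truth = records(rng.integers(10, 300, 20))
        pred = {r.plot_id: r.boll_count + rng.normal(0, 5) for r in truth}
        rep = es.regress_counts(pred, truth)
        y = np.array([r.boll_count for r in truth], float)
        yhat = np.array([pred[r.plot_id] for r in truth])
        rmse = np.sqrt(np.mean((y - yhat) ** 2))
        assert rep.nrmse * (y.max() - y.min()) == pytest.approx(rmse, abs=1e-12)

    def test_constant_truth_gives_undefined_nrmse(self):
        truth = records([50, 50, 50])
        rep = es.regress_counts({r.plot_id: 40 for r in truth}, truth)
        assert math.isnan(rep.nrmse)

    def test_zero_truth_gives_undefined_mape(self):
        truth = records([0, 10, 20])
        rep = es.regress_counts({r.plot_id: r.boll_count for r in truth}, truth)
        assert math.isnan(rep.mape_pct)

    def test_unmatched_plot_rejected(self):
        truth = records([1, 2, 3])
        with pytest.raises(ValidationError):
            es.regress_counts({"p0": 1, "p1": 2}, truth)

    def test_outlier_rule_flags_three_sigma_fraction(self):
        # standard-normal OLS residuals: expect ~0.27% beyond 3 SD
        rng = np.random.default_rng(42)
        n = 10_000
        y = rng.uniform(1, 1000, n)
        truth = records(np.round(y).astype(int))
        pred = {r.plot_id: r.boll_count + rng.standard_normal() for r in truth}
        rep = es.regress_counts(pred, truth)
        frac = len(rep.outlier_ids) / n
        assert abs(frac - 0.0027) < 0.002

    def test_injected_outlier_flagged_and_kept(self, rng):
        counts = rng.integers(100, 300, 30)
        truth = records(counts)
        pred = {r.plot_id: float(r.boll_count) + rng.normal(0, 2) for r in truth}
        pred["p0"] = float(truth[0].boll_count) + 100.0
        rep = es.regress_counts(pred, truth)
        assert "p0" in rep.outlier_ids
        assert rep.n == 30  # outlier kept in the reported fit
        refit = es.regress_counts(pred, truth, refit_without_outliers=True)
        assert refit.r_squared >= rep.r_squared


class TestAnova:
    def test_hand_computed_two_groups(self):
        F, dfb, dfw, p = es.anova_oneway({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert (F, dfb, dfw) == (pytest.approx(13.5), 1, 4)
        assert 0 < p < 0.05

    def test_identical_groups_give_zero_f(self):
        F, _, _, p = es.anova_oneway({"A": [5, 5, 5], "B": [5, 5, 5]})
        assert F == 0.0 and p == 1.0

    def test_trial_scale_degrees_of_freedom(self, rng):
        sizes = [10, 10, 10, 10, 16, 20, 10, 40, 184, 22, 8, 44, 10, 44, 18, 32]
        assert sum(sizes) == 488
        groups = {
            f"g{i}": rng.normal(200, 30, n).tolist() for i, n in enumerate(sizes)
        }
        _, dfb, dfw, _ = es.anova_oneway(groups)
        assert (dfb, dfw) == (15, 472)

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(50):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 5), 1, rng.integers(3, 12))
                for i in range(rng.integers(2, 6))
            }
            F, _, _, p = es.anova_oneway(groups)
            ref = stats.f_oneway(*groups.values())
            assert F == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_two_group_f_equals_t_squared(self, rng):
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 15))
            b = rng.normal(rng.uniform(0, 2), 1, rng.integers(3, 15))
            F, _, _, _ = es.anova_oneway({"a": a, "b": b})
            t = stats.ttest_ind(a, b).statistic
            assert F == pytest.approx(t**2, abs=1e-8)


class TestLsdLetters:
    def test_equal_means_share_one_letter(self):
        letters = es.lsd_letters({"A": [5, 5, 6], "B": [5, 6, 5], "C": [6, 5, 5]})
        assert set(letters.values()) == {"a"}

    def test_far_separated_groups_get_distinct_letters(self):
        letters = es.lsd_letters({"lo": [0, 0, 0, 0], "hi": [100, 100, 100, 100]})
        assert letters["hi"] == "a" and letters["lo"] == "b"

    def test_overlapping_middle_carries_both_letters(self):
        # n=2 per group, MSW=8, df_w=3 -> LSD = t(.975,3)*sqrt(8*(1/2+1/2)) ~ 9.0
        groups = {"top": [12, 8], "mid": [7, 3], "low": [2, -2]}
        letters = es.lsd_letters(groups)
        assert letters == {"top": "a", "mid": "ab", "low": "b"}

    def test_single_group(self):
        assert es.lsd_letters({"only": [1, 2, 3]}) == {"only": "a"}

    def test_shared_letter_implies_nonsignificant_pair(self, rng):
        for _ in range(30):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 6), 1, rng.integers(3, 8))
                for i in range(rng.integers(3, 7))
            }
            letters = es.lsd_letters(groups)
            _, _, dfw, _ = es.anova_oneway(groups)
            msw = sum(
                ((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()
            ) / dfw
            tcrit = stats.t.ppf(0.975, dfw)
            names = list(groups)
            for i, gi in enumerate(names):
                for gj in names[i + 1 :]:
                    if set(letters[gi]) & set(letters[gj]):
                        lsd = tcrit * math.sqrt(
                            msw * (1 / len(groups[gi]) + 1 / len(groups[gj]))
                        )
                        diff = abs(
                            np.mean(groups[gi]) - np.mean(groups[gj])
                        )
                        assert diff <= lsd + 1e-12


class TestGenotypeSummary:
    def test_mean_and_se(self):
        truth = records([10, 20], ["A", "A"]) + records([5, 5, 5], ["B", "B", "B"])
        # fix ids to be unique across the two calls
        truth = [
            GroundTruthRecord(f"p{i}", r.genotype, r.boll_count)
            for i, r in enumerate(truth)
        ]
        counts = {r.plot_id: float(r.boll_count) for r in truth}
        summ = es.genotype_summary(counts, truth)
        row = summ.table.set_index("genotype").loc["A"]
        assert row["mean"] == pytest.approx(15.0)
        assert row["se"] == pytest.approx(5.0)
        rowb = summ.table.set_index("genotype").loc["B"]
        assert rowb["se"] == pytest.approx(0.0)

    def test_singleton_genotype_excluded_from_letters(self, rng):
        truth = records(
            [10, 12, 30, 31, 99], ["A", "A", "B", "B", "solo"]
        )
        counts = {r.plot_id: float(r.boll_count) for r in truth}
        summ = es.genotype_summary(counts, truth)
        tab = summ.table.set_index("genotype")
        assert math.isnan(tab.loc["solo", "se"])
        assert tab.loc["solo", "letters"] == ""
        assert tab.loc["A", "letters"] != ""

    def test_anova_embedded(self, rng):
        truth = records(
            list(rng.integers(100, 200, 12)), [f"G{i % 3}" for i in range(12)]
        )
        counts = {r.plot_id: float(r.boll_count) for r in truth}
        summ = es.genotype_summary(counts, truth)
        assert summ.df_between == 2 and summ.df_within == 9
        assert 0 <= summ.p_value <= 1
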