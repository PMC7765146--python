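"""Empathy-scale scoring and the survey statistical battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meowdecode import (
    CohortSpec,
    accuracy_table,
    analyze,
    chance_test,
    chisq_2x2,
    cohort_frames,
    cronbach_alpha,
    mann_whitney,
    score_aes,
    score_ces,
    spearman,
    synth_cohort,
)
from meowdecode.datasets import ASSIGNMENT_COUNTS, ATTRIBUTE_COUNTS
from meowdecode.survey import (
    CONTEXTS,
    DEFAULT_AES_POLARITY,
    MeowResponse,
    ResponseRecord,
    n_correct_medioids,
    reverse_item,
)


def _aes_raw(empathic_value, unempathic_value):
    return [empathic_value if p == "empathic" else unempathic_value
            for p in DEFAULT_AES_POLARITY]


class TestScaleScoring:
    def test_aes_maximum(self):
        # full agreement with empathic items, none with unempathic ones
        assert score_aes(_aes_raw(9, 1)) == 198

    def test_aes_minimum(self):
        assert score_aes(_aes_raw(1, 9)) == 22

    def test_aes_neutral_fixed_point(self):
        assert score_aes([5] * 22) == 110

    def test_unempathic_agreement_scores_low(self):
        items = _aes_raw(9, 1)
        idx = DEFAULT_AES_POLARITY.index("unempathic")
        items[idx] = 9  # strong agreement with an unempathic statement
        assert score_aes(items) == 198 - 8  # contributes 1 instead of 9

    def test_ces_bounds_and_neutral(self):
        assert score_ces([9, 9, 9]) == 27
        assert score_ces([1, 1, 1]) == 3
        assert score_ces([5, 5, 5]) == 15

    def test_out_of_range_items_rejected(self):
        with pytest.raises(ValueError):
            score_aes([0] + [5] * 21)
        with pytest.raises(ValueError):
            score_ces([5, 5, 10])
        with pytest.raises(ValueError):
            score_ces([5, 5])

    @given(st.integers(min_value=1, max_value=9))
    def test_reversal_is_involution(self, x):
        assert reverse_item(reverse_item(x)) == x
        assert 1 <= reverse_item(x) <= 9

    def test_medioid_correct_count_ignores_outliers(self):
        responses = []
        for ctx in CONTEXTS:
            responses.append(MeowResponse(ctx, "medioid", ctx, "positive",
                                          {}))  # correct
            responses.append(MeowResponse(ctx, "outlier", "isolation"
                                          if ctx != "isolation" else "brushing",
                                          "negative", {}))  # wrong
        rec = ResponseRecord("p0", "female", False, True, True,
                             [5] * 22, [5] * 3, responses)
        assert n_correct_medioids(rec) == 3


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.arange(10, dtype=float)
        m = np.column_stack([x, x, x])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        m = rng.normal(size=(2000, 22))
        assert abs(cronbach_alpha(m)) < 0.1

    def test_two_item_closed_form(self, rng):
        # population covariance [[1, .5], [.5, 1]]:
        # alpha = 2 * (1 - 2/3) = 2/3
        cov = [[1.0, 0.5], [0.5, 1.0]]
        m = rng.multivariate_normal([0, 0], cov, size=60000)
        assert cronbach_alpha(m) == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_matches_reference_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        m = rng.integers(1, 10, size=(50, 8)).astype(float)
        ours = cronbach_alpha(m)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((2, 5)))


def _responses_from_counts(context, variant, correct, incorrect):
    """Build a responses frame realizing given correct/incorrect counts."""
    wrong = [c for c in CONTEXTS if c != context][0]
    rows = []
    for i in range(correct + incorrect):
        rows.append({
            "participant_id": f"p{i:04d}",
            "true_context": context,
            "variant": variant,
            "chosen_context": context if i < correct else wrong,
            "valence": "positive",
        })
    return pd.DataFrame(rows)


class TestAccuracyTable:
    @pytest.mark.parametrize("context,variant,expected_pct", [
        ("waiting_for_food", "medioid", 40.44),
        ("waiting_for_food", "outlier", 27.11),
        ("isolation", "medioid", 26.67),
        ("isolation", "outlier", 14.22),
        ("brushing", "medioid", 32.89),
        ("brushing", "outlier", 13.33),
    ])
    def test_published_counts_reproduce_percentages(self, context, variant,
                                                    expected_pct):
        corr, incorr = ASSIGNMENT_COUNTS[context][variant]
        df = _responses_from_counts(context, variant, corr, incorr)
        table = accuracy_table(df, context, variant)
        assert table.loc[0, "pct_correct"] == pytest.approx(expected_pct,
                                                            abs=0.005)

    def test_all_correct_cohort(self):
        acc = {(g, c): 1.0 for g in ("owner", "nonowner") for c in CONTEXTS}
        cohort = synth_cohort(CohortSpec(n_participants=15, seed=0,
                                         accuracy_by_group_context=acc,
                                         outlier_accuracy_factor=1.0))
        _, responses = cohort_frames(cohort)
        t = accuracy_table(responses, "brushing", "medioid")
        assert t.loc[0, "pct_correct"] == 100.00

    def test_percentages_sum_to_100(self, planted_cohort):
        _, _, participants, responses = planted_cohort
        for ctx in CONTEXTS:
            for variant in ("medioid", "outlier"):
                t = accuracy_table(responses, ctx, variant, grouping="gender",
                                   participants=participants)
                for _, row in t.iterrows():
                    assert row["pct_correct"] + row["pct_incorrect"] == \
                        pytest.approx(100.0, abs=0.02)


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chisq_2x2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_food_medioid_vs_outlier(self):
        # expected counts 76/149 per row under independence
        res = chisq_2x2([[91, 134], [61, 164]])
        np.testing.assert_allclose(res.expected[0], [76, 149])
        assert res.chi2 == pytest.approx(8.94, abs=0.05)
        assert res.p < 0.01
        assert chisq_2x2([[91, 134], [61, 164]], correction=True).p < 0.01

    def test_brushing_medioid_vs_outlier_robust_to_correction(self):
        for correction in (False, True):
            res = chisq_2x2([[74, 151], [30, 195]], correction=correction)
            assert res.p < 0.001

    def test_brute_force_oracle_equivalence(self, rng):
        for _ in range(200):
            obs = rng.integers(1, 60, size=(2, 2)).astype(float)
            res = chisq_2x2(obs)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            chi2 = np.sum((obs - expected) ** 2 / expected)
            assert res.chi2 == pytest.approx(chi2, rel=1e-12)
            assert res.df == 1

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 5]])

    def test_cohort_power_with_ownership_gap(self):
        # owners 20 points more accurate: the owner-vs-nonowner chi-square
        # should reject at 0.05 in at least 80 percent of runs at n=225
        acc = {("owner", c): 0.5 for c in CONTEXTS}
        acc.update({("nonowner", c): 0.3 for c in CONTEXTS})
        rejections = 0
        n_runs = 100
        for seed in range(n_runs):
            cohort = synth_cohort(CohortSpec(
                n_participants=225, seed=seed,
                accuracy_by_group_context=acc))
            participants, responses = cohort_frames(cohort)
            t = accuracy_table(responses, "isolation", "medioid",
                               grouping="cat_owner", participants=participants)
            res = chisq_2x2(t[["correct", "incorrect"]].to_numpy())
            rejections += res.p < 0.05
        assert rejections / n_runs >= 0.8

    def test_cohort_null_rejection_rate(self):
        # no ownership gap: rejection rate compatible with the 5% level
        acc = {(g, c): 0.35 for g in ("owner", "nonowner") for c in CONTEXTS}
        rejections = 0
        n_runs = 200
        for seed in range(n_runs):
            cohort = synth_cohort(CohortSpec(
                n_participants=225, seed=1000 + seed,
                accuracy_by_group_context=acc))
            participants, responses = cohort_frames(cohort)
            t = accuracy_table(responses, "isolation", "medioid",
                               grouping="cat_owner", participants=participants)
            res = chisq_2x2(t[["correct", "incorrect"]].to_numpy())
            rejections += res.p < 0.05
        rate = rejections / n_runs
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert abs(rate - 0.05) < 3 * se


class TestChanceTest:
    def test_observation_at_expectation(self):
        res = chance_test(75, 225)
        assert res.p_greater > 0.5

    def test_perfect_score_boundary(self):
        res = chance_test(225, 225)
        assert res.p_greater == pytest.approx((1 / 3) ** 225, rel=1e-9)

    def test_91_of_225_above_chance(self):
        # the best-recognized context: 91/225 is nominally above 1/3
        res = chance_test(91, 225)
        assert res.p_greater == pytest.approx(0.016, abs=0.003)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            chance_test(10, 5)


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        u, p, method = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups(self):
        u, p, method = mann_whitney([1, 2, 3, 4] * 10, [1, 2, 3, 4] * 10)
        assert p > 0.9

    def test_shift_decreases_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        ps = [mann_whitney(a, b + shift)[1] for shift in (0.5, 2.0, 5.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestSpearman:
    def test_perfectly_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_antisymmetry(self):
        rho, _ = spearman([5, 4, 3, 2, 1], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_computation(self):
        # ranks differ by d = (0, 1, -1, 1, -1); sum d^2 = 4
        # rho = 1 - 6*4 / (5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestAttributeTables:
    @pytest.mark.parametrize("context,attr,bound", [
        ("isolation", "gender", 0.05),
        ("isolation", "cat_owner", 0.01),
        ("brushing", "cat_owner", 0.001),
    ])
    def test_published_attribute_effects(self, context, attr, bound):
        # cells whose significance bound holds under both chi-square
        # conventions (with and without continuity correction)
        rows = ATTRIBUTE_COUNTS[context][attr]
        table = [[r[1], r[2]] for r in rows]
        for correction in (False, True):
            assert chisq_2x2(table, correction=correction).p < bound

    def test_brushing_gender_effect_uncorrected(self):
        rows = ATTRIBUTE_COUNTS["brushing"]["gender"]
        table = [[r[1], r[2]] for r in rows]
        assert chisq_2x2(table).p < 0.05

    @pytest.mark.parametrize("context,attr", [
        ("waiting_for_food", "gender"),
        ("waiting_for_food", "parent"),
        ("isolation", "grew_up_with_cats"),
    ])
    def test_published_nonsignificant_effects(self, context, attr):
        rows = ATTRIBUTE_COUNTS[context][attr]
        table = [[r[1], r[2]] for r in rows]
        assert chisq_2x2(table).p > 0.05


class TestAnalyzeBattery:
    def test_full_report_structure(self, planted_cohort):
        _, _, participants, responses = planted_cohort
        report = analyze(participants, responses)
        assert set(report["contexts"]) == set(CONTEXTS)
        for ctx in CONTEXTS:
            d = report["contexts"][ctx]
            assert d["medioid"]["pct_correct"] + d["medioid"]["pct_incorrect"] \
                == pytest.approx(100.0, abs=0.02)
            assert 0 <= d["medioid_vs_outlier"]["p"] <= 1
        assert 0 < report["cronbach_alpha_aes"] <= 1
        assert "aes_vs_ces" in report["correlations"]

    def test_planted_group_structure_recovered(self, planted_cohort):
        _, _, participants, responses = planted_cohort
        report = analyze(participants, responses)
        # owners are generated both more accurate and more empathic
        aes = report["empathy"]["aes_total"]["cat_owner"]
        assert aes["mean_a"] > aes["mean_b"]  # owners above nonowners
        ces = report["empathy"]["ces_total"]["cat_owner"]
        assert ces["p"] < 0.01
        # the shared latent trait makes AES and CES correlate positively
        assert report["correlations"]["aes_vs_ces"]["rho"] > 0.2
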