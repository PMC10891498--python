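"""Statistical conventions, checked against independent oracles.

The package authors its own Wilcoxon / McNemar / Spearman implementations
(fixing the exact conventions used in the analysis); scipy and brute-force
enumeration serve as independent oracles here.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dietvalid.records_io import Education, Gender, IdentificationMode, Participant
from dietvalid.validity_stats import (
    Direction,
    bland_altman,
    compare_tables,
    intakes_to_frame,
    mcnemar,
    median_of_correlations,
    recording_mode_tally,
    relevance_flag,
    spearman_rho,
    sus_score,
    sus_summary,
    wilcoxon_signed_rank,
)


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Brute-force two-sided signed-rank p by enumerating all 2^n sign
    assignments (average ranks of |d|, zeros already removed)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mu)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= stat_obs - 1e-12:
            count += 1
    return count / 2.0**n


class TestWilcoxon:
    def test_agrees_with_scipy_normal_approximation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            d = rng.normal(0.2, 1.0, size=rng.integers(12, 60))
            ours = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(
                d, zero_method="wilcox", correction=False, method="approx"
            ).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_tied_differences_agree_with_scipy(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 2.0, -3.0, 4.0, 4.0, -4.0, 5.0])
        ref = scipy.stats.wilcoxon(
            d, zero_method="wilcox", correction=False, method="approx"
        ).pvalue
        assert wilcoxon_signed_rank(d) == pytest.approx(ref, abs=1e-10)

    def test_close_to_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(30):
            d = rng.normal(0.3, 1.0, size=rng.integers(8, 11))
            err = abs(wilcoxon_signed_rank(d) - exact_wilcoxon_p(d))
            worst = max(worst, err)
        # documented tolerance of the normal approximation at n = 8..10
        assert worst < 0.1

    def test_all_positive_differences_are_highly_significant(self):
        d = np.arange(1.0, 21.0)
        assert wilcoxon_signed_rank(d) < 0.001

    def test_sign_flip_symmetry(self):
        d = np.array([1.5, -0.3, 2.0, 4.0, -1.0, 0.7, 3.3])
        assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_signed_rank(-d))

    def test_all_zero_differences_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_pratt_zero_method_matches_scipy(self):
        d = np.array([0.0, 0.0, 1.0, -2.0, 3.0, 4.0, 5.0, -1.5, 2.5])
        ref = scipy.stats.wilcoxon(
            d, zero_method="pratt", correction=False, method="approx"
        ).pvalue
        ours = wilcoxon_signed_rank(d, zero_method="pratt")
        assert ours == pytest.approx(ref, abs=1e-10)


class TestMcNemar:
    def test_chi_squared_branch_hand_value(self):
        # b = 10, c = 2 discordant pairs: chi2 = (10-2)^2/12 = 16/3
        a = [True] * 10 + [False] * 2 + [True] * 5
        b = [False] * 10 + [True] * 2 + [True] * 5
        expected = scipy.stats.chi2.sf(16 / 3, df=1)
        assert mcnemar(a, b) == pytest.approx(expected)
        assert mcnemar(a, b) == pytest.approx(0.0209, abs=5e-4)

    def test_exact_branch_for_few_discordant_pairs(self):
        # b = 1, c = 0: exact two-sided binomial p = 1.0
        a = [True, True, False]
        b = [False, True, False]
        assert mcnemar(a, b) == pytest.approx(1.0)

    def test_exact_branch_matches_binomial_oracle(self):
        # b = 6, c = 1 -> binomtest(6, 7, 0.5) two-sided
        a = [True] * 6 + [False] * 1 + [True] * 4
        b = [False] * 6 + [True] * 1 + [True] * 4
        ref = scipy.stats.binomtest(6, 7, 0.5).pvalue
        assert mcnemar(a, b) == pytest.approx(ref)

    def test_symmetry_in_methods(self):
        rng = np.random.default_rng(3)
        a = rng.random(40) < 0.6
        b = rng.random(40) < 0.5
        assert mcnemar(a, b) == pytest.approx(mcnemar(b, a))

    def test_no_discordant_pairs_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert mcnemar([True, False], [True, False]) == 1.0

    def test_continuity_correction_option(self):
        a = [True] * 10 + [False] * 2
        b = [False] * 10 + [True] * 2
        expected = scipy.stats.chi2.sf((abs(10 - 2) - 1) ** 2 / 12, df=1)
        assert mcnemar(a, b, correction=True) == pytest.approx(expected)


class TestSpearman:
    def test_hand_computed_tied_fixture(self):
        # ranks of y = [10,20,20,30,40,50] are [1, 2.5, 2.5, 4, 5, 6];
        # Pearson of ranks = 17 / sqrt(297.5) (hand computation)
        x = [1, 2, 3, 4, 5, 6]
        y = [10, 20, 20, 30, 40, 50]
        assert spearman_rho(x, y) == pytest.approx(17 / np.sqrt(297.5), abs=1e-12)

    def test_agrees_with_scipy_under_heavy_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 4, size=30).astype(float)  # many ties + zeros
            y = x * 0.8 + rng.normal(0, 1, size=30)
            assert spearman_rho(x, y) == pytest.approx(
                scipy.stats.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_perfect_monotone_association_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_median_of_correlations(self):
        assert median_of_correlations([0.9, 0.1, 0.5]) == 0.5
        assert median_of_correlations([0.2, 0.4]) == pytest.approx(0.3)


class TestBlandAltman:
    def test_hand_fixture(self):
        # differences are exactly [-1, 0, 1]: mean 0, sd 1, LoA = ±1.96
        res = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert res.mean_difference == pytest.approx(0.0)
        assert res.sd_difference == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        assert res.n == 3

    def test_sd_uses_sample_denominator(self):
        x = np.array([3.0, 5.0, 9.0, 13.0])
        y = np.zeros(4)
        res = bland_altman(x, y)
        assert res.sd_difference == pytest.approx(np.std(x, ddof=1))

    def test_translation_invariance_of_interval_width(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = bland_altman(x, y)
        shifted = bland_altman(x + 100.0, y)
        assert shifted.loa_high - shifted.loa_low == pytest.approx(
            base.loa_high - base.loa_low
        )
        assert shifted.mean_difference == pytest.approx(base.mean_difference + 100.0)


class TestRelevanceRule:
    def test_significant_and_large_difference_is_relevant(self):
        flag = relevance_flag(median_a=83.0, median_b=129.0, p=0.001)
        assert flag.relevant is True
        assert flag.direction is Direction.METHOD_A_LOWER

    def test_significant_but_small_difference_is_not_relevant(self):
        flag = relevance_flag(median_a=105.0, median_b=100.0, p=0.001)
        assert flag.relevant is False

    def test_large_but_nonsignificant_difference_is_not_relevant(self):
        flag = relevance_flag(median_a=50.0, median_b=100.0, p=0.20)
        assert flag.relevant is False
        # direction is descriptive and reported regardless of relevance
        assert flag.direction is Direction.METHOD_A_LOWER
        assert relevance_flag(100.0, 100.0, 0.5).direction is Direction.NONE

    def test_threshold_is_strict(self):
        # exactly 10% of the reference median does not flag
        flag = relevance_flag(median_a=110.0, median_b=100.0, p=0.001)
        assert flag.relevant is False

    def test_zero_reference_median_is_not_evaluable(self):
        flag = relevance_flag(median_a=5.0, median_b=0.0, p=0.001)
        assert flag.relevant is None


def _cohort(n):
    return [
        Participant(
            f"P{i:03d}",
            Gender.MAN if i % 2 else Gender.WOMAN,
            30 + i % 20,
            1.70,
            60.0 + (i % 3) * 15,  # spreads BMI over all 3 classes
            list(Education)[i % 3],
        )
        for i in range(n)
    ]


def _frames(n=30, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"P{i:03d}" for i in range(n)]
    cols = ["Fruit", "Bread", "energy_kcal"]
    a = pd.DataFrame(rng.gamma(2.0, 50.0, (n, 3)), index=ids, columns=cols)
    b = a * rng.lognormal(0.1, 0.2, (n, 3))
    return a, b


class TestCompareTables:
    def test_identical_methods_show_no_relevant_differences(self):
        a, _ = _frames()
        report = compare_tables(a, a.copy(), ["Fruit", "Bread"], ["energy_kcal"])
        assert (report.paired["wilcoxon_p"] == 1.0).all()
        assert not report.paired["relevant"].any()
        assert np.allclose(report.paired["spearman_rho"], 1.0)

    def test_output_invariant_to_participant_order(self):
        a, b = _frames()
        report1 = compare_tables(a, b, ["Fruit", "Bread"], ["energy_kcal"])
        shuffled = a.sample(frac=1.0, random_state=1)
        report2 = compare_tables(shuffled, b, ["Fruit", "Bread"], ["energy_kcal"])
        pd.testing.assert_frame_equal(report1.paired, report2.paired)

    def test_mismatched_participants_are_fatal(self):
        a, b = _frames()
        with pytest.raises(ValueError, match="different participants"):
            compare_tables(a.iloc[:-1], b, ["Fruit"])

    def test_rare_group_left_out_of_main_table_but_kept_in_consumer_table(self):
        a, b = _frames()
        a["Nuts"] = 0.0
        b["Nuts"] = 0.0
        b.loc[b.index[0], "Nuts"] = 30.0  # one consumer -> 75th pct still 0
        report = compare_tables(a, b, ["Fruit", "Bread", "Nuts"])
        assert "Nuts" not in set(report.paired["variable"])
        assert "Nuts" in set(report.consumers["variable"])

    def test_stratified_output_covers_observed_classes(self):
        a, b = _frames()
        report = compare_tables(
            a,
            b,
            ["Fruit", "Bread"],
            ["energy_kcal"],
            participants=_cohort(30),
            strata=("education", "bmi"),
        )
        assert set(report.stratified) == {"education", "bmi"}
        assert set(report.stratified["education"]) == {"low", "middle", "high"}
        for table in report.stratified["education"].values():
            assert list(table["variable"]) == ["Fruit", "Bread", "energy_kcal"]

    def test_tiny_stratum_is_suppressed_with_warning(self):
        a, b = _frames(n=4)
        cohort = _cohort(4)
        # make exactly one participant 'low': a stratum of size 1
        cohort = [
            Participant(p.participant_id, p.gender, p.age_years, p.height_m,
                        p.weight_kg, Education.LOW if i == 0 else Education.HIGH)
            for i, p in enumerate(cohort)
        ]
        with pytest.warns(UserWarning, match="suppressed"):
            report = compare_tables(
                a, b, ["Fruit"], participants=cohort, strata=("education",)
            )
        assert set(report.stratified["education"]) == {"high"}


class TestModeTallyAndSus:
    COUNTS = {
        IdentificationMode.GENERIC_SEARCH: 211,
        IdentificationMode.PREVIOUSLY_SELECTED: 175,
        IdentificationMode.BRANDED_SEARCH: 169,
        IdentificationMode.BARCODE_SCAN: 114,
        IdentificationMode.RECIPE: 16,
        IdentificationMode.ASSOCIATED_ITEM: 147,
        IdentificationMode.SUPPLEMENT_ENTRY: 62,
    }

    def test_barcode_share_of_all_entries(self):
        tally = recording_mode_tally(self.COUNTS)
        assert tally.total == 894
        assert tally.share(IdentificationMode.BARCODE_SCAN) == pytest.approx(114 / 894)

    def test_branded_share_excluding_previously_selected(self):
        tally = recording_mode_tally(self.COUNTS)
        assert tally.branded_share_excluding_previous == pytest.approx(283 / 719)

    def test_shares_sum_to_one(self):
        tally = recording_mode_tally(self.COUNTS)
        assert sum(tally.share(m) for m in self.COUNTS) == pytest.approx(1.0)

    def test_sus_extremes_and_midpoint(self):
        best = [5, 1] * 5  # odd items 5, even items 1
        worst = [1, 5] * 5
        neutral = [3] * 10
        assert sus_score(best) == 100.0
        assert sus_score(worst) == 0.0
        assert sus_score(neutral) == 50.0

    def test_sus_hand_fixture(self):
        responses = [4, 2, 4, 1, 5, 2, 4, 2, 4, 1]
        # odd contributions: 3+3+4+3+3 = 16; even: 3+4+3+3+4 = 17 -> 33*2.5
        assert sus_score(responses) == pytest.approx(82.5)

    def test_missing_item_gives_none_but_summary_keeps_item_means(self):
        complete = [3] * 10
        partial = [5] + [None] * 9
        assert sus_score(partial) is None
        summary = sus_summary([complete, partial])
        assert summary.n_respondents == 2 and summary.n_complete == 1
        assert summary.mean_score == 50.0
        assert summary.item_means[0] == pytest.approx(4.0)  # mean of 3 and 5


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    d=st.lists(
        st.floats(min_value=-1e3, max_value=1e3, allow_nan=False).filter(
            lambda v: v != 0
        ),
        min_size=5,
        max_size=40,
    )
)
def test_wilcoxon_p_is_a_probability_and_sign_symmetric(d):
    arr = np.asarray(d)
    p = wilcoxon_signed_rank(arr)
    assert 0.0 <= p <= 1.0
    assert wilcoxon_signed_rank(-arr) == pytest.approx(p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=3,
        max_size=25,
        unique=True,
    )
)
def test_spearman_is_bounded_and_monotone_invariant(x):
    arr = np.asarray(x)
    y = np.cbrt(arr) + arr  # strictly increasing transform
    rho = spearman_rho(arr, y)
    assert rho == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    noisy = spearman_rho(arr, rng.permutation(arr))
    assert -1.0 <= noisy <= 1.0
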