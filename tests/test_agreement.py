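"""Percent agreement, Gwet's AC1, interpretation bands, Wilcoxon test.

``brute_force_ac1`` re-evaluates the pa / pi / pe definitions directly from
the rating cells (loops, no shared code with the implementation) and is the
oracle for the fast path.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirads_cde import (
    RatingMatrix,
    gwet_ac1,
    interpret_band,
    intra_rater_agreement,
    jackknife_variance,
    pairwise_mean_agreement,
    percent_agreement,
    wilcoxon_signed_rank,
)
from pirads_cde.errors import (
    AlignmentError,
    DegenerateDataError,
    InsufficientDataError,
)


def brute_force_ac1(cells, categories):
    """Direct evaluation of the pa/pi/pe formulas from a list of subject rows.

    ``cells``: list of lists of category labels (None = missing).
    """
    rows = [[v for v in row if v is not None] for row in cells]
    rows = [r for r in rows if len(r) >= 1]
    n = len(rows)
    q = len(categories)
    # observed agreement over subjects with >= 2 ratings
    pa_terms = []
    for r in rows:
        if len(r) < 2:
            continue
        pairs = list(itertools.combinations(range(len(r)), 2))
        agree = sum(1 for i, j in pairs if r[i] == r[j])
        pa_terms.append(agree / len(pairs))
    pa = sum(pa_terms) / len(pa_terms)
    # category propensities over all rated subjects
    pi = []
    for c in categories:
        pi.append(sum(r.count(c) / len(r) for r in rows) / n)
    pe = sum(p * (1 - p) for p in pi) / (q - 1)
    return pa, pe, (pa - pe) / (1 - pe)


def random_matrix(rng, n=None, raters=None, q=None):
    n = n or int(rng.integers(4, 13))
    raters = raters or int(rng.integers(2, 5))
    q = q or int(rng.integers(2, 5))
    cats = [chr(97 + i) for i in range(q)]
    data = rng.choice(cats, size=(n, raters)).astype(object)
    # sprinkle missing cells but keep every subject with >= 2 ratings
    if raters > 2 and rng.random() < 0.5:
        for i in range(n):
            if rng.random() < 0.3:
                data[i, rng.integers(raters)] = None
    return RatingMatrix(pd.DataFrame(data), categories=cats)


class TestPercentAgreement:
    def test_identical_columns_agree_perfectly(self):
        m = RatingMatrix.from_columns([list("aabba"), list("aabba")])
        assert percent_agreement(m) == 1.0

    def test_two_raters_fraction_of_concordant_subjects(self):
        a = list("aaaaaaaabb")
        b = list("aaaaaaabab")  # 8 of 10 concordant
        m = RatingMatrix.from_columns([a, b])
        assert percent_agreement(m) == pytest.approx(0.8)

    def test_three_raters_pairwise_formula(self):
        m = RatingMatrix.from_columns([["a"], ["a"], ["b"]])
        with pytest.raises(InsufficientDataError):
            gwet_ac1(m)  # one subject is not enough for AC1
        assert percent_agreement(m) == pytest.approx(1 / 3)

    def test_no_multiply_rated_subject_raises(self):
        df = pd.DataFrame({"r1": ["a", None], "r2": [None, "b"]})
        with pytest.raises(InsufficientDataError):
            percent_agreement(RatingMatrix(df))


class TestGwetAc1:
    def test_hand_worked_two_rater_example(self):
        # 10 subjects: 6 both-a, 2 both-b, 2 discordant
        a = list("aaaaaabbab")
        b = list("aaaaaabbba")
        res = gwet_ac1(RatingMatrix.from_columns([a, b]))
        assert res.pa == pytest.approx(0.8)
        assert res.pe == pytest.approx(2 * 0.7 * 0.3)
        assert res.ac1 == pytest.approx(0.38 / 0.58)

    def test_perfect_agreement_mixed_prevalence(self):
        m = RatingMatrix.from_columns([list("aabbc"), list("aabbc")])
        res = gwet_ac1(m)
        assert res.pa == 1.0
        assert res.ac1 == 1.0
        assert res.band == "excellent"

    def test_balanced_complete_disagreement_is_minus_one(self):
        m = RatingMatrix.from_columns([list("abababab"), list("babababa")])
        res = gwet_ac1(m)
        assert res.pa == 0.0
        assert res.pe == pytest.approx(0.5)
        assert res.ac1 == pytest.approx(-1.0)

    def test_single_category_domain_is_degenerate(self):
        m = RatingMatrix.from_columns([["a", "a"], ["a", "a"]])
        with pytest.raises(DegenerateDataError):
            gwet_ac1(m)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(101)
        for _ in range(50):
            m = random_matrix(rng)
            res = gwet_ac1(m)
            cells = [list(row) for _, row in m.data.iterrows()]
            cells = [[None if isinstance(v, float) and math.isnan(v) else v for v in row]
                     for row in cells]
            pa, pe, ac1 = brute_force_ac1(cells, m.categories)
            assert res.pa == pytest.approx(pa, abs=1e-12)
            assert res.pe == pytest.approx(pe, abs=1e-12)
            assert res.ac1 == pytest.approx(ac1, abs=1e-12)

    def test_ci_brackets_the_point_estimate(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            res = gwet_ac1(random_matrix(rng))
            assert res.ci_low <= res.ac1 <= res.ci_high <= 1.0

    def test_q2_prevalence_paradox_bound(self):
        # for two categories pe <= 0.5, hence AC1 >= 2 pa - 1
        rng = np.random.default_rng(13)
        for _ in range(200):
            m = random_matrix(rng, q=2)
            res = gwet_ac1(m)
            assert res.ac1 >= 2 * res.pa - 1 - 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(23)
        m = random_matrix(rng, n=10, raters=3, q=3)
        res = gwet_ac1(m)
        shuffled = RatingMatrix(
            m.data.sample(frac=1, random_state=1)[list(reversed(m.raters))],
            categories=m.categories,
        )
        res2 = gwet_ac1(shuffled)
        assert res2.ac1 == pytest.approx(res.ac1, abs=1e-12)
        assert res2.variance == pytest.approx(res.variance, abs=1e-12)

    def test_variance_tracks_jackknife(self):
        rng = np.random.default_rng(31)
        ratios = []
        for _ in range(60):
            m = random_matrix(rng, n=12)
            res = gwet_ac1(m)
            jv = jackknife_variance(m)
            if jv > 1e-12:
                ratios.append(res.variance / jv)
        assert 0.85 < float(np.median(ratios)) < 1.15


class TestInterpretBand:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.95, "excellent"), (0.81, "excellent"),
            (0.80, "good"), (0.61, "good"),
            (0.60, "moderate"), (0.42, "moderate"), (0.41, "moderate"),
            (0.40, "fair"), (0.21, "fair"), (0.205, "fair"),
            (0.20, "poor"), (0.0, "poor"), (-1.0, "poor"),
        ],
    )
    def test_band_partition(self, value, band):
        assert interpret_band(value) == band


class TestPairwiseMean:
    def test_six_raters_give_fifteen_pairs(self):
        rng = np.random.default_rng(3)
        data = rng.choice(list("ab"), size=(10, 6))
        res = pairwise_mean_agreement(RatingMatrix(pd.DataFrame(data)))
        assert res.n_pairs == 15

    def test_three_raters_give_three_pairs(self):
        rng = np.random.default_rng(3)
        data = rng.choice(list("ab"), size=(10, 3))
        res = pairwise_mean_agreement(RatingMatrix(pd.DataFrame(data)))
        assert res.n_pairs == 3

    def test_identical_columns_mean_one(self):
        col = list("aabbab")
        res = pairwise_mean_agreement(RatingMatrix.from_columns([col] * 4))
        assert res.mean_pa == 1.0
        assert res.mean_ac1 == 1.0

    def test_pair_without_corated_subjects_is_excluded(self):
        df = pd.DataFrame(
            {"r1": ["a", "b", None, None], "r2": ["a", "b", None, None],
             "r3": [None, None, "a", "b"]}
        )
        res = pairwise_mean_agreement(RatingMatrix(df))
        assert ("r1", "r2") in [tuple(x) for x in res.per_pair[["rater_a", "rater_b"]].values]
        assert set(res.excluded_pairs) == {("r1", "r3"), ("r2", "r3")}


class TestIntraRater:
    def test_identical_sessions_give_one(self):
        m = RatingMatrix.from_columns([list("aabb"), list("abab")], raters=["r1", "r2"])
        res = intra_rater_agreement(m, m)
        assert all(r.pa == 1.0 and r.ac1 == 1.0 for r in res.values())

    def test_mismatched_subjects_raise(self):
        m1 = RatingMatrix.from_columns([list("aabb")], subjects=[1, 2, 3, 4], raters=["r"])
        m2 = RatingMatrix.from_columns([list("aabb")], subjects=[1, 2, 3, 5], raters=["r"])
        with pytest.raises(AlignmentError):
            intra_rater_agreement(m1, m2)

    def test_independent_uniform_ratings_have_null_ac1(self):
        rng = np.random.default_rng(55)
        s1 = rng.choice(list("ab"), size=(500, 1))
        s2 = rng.choice(list("ab"), size=(500, 1))
        res = intra_rater_agreement(
            RatingMatrix(pd.DataFrame(s1, columns=["r"])),
            RatingMatrix(pd.DataFrame(s2, columns=["r"])),
        )["r"]
        se = math.sqrt(res.variance)
        assert abs(res.ac1) < 3 * se


class TestWilcoxon:
    def test_identical_samples_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_three_positive_tied_differences(self):
        res = wilcoxon_signed_rank([1, 2, 3], [0, 1, 2])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)
        assert res.method == "exact"

    def test_swap_symmetry(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 2.0, 3.0, 1.0, 4.5]
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        n = a.n
        assert a.statistic + b.statistic == pytest.approx(n * (n + 1) / 2)
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_matches_scipy_without_ties(self):
        from scipy import stats

        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            mine = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, method="exact", alternative="two-sided")
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(19)
        x = rng.normal(1.0, 1, size=60)
        y = rng.normal(0.0, 1, size=60)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal"
        assert res.p_value < 0.05


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
        min_size=3, max_size=20,
    )
)
def test_ac1_never_exceeds_one_and_equals_one_iff_perfect(pairs):
    m = RatingMatrix.from_columns(
        [[p[0] for p in pairs], [p[1] for p in pairs]], categories=list("abc")
    )
    try:
        res = gwet_ac1(m)
    except DegenerateDataError:
        return
    assert res.ac1 <= 1.0 + 1e-12
    assert (res.ac1 == pytest.approx(1.0)) == (res.pa == pytest.approx(1.0))
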