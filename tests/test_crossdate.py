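"""Cross-dating statistics against independent oracles, and sliding dating."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dendrodate as dd
from dendrodate.core import IndexedSeries
from dendrodate.crossdate import SlideConfig, T_SENTINEL


def glk_sign_oracle(da, db):
    """Hand-enumeration oracle on difference sign patterns."""
    scores = []
    for x, y in zip(da, db):
        if x == 0 or y == 0:
            scores.append(0.5)
        else:
            scores.append(1.0 if x == y else 0.0)
    return sum(scores) / len(scores)


def series_with_diffs(diffs, start=5.0):
    vals = [start]
    for d in diffs:
        vals.append(vals[-1] + d)
    return IndexedSeries("d", np.array(vals), np.ones(len(vals), dtype=bool))


class TestGLK:
    def test_monotone_series_against_itself_is_one(self):
        a = series_with_diffs([0.3, 0.1, 0.2, 0.4, 0.1])
        assert dd.glk(a, a) == 1.0

    def test_hand_enumerated_pattern(self):
        # signs a=[+,+,-,+], b=[+,-,-,+]: agree, disagree, agree, agree
        a = series_with_diffs([1, 1, -1, 1])
        b = series_with_diffs([1, -1, -1, 1])
        assert dd.glk(a, b) == 0.75

    def test_inverted_series_scores_zero(self):
        a = series_with_diffs([0.3, -0.1, 0.2, -0.4])
        b = series_with_diffs([-0.3, 0.1, -0.2, 0.4], start=50.0)
        assert dd.glk(a, b) == 0.0

    def test_exhaustive_sign_patterns_match_oracle(self):
        """All difference sign patterns for series of up to 6 points."""
        for n_diff in (1, 2, 3, 4, 5):
            for da in itertools.product((-1, 0, 1), repeat=n_diff):
                for db in itertools.product((-1, 0, 1), repeat=n_diff):
                    a = series_with_diffs(da)
                    b = series_with_diffs(db)
                    assert dd.glk(a, b) == pytest.approx(
                        glk_sign_oracle(da, db)
                    ), (da, db)

    @settings(max_examples=40, deadline=None)
    @given(
        av=st.lists(st.floats(0.1, 2.0), min_size=6, max_size=25),
        bv=st.lists(st.floats(0.1, 2.0), min_size=6, max_size=25),
        k=st.integers(-5, 5),
    )
    def test_symmetry_and_range(self, av, bv, k):
        a = IndexedSeries("a", np.array(av), np.ones(len(av), dtype=bool))
        b = IndexedSeries("b", np.array(bv), np.ones(len(bv), dtype=bool))
        g = dd.glk(a, b, k)
        assert g == dd.glk(b, a, -k)
        if g is not None:
            assert 0.0 <= g <= 1.0

    def test_insufficient_overlap_is_undefined(self):
        a = series_with_diffs([1, 1])
        assert dd.glk(a, a, offset=10) is None


def naive_pearson(x, y):
    """Two-pass textbook Pearson correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (
        sum((a - mx) ** 2 for a in x) ** 0.5
        * sum((b - my) ** 2 for b in y) ** 0.5
    )
    return num / den


class TestOverlapCorr:
    def test_series_against_itself(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=80)
        valid = rng.random(80) > 0.1
        a = IndexedSeries("a", v, valid)
        r, n = dd.overlap_corr(a, a, 0, min_overlap=10)
        assert r == pytest.approx(1.0)
        assert n == int(valid.sum())

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), offset=st.integers(-10, 10))
    def test_matches_naive_two_pass_oracle(self, seed, offset):
        rng = np.random.default_rng(seed)
        a = IndexedSeries("a", rng.normal(size=70), rng.random(70) > 0.15)
        b = IndexedSeries("b", rng.normal(size=60), rng.random(60) > 0.15)
        r, n = dd.overlap_corr(a, b, offset, min_overlap=10)
        lo = max(0, -offset)
        hi = min(70, 60 - offset)
        xs, ys = [], []
        for i in range(lo, hi):
            if a.valid[i] and b.valid[i + offset]:
                xs.append(a.index[i])
                ys.append(b.index[i + offset])
        assert n == len(xs)
        if r is not None:
            assert r == pytest.approx(naive_pearson(xs, ys), abs=1e-10)

    def test_white_noise_null_distribution(self):
        rng = np.random.default_rng(1)
        rs = []
        n = 500
        for _ in range(300):
            a = IndexedSeries("a", rng.normal(size=n), np.ones(n, dtype=bool))
            b = IndexedSeries("b", rng.normal(size=n), np.ones(n, dtype=bool))
            r, _ = dd.overlap_corr(a, b, 0, min_overlap=50)
            rs.append(r)
        rs = np.array(rs)
        assert abs(rs.mean()) < 0.05
        assert rs.std() == pytest.approx(1 / np.sqrt(n), rel=0.25)

    def test_zero_variance_window_is_undefined(self):
        a = IndexedSeries("a", np.ones(60), np.ones(60, dtype=bool))
        b = IndexedSeries("b", np.arange(60.0), np.ones(60, dtype=bool))
        r, n = dd.overlap_corr(a, b, 0, min_overlap=10)
        assert r is None and n == 60

    def test_short_overlap_is_undefined_but_counted(self):
        a = IndexedSeries("a", np.arange(20.0), np.ones(20, dtype=bool))
        r, n = dd.overlap_corr(a, a, 15, min_overlap=50)
        assert r is None and n == 5


class TestBPTValue:
    def test_closed_form_values(self):
        assert dd.bp_tvalue(0.0, 50) == 0.0
        assert dd.bp_tvalue(0.5, 100) == pytest.approx(5.715, abs=5e-4)

    def test_monotone_in_r_and_n(self):
        assert dd.bp_tvalue(0.6, 100) > dd.bp_tvalue(0.4, 100)
        assert dd.bp_tvalue(0.4, 200) > dd.bp_tvalue(0.4, 100)

    def test_negative_r_gives_negative_t(self):
        assert dd.bp_tvalue(-0.3, 80) == -dd.bp_tvalue(0.3, 80)

    def test_r_of_one_returns_sentinel_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert dd.bp_tvalue(1.0, 50) == T_SENTINEL

    def test_tiny_overlap_is_an_error(self):
        with pytest.raises(dd.ValidationError):
            dd.bp_tvalue(0.5, 2)

    def test_t_pvalue_matches_permutation_test(self):
        """The t on n-2 df agrees with a permutation null within MC error."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        r = np.corrcoef(x, y)[0, 1]
        t = dd.bp_tvalue(r, 30)
        p_t = 2 * stats.t.sf(abs(t), df=28)
        perm = []
        for _ in range(4000):
            perm.append(abs(np.corrcoef(x, rng.permutation(y))[0, 1]))
        p_perm = np.mean(np.array(perm) >= abs(r))
        assert p_t == pytest.approx(p_perm, abs=0.02)


class TestSlideDate:
    def _reference(self, seed=2, n=600, first=1400):
        rng = np.random.default_rng(seed)
        return IndexedSeries(
            "ref", rng.normal(size=n), np.ones(n, dtype=bool), first_year=first
        )

    def test_exact_slice_recovers_true_year_with_r_one(self):
        ref = self._reference()
        sub = IndexedSeries(
            "u", ref.index[150:450].copy(), np.ones(300, dtype=bool)
        )
        res = dd.slide_date(sub, ref)
        assert res[0].rank == 1
        assert res[0].candidate_first_year == 1400 + 150
        assert res[0].corr == pytest.approx(1.0)
        assert res[0].glk == pytest.approx(1.0)

    def test_generator_series_recovers_truth_against_master(self, small_site):
        series, truth = small_site
        res = dd.slide_date(series[0], truth.climate_series())
        assert res[0].significant
        assert (
            res[0].candidate_first_year
            == truth.records[series[0].series_id].first_year
        )

    def test_translation_consistency(self):
        ref = self._reference()
        sub = IndexedSeries("u", ref.index[100:400].copy(), np.ones(300, dtype=bool))
        shifted_ref = IndexedSeries(
            "ref2", ref.index, ref.valid, first_year=ref.first_year + 57
        )
        a = dd.slide_date(sub, ref)
        b = dd.slide_date(sub, shifted_ref)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert cb.candidate_first_year == ca.candidate_first_year + 57
            assert cb.tvalue == pytest.approx(ca.tvalue)
            assert cb.glk == pytest.approx(ca.glk)

    def test_self_dating_ranks_zero_offset_first(self, small_site):
        series, truth = small_site
        dated = truth.date(series[0])
        idx = dd.index_series(dated)
        res = dd.slide_date(
            IndexedSeries("u", idx.index, idx.valid), idx
        )
        assert res[0].candidate_first_year == dated.first_year
        assert res[0].corr == pytest.approx(1.0)
        assert res[0].glk == pytest.approx(1.0)

    def test_reference_shorter_than_min_overlap_gives_empty(self):
        ref = IndexedSeries(
            "r", np.arange(30.0), np.ones(30, dtype=bool), first_year=1900
        )
        sub = IndexedSeries("u", np.arange(30.0), np.ones(30, dtype=bool))
        assert dd.slide_date(sub, ref, SlideConfig(min_overlap=50)) == []

    def test_negative_t_candidates_never_significant(self):
        ref = self._reference(seed=9)
        inverted = IndexedSeries(
            "u", -ref.index[200:480], np.ones(280, dtype=bool)
        )
        res = dd.slide_date(inverted, ref)
        for c in res:
            if c.tvalue < 0:
                assert not c.significant

    def test_results_ranked_by_tvalue(self):
        ref = self._reference(seed=4)
        sub = IndexedSeries("u", ref.index[100:350].copy(), np.ones(250, dtype=bool))
        res = dd.slide_date(sub, ref)
        ts = [c.tvalue for c in res]
        assert ts == sorted(ts, reverse=True)
        assert [c.rank for c in res] == list(range(1, len(res) + 1))
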