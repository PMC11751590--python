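"""Missing-ring insertion, segment lag diagnostics, and the greedy search."""

import numpy as np
import pytest

import dendrodate as dd
from dendrodate.core import RingFlag
from dendrodate.missing import segment_lag_scan

from conftest import delete_rings


def clean_series(seed, n=300):
    cfg = dd.GeneratorConfig(
        n_samples=1, radii_per_sample=(1, 1), length_range=(n, n),
        missing_rate=0.0, wedging_prob=0.0, seed=seed,
    )
    series, truth = dd.generate_site(cfg)
    return truth.date(series[0]), truth


class TestApplyMissing:
    def test_fig_counts_1141_plus_35(self):
        s = dd.make_series("OLD", np.full(1141, 0.09), first_year=845)
        s2 = dd.apply_missing(s, list(range(200, 235)))
        assert len(s2) == 1176
        assert s2.n_measured == 1141 and s2.n_missing == 35
        assert s2.last_year == 2020

    def test_no_positions_is_identity(self):
        s = dd.make_series("A", [0.1, 0.2, 0.3], first_year=1990)
        s2 = dd.apply_missing(s, [])
        np.testing.assert_array_equal(s2.widths, s.widths)
        np.testing.assert_array_equal(s2.ring_flags, s.ring_flags)

    def test_boundary_insertions(self):
        s = dd.make_series("A", [0.1, 0.2, 0.3], first_year=1990)
        s2 = dd.apply_missing(s, [0, 4])
        assert len(s2) == 5
        assert s2.ring_flags[0] == RingFlag.MISSING_INSERTED
        assert s2.ring_flags[4] == RingFlag.MISSING_INSERTED
        np.testing.assert_array_equal(s2.widths[[1, 2, 3]], s.widths)

    def test_adjacent_missing_rings_are_expressible(self):
        s = dd.make_series("A", [0.1, 0.2, 0.3], first_year=1990)
        s2 = dd.apply_missing(s, [1, 2])
        assert s2.n_missing == 2 and s2.n_measured == 3

    def test_duplicates_rejected(self):
        s = dd.make_series("A", [0.1, 0.2, 0.3])
        with pytest.raises(dd.ValidationError, match="duplicate"):
            dd.apply_missing(s, [1, 1])

    def test_measured_widths_conserved(self):
        rng = np.random.default_rng(0)
        s = dd.make_series("A", rng.uniform(0.05, 1.0, 50), first_year=1900)
        s2 = dd.apply_missing(s, [3, 17, 44])
        np.testing.assert_array_equal(s2.widths[s2.measured_mask], s.widths)
        assert s2.n_measured == s.n_measured


class TestSegmentLagScan:
    def test_well_dated_series_sits_at_lag_zero(self):
        s, truth = clean_series(21)
        diags = segment_lag_scan(s, dd.index_series(s))
        assert all(d.best_lag == 0 for d in diags)
        assert not any(d.flagged for d in diags)

    def test_single_deletion_splits_lag_profile(self):
        s, truth = clean_series(22)
        p = 150
        broken = delete_rings(s, [p])
        diags = segment_lag_scan(broken, dd.index_series(s), step=25)
        before = [d for d in diags if d.end <= p - 5]
        after = [d for d in diags if d.start >= p + 5]
        assert before and after
        assert all(d.best_lag == 0 for d in before)
        assert all(d.best_lag == 1 for d in after)

    def test_short_series_scanned_whole_with_warning(self):
        s, truth = clean_series(23, n=150)
        short = dd.make_series("short", s.widths[:30], first_year=s.first_year)
        with pytest.warns(RuntimeWarning, match="single"):
            diags = segment_lag_scan(short, dd.index_series(s))
        assert len(diags) == 1
        assert (diags[0].start, diags[0].end) == (0, 30)


class TestProposeMissing:
    def test_clean_series_proposes_nothing(self):
        s, truth = clean_series(30)
        hyp = dd.propose_missing(s, truth.climate_series(), max_missing=3)
        assert hyp.positions == []
        assert hyp.score_after == hyp.score_before

    def test_single_deletion_recovered_within_one_ring(self):
        hits = 0
        for seed in range(10):
            s, truth = clean_series(31 + seed)
            rng = np.random.default_rng(seed)
            p = int(rng.integers(20, 280))
            hyp = dd.propose_missing(
                delete_rings(s, [p]), dd.index_series(s), max_missing=3
            )
            hits += len(hyp.positions) == 1 and abs(hyp.positions[0] - p) <= 1
        assert hits >= 9

    def test_score_after_reproducible_from_modified_series(self):
        s, truth = clean_series(44)
        p = 140
        broken = delete_rings(s, [p])
        ref = dd.index_series(s)
        hyp = dd.propose_missing(broken, ref, max_missing=3)
        assert hyp.positions
        rebuilt = dd.apply_missing(
            broken.dated_at(broken.first_year + hyp.anchor_shift), hyp.positions
        )
        idx = dd.index_series(rebuilt)
        r, n = dd.overlap_corr(
            idx, ref, rebuilt.first_year - ref.first_year, 10
        )
        assert dd.bp_tvalue(r, n) == pytest.approx(hyp.score_after)

    def test_greedy_matches_exhaustive_on_small_instances(self):
        agree = 0
        for seed in range(6):
            cfg = dd.GeneratorConfig(
                n_samples=1, radii_per_sample=(1, 1), length_range=(140, 140),
                missing_rate=0.0, wedging_prob=0.0, seed=60 + seed,
            )
            series, truth = dd.generate_site(cfg)
            s = truth.date(series[0])
            rng = np.random.default_rng(seed)
            ps = sorted(rng.choice(np.arange(15, 110), 2, replace=False).tolist())
            broken = dd.make_series(
                "b", np.delete(s.widths[:120], ps), first_year=s.first_year
            )
            ref = dd.index_series(s)
            g = dd.propose_missing(broken, ref, max_missing=2)
            e_pos, _ = dd.exhaustive_missing_search(broken, ref, max_k=2)
            agree += g.positions == e_pos
        assert agree == 6

    def test_negative_max_missing_rejected(self):
        s, truth = clean_series(50)
        with pytest.raises(dd.ValidationError):
            dd.propose_missing(s, truth.climate_series(), max_missing=-1)

    def test_undated_inputs_rejected(self):
        s, truth = clean_series(51)
        with pytest.raises(dd.ValidationError, match="dated"):
            dd.propose_missing(
                s.dated_at(None), truth.climate_series(), max_missing=1
            )
        with pytest.raises(dd.ValidationError, match="dated"):
            dd.propose_missing(
                s, dd.index_series(s.dated_at(None)), max_missing=1
            )
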