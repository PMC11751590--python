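"""The ring-width generator: reproducibility, missing-rate control, signal."""

import numpy as np
import pytest

import dendrodate as dd


def cfg(**kw):
    base = dict(
        n_samples=2, radii_per_sample=(1, 1), length_range=(300, 300),
        missing_rate=0.0, wedging_prob=0.0, seed=1,
    )
    base.update(kw)
    return dd.GeneratorConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        s1, t1 = dd.generate_site(cfg(seed=5))
        s2, t2 = dd.generate_site(cfg(seed=5))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.widths, b.widths)
        np.testing.assert_array_equal(t1.climate, t2.climate)

    def test_different_seed_differs(self):
        s1, _ = dd.generate_site(cfg(seed=5))
        s2, _ = dd.generate_site(cfg(seed=6))
        assert not np.array_equal(s1[0].widths, s2[0].widths)

    def test_export_fixture_byte_identical(self, tmp_path):
        series, truth = dd.generate_site(cfg(seed=7, missing_rate=0.02))
        p1 = dd.export_fixture(series, truth, tmp_path / "a")
        p2 = dd.export_fixture(series, truth, tmp_path / "b")
        assert p1["rwl"].read_bytes() == p2["rwl"].read_bytes()
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()

    def test_exported_rwl_round_trips(self, tmp_path):
        series, truth = dd.generate_site(cfg(seed=8))
        paths = dd.export_fixture(series, truth, tmp_path)
        back = dd.read_tucson(paths["rwl"].read_text())
        assert len(back) == len(series)
        np.testing.assert_allclose(back[0].widths, series[0].widths, atol=0.005)

    def test_truth_table_has_one_row_per_series(self, tmp_path):
        series, truth = dd.generate_site(cfg(n_samples=4, seed=9))
        paths = dd.export_fixture(series, truth, tmp_path)
        rows = paths["truth"].read_text().strip().splitlines()
        assert len(rows) - 1 == len(series)


class TestWidthProcess:
    def test_widths_strictly_positive(self):
        series, _ = dd.generate_site(cfg(seed=10, missing_rate=0.03))
        for s in series:
            assert (s.widths > 0).all()  # deletion is the only zero source

    def test_emitted_series_have_no_missing_flags(self):
        series, _ = dd.generate_site(cfg(seed=11, missing_rate=0.05))
        for s in series:
            assert s.n_missing == 0  # missing rings are deleted, not zeroed

    def test_realized_missing_fraction_matches_target(self):
        c = cfg(
            n_samples=1, length_range=(1000, 1000), missing_rate=0.03, seed=12
        )
        series, truth = dd.generate_site(c)
        rec = truth.records[series[0].series_id]
        realized = len(rec.deleted) / rec.disk_length
        assert realized == pytest.approx(0.03, abs=0.01)

    def test_impossible_zero_missing_config_errors(self):
        # a floor above every attainable width forces misses at rate 0
        c = cfg(
            seed=13, missing_rate=0.0, measurement_floor=5.0,
            trend_a=0.1, trend_b=0.01,
        )
        with pytest.raises(dd.ValidationError, match="impossible|floor"):
            dd.generate_site(c)


class TestSharedSignal:
    def test_full_signal_share_gives_near_perfect_pairwise_r(self):
        # radius noise off: the limit statement concerns the shared signal
        series, truth = dd.generate_site(
            cfg(seed=14, signal_share=1.0, length_range=(500, 500),
                living_fraction=1.0, radius_noise_sigma=0.0)
        )
        idx = [dd.index_series(truth.date(s)) for s in series]
        rbar, _, _ = dd.rbar_eps(idx)
        assert rbar > 0.95

    def test_zero_signal_share_gives_near_zero_pairwise_r(self):
        rbars = []
        for seed in range(8):
            series, truth = dd.generate_site(
                cfg(seed=100 + seed, signal_share=0.0, length_range=(500, 500),
                    living_fraction=1.0)
            )
            idx = [dd.index_series(truth.date(s)) for s in series]
            rbar, _, _ = dd.rbar_eps(idx)
            rbars.append(rbar)
        assert abs(np.mean(rbars)) < 0.05

    def test_rbar_increases_monotonically_with_signal_share(self):
        means = []
        for a in (0.1, 0.5, 0.9):
            vals = []
            for seed in range(4):
                series, truth = dd.generate_site(
                    cfg(n_samples=4, seed=200 + seed, signal_share=a,
                        length_range=(400, 400), living_fraction=1.0)
                )
                idx = [dd.index_series(truth.date(s)) for s in series]
                rbar, _, _ = dd.rbar_eps(idx)
                vals.append(rbar)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestTruth:
    def test_truth_scores_recovery_without_rerunning_generator(self):
        series, truth = dd.generate_site(cfg(seed=15, missing_rate=0.02))
        rec = truth.records[series[0].series_id]
        assert rec.disk_length == len(series[0]) + len(rec.deleted)
        assert rec.first_year == rec.disk_first_year + min(
            i for i in range(rec.disk_length) if i not in set(rec.deleted)
        )

    def test_restore_realigns_every_ring(self):
        series, truth = dd.generate_site(
            cfg(seed=16, missing_rate=0.02, length_range=(400, 400))
        )
        s = series[0]
        restored = dd.index_series(truth.restore(s))
        r, n = dd.overlap_corr(
            restored,
            truth.climate_series(),
            restored.first_year - truth.climate_first_year,
            min_overlap=50,
        )
        raw = dd.index_series(truth.date(s))
        r_raw, _ = dd.overlap_corr(
            raw, truth.climate_series(),
            raw.first_year - truth.climate_first_year, min_overlap=50,
        )
        assert r > r_raw  # restoration must improve alignment

    def test_wedging_creates_radius_specific_deletions(self):
        series, truth = dd.generate_site(
            dd.GeneratorConfig(
                n_samples=6, radii_per_sample=(2, 2), length_range=(300, 300),
                missing_rate=0.0, wedging_prob=1.0, seed=17,
            )
        )
        by_sample = {}
        for s in series:
            by_sample.setdefault(s.sample_id, []).append(truth.records[s.series_id])
        assert any(
            recs[0].deleted != recs[1].deleted for recs in by_sample.values()
        )
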