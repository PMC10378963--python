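"""Epoch-series feature extraction: wear validity, volume, histograms,
time-in-range summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from accelcox.features import (
    BinScheme,
    EpochSeries,
    build_histogram,
    compute_volume,
    default_bins,
    minutes_in_range,
    read_epoch_csv,
    sleep_minutes,
    time_budget,
    validate_wear,
    write_histogram_csv,
    read_histogram_csv,
    histograms_to_frame,
)
from accelcox.simulate import SimConfig, generate_epoch_series


def _series(values, epoch_seconds=5.0, **kw):
    return EpochSeries("p1", np.asarray(values, dtype=float), epoch_seconds, **kw)


def _full_days(n_days, per_day=17280, level=30.0):
    return _series(np.full(n_days * per_day, level))


class TestWearValidity:
    def test_seven_full_days_valid(self):
        assert validate_wear(_full_days(7))

    def test_two_days_invalid(self):
        assert not validate_wear(_full_days(2))

    def test_missing_hour_invalid(self):
        # four days of data but hour 3 of the 24-h cycle never covered
        per_day = 17280
        x = np.full(4 * per_day, 30.0)
        s = _series(x)
        keep = s.hour_of_day != 3
        s2 = EpochSeries("p1", x[keep], 5.0, s.day_index[keep], s.hour_of_day[keep])
        assert not validate_wear(s2)

    def test_empty_series_invalid_not_error(self):
        assert not validate_wear(_series([]))


class TestVolume:
    def test_constant_series(self):
        assert compute_volume(_series([30.0] * 10)) == pytest.approx(30.0)

    def test_sleep_epochs_included(self):
        assert compute_volume(_series([0.0, 60.0])) == pytest.approx(30.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_volume(_series([]))

    def test_values_capped_at_2000(self):
        s = _series([3000.0, 1000.0])
        assert s.accel_mg.max() == 2000.0


COARSE = BinScheme((3.0, 60.0, 300.0, 500.0, 2000.0), (30.0, 180.0, 400.0, 600.0))


class TestHistogram:
    def test_hand_counted_example(self):
        h = build_histogram(_series([2.0, 10.0, 10.0, 200.0]), COARSE)
        np.testing.assert_allclose(h.rel_freq, [2 / 3, 1 / 3, 0.0, 0.0])
        assert h.sleep_fraction == pytest.approx(0.25)
        assert h.volume == pytest.approx((2 + 10 + 10 + 200) / 4)

    def test_single_bin(self):
        h = build_histogram(_series([70.0, 80.0, 90.0]), COARSE)
        np.testing.assert_allclose(h.rel_freq, [0.0, 1.0, 0.0, 0.0])

    def test_all_sleep_flagged_empty(self):
        h = build_histogram(_series([1.0, 2.0, 0.5]), COARSE)
        assert h.empty
        assert np.all(np.isnan(h.rel_freq))
        assert h.sleep_fraction == 1.0

    @given(st.lists(st.floats(0.0, 1999.0), min_size=1, max_size=300))
    def test_normalization_and_permutation_invariance(self, values):
        bins = default_bins()
        h = build_histogram(_series(values), bins)
        if not h.empty:
            assert h.rel_freq.sum() == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(values))
        h2 = build_histogram(_series(np.asarray(values)[perm]), bins)
        assert h.empty == h2.empty
        if not h.empty:
            np.testing.assert_allclose(h.rel_freq, h2.rel_freq)

    @given(st.lists(st.floats(0.0, 1999.0), min_size=5, max_size=200),
           st.integers(0, 40), st.integers(2, 6))
    def test_coarsening_sums_mass_exactly(self, values, start, width):
        bins = default_bins()
        start = min(start, bins.n_bins - 2)
        stop = min(start + width, bins.n_bins - 1)
        if start >= stop:
            stop = start + 1
        merged = bins.merge_adjacent(start, stop)
        h = build_histogram(_series(values), bins)
        hm = build_histogram(_series(values), merged)
        if h.empty:
            return
        expected = np.concatenate(
            [h.rel_freq[:start], [h.rel_freq[start:stop].sum()], h.rel_freq[stop:]]
        )
        np.testing.assert_allclose(hm.rel_freq, expected, atol=1e-12)

    def test_volume_consistent_with_fine_histogram(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 600, size=5000)
        s = _series(x)
        # fine full-range histogram including sleep mass at midpoints
        edges = np.arange(0.0, 2001.0, 5.0)
        counts, _ = np.histogram(s.accel_mg, bins=edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        vol_hist = counts @ mids / counts.sum()
        assert abs(vol_hist - compute_volume(s)) <= 2.5  # half the bin width


class TestBinScheme:
    def test_edges_must_start_at_3_and_end_at_2000(self):
        with pytest.raises(ValueError):
            BinScheme((5.0, 60.0, 500.0, 2000.0), (30.0, 200.0, 600.0))

    def test_terminal_interval_fixed(self):
        with pytest.raises(ValueError):
            BinScheme((3.0, 60.0, 400.0, 2000.0), (30.0, 200.0, 600.0))

    def test_representatives_inside_intervals(self):
        with pytest.raises(ValueError):
            BinScheme((3.0, 500.0, 2000.0), (600.0, 600.0))

    def test_default_bins_align_with_walking_categories(self):
        e = default_bins().edges
        for boundary in (60.0, 125.0, 300.0, 500.0):
            assert boundary in e


class TestMinutesInRange:
    def test_sleep_hours(self):
        h = build_histogram(_series([30.0] * 7 + [1.0] * 3), COARSE)
        assert sleep_minutes(h) / 60 == pytest.approx(0.3 * 24)

    def test_single_sedentary_bin_full_day(self):
        h = build_histogram(_series([30.0] * 10), COARSE)
        assert minutes_in_range(h, 3.0, 60.0) == pytest.approx(1440.0)

    def test_partition_conserves_awake_minutes(self):
        rng = np.random.default_rng(1)
        h = build_histogram(_series(rng.uniform(0, 900, 2000)), COARSE)
        total = sum(
            minutes_in_range(h, lo, hi)
            for lo, hi in [(3, 60), (60, 300), (300, 500), (500, 2000)]
        )
        assert total == pytest.approx((1 - h.sleep_fraction) * 1440.0)

    def test_misaligned_range_names_nearest_edges(self):
        h = build_histogram(_series([30.0] * 10), COARSE)
        with pytest.raises(ValueError, match="nearest valid edges are 60 and 300"):
            minutes_in_range(h, 62.0, 305.0)

    def test_time_budget_keys(self):
        h = build_histogram(_series([30.0] * 10), default_bins())
        tb = time_budget(h)
        assert set(tb) == {"sleep_h", "sedentary_h", "slow_walk_min",
                           "moderate_walk_min", "brisk_walk_min"}


class TestCSVRoundTrip:
    def test_histogram_csv(self, tmp_path, bins):
        rng = np.random.default_rng(7)
        hists = [
            build_histogram(
                EpochSeries(i, rng.uniform(0, 700, 500), 5.0), bins
            )
            for i in range(4)
        ]
        path = tmp_path / "h.csv"
        write_histogram_csv(hists, path)
        df, bins2 = read_histogram_csv(path)
        assert bins2.edges == bins.edges
        np.testing.assert_allclose(
            df[bins.labels()].to_numpy(), histograms_to_frame(hists)[bins.labels()].to_numpy()
        )

    def test_epoch_csv(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant_id": [1, 1, 1, 2, 2],
                "epoch_index": [0, 1, 2, 0, 1],
                "accel_mg": [5.0, 10.0, 20.0, 1.0, 400.0],
            }
        )
        path = tmp_path / "e.csv"
        df.to_csv(path, index=False)
        series = read_epoch_csv(path)
        assert len(series) == 2
        assert compute_volume(series[0]) == pytest.approx(35.0 / 3)

    def test_epoch_csv_missing_column(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"participant_id": [1], "accel_mg": [5.0]}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(ValueError, match="epoch_index"):
            read_epoch_csv(tmp_path / "bad.csv")


def test_simulated_epoch_series_has_realistic_histogram(bins):
    """A sampled epoch series from the generator feeds cleanly through the
    feature extraction and shows the dominant sub-60 mg mass."""
    cfg = SimConfig(n_participants=1, seed=1)
    rng = np.random.default_rng(9)
    w = cfg.dirichlet_alpha() / cfg.dirichlet_alpha().sum()
    s = generate_epoch_series(cfg, 0, w, rng)
    assert validate_wear(s)
    h = build_histogram(s, bins)
    mask_low = np.asarray(bins.edges[:-1]) < 60.0
    assert h.rel_freq[mask_low].sum() > 0.7
    assert 0.2 < h.sleep_fraction < 0.45
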