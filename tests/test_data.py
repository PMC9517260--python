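"""Stream synchronization, sliding-window segmentation, normalization, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hear.data import (
    NormStats,
    SensorStream,
    WindowedDataset,
    count_windows,
    dataset_to_streams,
    fit_norm_stats,
    normalize,
    read_csv,
    segment_windows,
    synchronize,
    write_csv,
)
from hear.generate import generate_dataset, make_profiles, scenario

from conftest import make_stream


class TestSynchronize:
    def test_identical_grids_unchanged(self):
        streams = [make_stream(1, n=50), make_stream(2, n=50)]
        out = synchronize(streams)
        for before, after in zip(streams, out):
            np.testing.assert_array_equal(before.timestamps, after.timestamps)
            np.testing.assert_array_equal(before.values, after.values)

    def test_overlap_truncated_to_intersection(self):
        a = make_stream(1, t0=0, n=100)
        b = make_stream(2, t0=50, n=100)
        out = synchronize([a, b])
        for s in out:
            np.testing.assert_array_equal(s.timestamps, np.arange(50, 100))
        # values follow their own stream, restricted to the common grid
        np.testing.assert_array_equal(out[0].values, a.values[50:])
        np.testing.assert_array_equal(out[1].values, b.values[:50])

    def test_disjoint_grids_error(self):
        a = make_stream(1, t0=0, n=10)
        b = make_stream(2, t0=20, n=10)
        with pytest.raises(ValueError, match="no overlapping"):
            synchronize([a, b])

    def test_conflicting_labels_name_timestamp(self):
        a = make_stream(1, n=10, label="cooking")
        b = make_stream(2, n=10, label="cooking")
        b.labels[7] = "writing"
        with pytest.raises(ValueError, match="timestamp 7"):
            synchronize([a, b])

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            synchronize([])


class TestSegmentWindows:
    def test_single_full_window(self):
        streams = [make_stream(1, n=50), make_stream(2, n=50)]
        ds = segment_windows(streams, T=50, step=25)
        assert len(ds) == 1
        assert ds.X.shape == (1, 50, 2, 9)

    def test_three_windows_from_length_100(self):
        streams = [make_stream(1, n=100), make_stream(2, n=100)]
        ds = segment_windows(streams, T=50, step=25)
        assert len(ds) == 3  # floor((100-50)/25) + 1

    def test_window_covers_half_open_range(self):
        s = make_stream(1, n=100)
        ds = segment_windows([s], T=50, step=25)
        np.testing.assert_allclose(ds.X[1, :, 0, :], s.values[25:75], rtol=1e-6)

    def test_mixed_label_spans_skipped(self):
        s = make_stream(1, n=100, label="cooking")
        s.labels[60:] = "writing"
        ds = segment_windows([s], T=50, step=25)
        # runs: cooking 0..59 (one window), writing 60..99 (none of length 50)
        assert len(ds) == 1
        assert ds.class_names[ds.y[0]] == "cooking"

    def test_timestamp_gap_breaks_contiguity(self):
        a = make_stream(1, t0=0, n=50)
        b = make_stream(1, t0=60, n=50)
        s = SensorStream(
            1,
            np.concatenate([a.timestamps, b.timestamps]),
            np.concatenate([a.values, b.values]),
            np.concatenate([a.labels, b.labels]),
        )
        ds = segment_windows([s], T=50, step=25)
        assert len(ds) == 2  # one per contiguous run, none across the gap

    @pytest.mark.parametrize("T,step", [(0, 1), (1, 0), (-3, 2)])
    def test_invalid_geometry_error(self, T, step):
        with pytest.raises(ValueError):
            segment_windows([make_stream(1, n=10)], T=T, step=step)

    def test_unsynchronized_error(self):
        with pytest.raises(ValueError, match="synchron"):
            segment_windows(
                [make_stream(1, n=60), make_stream(2, n=50)], T=10, step=5
            )

    @given(
        n_seg=st.integers(min_value=0, max_value=200),
        T=st.integers(min_value=1, max_value=20),
        step=st.integers(min_value=1, max_value=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_window_count_matches_bruteforce(self, n_seg, T, step):
        """Closed-form count equals enumeration of valid start indices."""
        brute = sum(1 for start in range(n_seg) if start % step == 0
                    and start + T <= n_seg)
        assert count_windows(n_seg, T, step) == brute

    def test_nonoverlapping_windows_reconstruct_segment(self):
        s = make_stream(1, n=60)
        ds = segment_windows([s], T=20, step=20)
        rebuilt = np.concatenate([w[:, 0, :] for w in ds.X])
        np.testing.assert_allclose(rebuilt, s.values, rtol=1e-6)


class TestNormalize:
    def _dataset(self, X):
        return WindowedDataset(X, np.zeros(len(X), dtype=int), ["a"], X.shape[1], 1)

    def test_fit_gives_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        ds = self._dataset(rng.normal(3.0, 2.0, size=(40, 10, 2, 9)))
        out, _ = normalize(ds, "fit")
        mean = out.X.mean(axis=(0, 1))
        std = out.X.std(axis=(0, 1))
        assert np.abs(mean).max() < 1e-6
        assert np.abs(std - 1).max() < 1e-5

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(1)
        ds = self._dataset(rng.normal(size=(30, 8, 1, 9)))
        once, stats = normalize(ds, "fit")
        twice, _ = normalize(once, "fit")
        np.testing.assert_allclose(twice.X, once.X, atol=1e-5)

    def test_constant_channel_maps_to_zero(self):
        X = np.full((5, 6, 1, 9), 5.0)
        out, _ = normalize(self._dataset(X), "fit")
        assert np.all(out.X == 0.0)

    def test_validation_uses_train_statistics(self):
        rng = np.random.default_rng(2)
        train = self._dataset(rng.normal(0, 1, size=(20, 6, 1, 9)))
        val = self._dataset(rng.normal(10, 5, size=(20, 6, 1, 9)))
        _, stats = normalize(train, "fit")
        out, _ = normalize(val, stats)
        # val keeps its offset relative to the train statistics
        assert out.X.mean() > 5

    def test_nonfinite_error_lists_window(self):
        X = np.zeros((3, 4, 1, 9))
        X[1, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize(self._dataset(X), "fit")

    def test_supplied_stats_applied_verbatim(self):
        X = np.ones((2, 3, 1, 9))
        stats = NormStats(mean=np.zeros((1, 9)), std=np.full((1, 9), 2.0))
        out, _ = normalize(self._dataset(X), stats)
        np.testing.assert_allclose(out.X, 0.5)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        streams = [make_stream(1, n=30, label="reading"),
                   make_stream(2, n=30, label="reading", seed=5)]
        path = tmp_path / "data.csv"
        write_csv(streams, path)
        back = read_csv(path)
        assert len(back) == 2
        for a, b in zip(streams, back):
            assert a.sensor_id == b.sensor_id
            np.testing.assert_array_equal(a.timestamps, b.timestamps)
            np.testing.assert_allclose(a.values, b.values)
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_missing_column_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timestamp,sensor_id,ax\n0,1,0.1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_csv(path)

    def test_npz_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "ds.npz"
        small_dataset.save(path)
        back = WindowedDataset.load(path)
        np.testing.assert_allclose(back.X, small_dataset.X)
        np.testing.assert_array_equal(back.y, small_dataset.y)
        assert back.class_names == small_dataset.class_names

    def test_dataset_to_streams_resegments_losslessly(self):
        profiles = make_profiles(3, seed=0)
        ds = generate_dataset(
            profiles, scenario("S1", majority=5,
                               class_names=("a", "b", "c")), T=50, seed=0)
        streams = synchronize(dataset_to_streams(ds))
        back = segment_windows(streams, T=50, step=25,
                               class_names=ds.class_names)
        assert len(back) == len(ds)
        np.testing.assert_array_equal(np.sort(back.y), np.sort(ds.y))
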