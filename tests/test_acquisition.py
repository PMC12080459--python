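"""Tests of scan-stream I/O, TIC segmentation and spectral reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asapqc.acquisition import (
    AveragedSpectrum,
    DetectionParams,
    InsertionWindow,
    ProcessParams,
    ScanStream,
    average_window,
    compute_tic,
    detect_insertions,
    flag_saturation,
    normalize_unit_area,
    process_acquisition,
    read_scan_stream,
    subtract_background,
    write_scan_stream,
)
from asapqc.errors import ProcessingError, ValidationError
from asapqc.simulate import AcquisitionConfig, generate_acquisition


def brute_force_detect(values, times, params: DetectionParams):
    """Independent loop-based reimplementation of the segmentation contract."""
    values = list(map(float, values))
    if params.baseline_fraction < 1.0:
        k = max(1, round(params.baseline_fraction * len(values)))
        subset = sorted(values)[:k]
    else:
        subset = values
    baseline = float(np.median(subset))
    mad = float(np.median([abs(v - baseline) for v in subset]))
    threshold = baseline + params.k_mad * mad

    runs, current = [], None
    for i, v in enumerate(values):
        if v > threshold:
            if current is None:
                current = [i, i + 1]
            else:
                current[1] = i + 1
        elif current is not None:
            runs.append(current)
            current = None
    if current is not None:
        runs.append(current)
    if not runs:
        return []

    merged = [runs[0]]
    for start, end in runs[1:]:
        if times[start] - times[merged[-1][1] - 1] < params.merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    period = float(np.median(np.diff(times)))
    out = []
    for start, end in merged:
        if times[end - 1] - times[start] + period >= params.min_window_s:
            out.append((start, end))
    return out


class TestIO:
    def test_csv_round_trip_preserves_stream(self, small_grid, tmp_path):
        stream = generate_acquisition(
            AcquisitionConfig(mz_grid=small_grid, rng_seed=4, baseline_noise_sd=0.0)
        )
        path = tmp_path / "stream.csv"
        write_scan_stream(stream, path)
        back = read_scan_stream(path)
        assert np.allclose(back.mz_grid, stream.mz_grid)
        assert np.allclose(back.times, stream.times)
        assert np.allclose(back.intensities, stream.intensities, rtol=1e-9)

    def test_shuffled_rows_read_identically(self, small_grid, tmp_path):
        stream = generate_acquisition(
            AcquisitionConfig(mz_grid=small_grid, rng_seed=4, baseline_noise_sd=0.0)
        )
        path = tmp_path / "stream.csv"
        write_scan_stream(stream, path)
        frame = pd.read_csv(path)
        shuffled = frame.sample(frac=1.0, random_state=1)
        shuffled.to_csv(tmp_path / "shuffled.csv", index=False)
        a = read_scan_stream(path)
        b = read_scan_stream(tmp_path / "shuffled.csv")
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.times, b.times)

    def test_empty_file_rejected_with_filename(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValidationError, match="empty.csv"):
            read_scan_stream(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("scan_index,time_s\n0,0.0\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_scan_stream(path)

    def test_out_of_range_bins_dropped(self, tmp_path):
        rows = ["scan_index,time_s,mz,intensity"]
        for i, t in enumerate((0.0, 0.9)):
            for mz in (5.0, 100.0, 200.0, 1500.0):
                rows.append(f"{i},{t},{mz},1.0")
        path = tmp_path / "ranged.csv"
        path.write_text("\n".join(rows) + "\n")
        stream = read_scan_stream(path)
        assert stream.mz_grid.tolist() == [100.0, 200.0]


class TestTIC:
    def test_single_scan_of_ones_sums_to_bin_count(self):
        grid = np.arange(10.0, 1001.0)
        stream = ScanStream(
            mz_grid=grid, times=[0.0], intensities=np.ones((1, grid.size))
        )
        assert compute_tic(stream).iloc[0] == 991.0

    def test_all_zero_scans_give_zero_series(self, small_grid):
        stream = ScanStream(
            mz_grid=small_grid,
            times=np.arange(5) * 0.9,
            intensities=np.zeros((5, small_grid.size)),
        )
        assert (compute_tic(stream).values == 0).all()

    def test_burst_argmax_inside_configured_insertion(self, small_grid):
        stream = generate_acquisition(
            AcquisitionConfig(mz_grid=small_grid, n_insertions=1, rng_seed=9)
        )
        tic = compute_tic(stream)
        win = next(w for w in stream.annotations["windows"] if w["kind"] == "sample")
        assert win["start_scan"] <= int(np.argmax(tic.values)) < win["end_scan"]


class TestDetection:
    def test_flat_tic_yields_no_windows(self):
        tic = pd.Series(np.full(50, 7.0), index=np.arange(50) * 0.9)
        assert detect_insertions(tic) == []

    def test_single_burst_window_matches_known_position(self):
        values = np.full(200, 10.0)
        values[50:80] += 1000.0 * np.exp(-np.arange(30) / 8.0)
        tic = pd.Series(values, index=np.arange(200) * 0.9)
        windows = detect_insertions(tic, first_is_background=False)
        assert len(windows) == 1
        assert windows[0].start_scan == 50

    def test_two_bursts_in_time_order_first_is_background(self):
        values = np.full(300, 10.0)
        values[40:70] += 500.0
        values[150:180] += 800.0 * np.exp(-np.arange(30) / 8.0)
        tic = pd.Series(values, index=np.arange(300) * 0.9)
        windows = detect_insertions(tic)
        assert [w.kind for w in windows] == ["background", "sample"]
        assert windows[0].start_scan < windows[1].start_scan

    def test_fewer_than_ten_scans_rejected(self):
        tic = pd.Series(np.arange(5.0), index=np.arange(5) * 0.9)
        with pytest.raises(ValidationError):
            detect_insertions(tic)

    def test_windows_nonoverlapping_and_ordered_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n = int(rng.integers(60, 300))
            values = rng.normal(20.0, 1.0, n).clip(min=0)
            for _ in range(int(rng.integers(0, 4))):
                start = int(rng.integers(0, n - 10))
                width = int(rng.integers(4, 40))
                values[start : start + width] += rng.uniform(50, 500)
            tic = pd.Series(values, index=np.arange(n) * 0.9)
            windows = detect_insertions(tic)
            for a, b in zip(windows, windows[1:]):
                assert a.end_scan <= b.start_scan

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(99)
        params = DetectionParams()
        for _ in range(50):
            n = int(rng.integers(60, 250))
            times = np.arange(n) * 0.9
            values = rng.normal(20.0, 1.0, n).clip(min=0)
            for _ in range(int(rng.integers(0, 4))):
                start = int(rng.integers(0, n - 10))
                width = int(rng.integers(4, 40))
                values[start : start + width] += rng.uniform(50, 500)
            got = detect_insertions(
                pd.Series(values, index=times), params, first_is_background=False
            )
            expected = brute_force_detect(values, times, params)
            assert [(w.start_scan, w.end_scan) for w in got] == expected


class TestReduction:
    def test_identical_scans_average_to_scan_with_zero_sd(self, small_grid):
        row = np.linspace(1, 5, small_grid.size)
        stream = ScanStream(
            mz_grid=small_grid,
            times=np.arange(4) * 0.9,
            intensities=np.tile(row, (4, 1)),
        )
        avg = average_window(stream, InsertionWindow(0, 4))
        assert np.allclose(avg.mean, row)
        assert np.allclose(avg.sd, 0.0)

    def test_two_point_mean_and_sd(self, small_grid):
        rows = np.ones((2, small_grid.size))
        rows[0, 0], rows[1, 0] = 1.0, 3.0
        stream = ScanStream(
            mz_grid=small_grid, times=[0.0, 0.9], intensities=rows
        )
        avg = average_window(stream, InsertionWindow(0, 2))
        assert avg.mean[0] == pytest.approx(2.0)
        assert avg.sd[0] == pytest.approx(np.sqrt(2.0))

    def test_average_matches_explicit_loop(self, small_grid):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, (20, small_grid.size))
        stream = ScanStream(
            mz_grid=small_grid, times=np.arange(20) * 0.9, intensities=X
        )
        avg = average_window(stream, InsertionWindow(3, 17))
        block = X[3:17]
        n = block.shape[0]
        mean = np.array([sum(block[:, j]) / n for j in range(block.shape[1])])
        sd = np.array(
            [
                (sum((block[i, j] - mean[j]) ** 2 for i in range(n)) / (n - 1)) ** 0.5
                for j in range(block.shape[1])
            ]
        )
        assert np.allclose(avg.mean, mean, atol=1e-12)
        assert np.allclose(avg.sd, sd, atol=1e-12)

    def test_single_scan_window_has_zero_sd(self, small_grid):
        stream = ScanStream(
            mz_grid=small_grid,
            times=[0.0],
            intensities=np.ones((1, small_grid.size)),
        )
        avg = average_window(stream, InsertionWindow(0, 1))
        assert (avg.sd == 0).all()

    def test_background_subtraction_policies(self, small_grid):
        mk = lambda v: AveragedSpectrum(  # noqa: E731
            mz_grid=small_grid, mean=np.full(small_grid.size, v), sd=np.zeros(small_grid.size), n_scans=3
        )
        assert np.allclose(subtract_background(mk(4.0), mk(4.0)), 0.0)
        assert np.allclose(subtract_background(mk(4.0), mk(0.0)), 4.0)
        assert np.allclose(subtract_background(mk(1.0), mk(2.0), clip_negative=True), 0.0)
        assert np.allclose(
            subtract_background(mk(1.0), mk(2.0), clip_negative=False), -1.0
        )
        other = AveragedSpectrum(
            mz_grid=small_grid + 1.0,
            mean=np.zeros(small_grid.size),
            sd=np.zeros(small_grid.size),
            n_scans=1,
        )
        with pytest.raises(ValidationError, match="grid"):
            subtract_background(mk(1.0), other)

    def test_normalize_unit_area_basic_and_errors(self):
        assert np.allclose(normalize_unit_area([2.0, 3.0, 5.0]), [0.2, 0.3, 0.5])
        v = np.array([0.25, 0.75])
        assert np.allclose(normalize_unit_area(v), v, atol=1e-12)
        with pytest.raises(ValidationError):
            normalize_unit_area(np.zeros(5))

    @given(
        v=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=50).filter(
            lambda v: sum(v) > 1e-6
        ),
        c=st.floats(1e-6, 1e6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_normalize_scale_invariance(self, v, c):
        v = np.asarray(v)
        assert np.allclose(
            normalize_unit_area(v), normalize_unit_area(c * v), rtol=1e-9, atol=1e-12
        )


class TestSaturationFlag:
    def _tic(self, values):
        return pd.Series(values, index=np.arange(len(values)) * 0.9)

    def test_decaying_burst_not_flagged(self):
        values = np.full(100, 10.0)
        values[20:50] += 1000.0 * np.exp(-np.arange(30) * 0.9 / 3.0)
        flagged, ratio = flag_saturation(self._tic(values), InsertionWindow(20, 50))
        assert not flagged
        assert ratio < 0.05

    def test_constant_elevated_tic_flagged(self):
        values = np.full(100, 10.0)
        values[20:50] += 1000.0
        flagged, ratio = flag_saturation(self._tic(values), InsertionWindow(20, 50))
        assert flagged
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_short_window_rejected(self):
        values = np.full(100, 10.0)
        with pytest.raises(ValidationError):
            flag_saturation(self._tic(values), InsertionWindow(20, 23))


class TestProcessAcquisition:
    def test_replicate_insertions_give_identical_spectra(self, small_grid):
        cfg = AcquisitionConfig(
            mz_grid=small_grid, n_insertions=5, baseline_noise_sd=0.0, rng_seed=0
        )
        result = process_acquisition(generate_acquisition(cfg))
        assert len(result.sample_spectra) == 5
        for s in result.sample_spectra:
            assert np.allclose(s.intensities, result.averaged.intensities, atol=1e-12)

    def test_recovers_generator_truth_spectrum(self, small_grid):
        cfg = AcquisitionConfig(mz_grid=small_grid, rng_seed=6)
        stream = generate_acquisition(cfg)
        result = process_acquisition(stream)
        truth = stream.annotations["true_sample_profile"]
        assert np.abs(result.averaged.intensities - truth).max() < 1e-4

    def test_saturated_stream_carries_flag(self, small_grid):
        cfg = AcquisitionConfig(
            mz_grid=small_grid, n_insertions=1, saturation=True, rng_seed=1
        )
        result = process_acquisition(generate_acquisition(cfg))
        assert "saturation" in result.averaged.qc_flags

    def test_no_background_window_rejected_with_hint(self, small_grid):
        stream = ScanStream(
            mz_grid=small_grid,
            times=np.arange(50) * 0.9,
            intensities=np.full((50, small_grid.size), 2.0),
        )
        with pytest.raises(ProcessingError, match="background"):
            process_acquisition(stream)

    def test_global_rescaling_leaves_output_unchanged(self, small_grid):
        cfg = AcquisitionConfig(mz_grid=small_grid, rng_seed=13)
        stream = generate_acquisition(cfg)
        scaled = ScanStream(
            mz_grid=stream.mz_grid,
            times=stream.times,
            intensities=stream.intensities * 37.5,
            source_id=stream.source_id,
        )
        a = process_acquisition(stream).averaged.intensities
        b = process_acquisition(scaled).averaged.intensities
        assert np.allclose(a, b, atol=1e-9)

    def test_all_spectra_unit_area_and_nonnegative(self, small_grid):
        cfg = AcquisitionConfig(mz_grid=small_grid, rng_seed=21, baseline_noise_sd=1.0)
        result = process_acquisition(generate_acquisition(cfg))
        for s in result.sample_spectra + [result.averaged]:
            assert abs(s.intensities.sum() - 1.0) < 1e-9
            assert (s.intensities >= 0).all()

    def test_mz_subrange_filter_applied_before_normalization(self, small_grid):
        cfg = AcquisitionConfig(mz_grid=small_grid, rng_seed=2, baseline_noise_sd=0.0)
        stream = generate_acquisition(cfg)
        result = process_acquisition(
            stream, params=ProcessParams(mz_range=(50.0, 150.0))
        )
        grid = result.averaged.mz_grid
        assert grid.min() >= 50.0 and grid.max() < 150.0
        assert abs(result.averaged.intensities.sum() - 1.0) < 1e-9
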