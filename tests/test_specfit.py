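"""Preprocessing, alignment, lipid handling and the constant-shape Voigt fit."""

import math

import numpy as np
import pytest

from lacdqf import specfit
from lacdqf.seqmodel import AcquisitionTag, TimingSchedule
from lacdqf.synthgen import (
    GroundTruth,
    SpectrumSeries,
    VoigtDoubletShape,
    generate_series,
    render_fid,
)


def _manual_series(fids, dwell=2.5e-4):
    tags = [
        AcquisitionTag(index=i, tag="fixed", tau1=22.8, wall_time=8.0 * i)
        for i in range(len(fids))
    ]
    return SpectrumSeries(np.asarray(fids), dwell, tags, "time")


class TestPreprocess:
    def test_zero_fill_doubles_points(self, noisy_small_series):
        out = specfit.preprocess(noisy_small_series, zf_factor=2)
        assert out.n_points == 2 * noisy_small_series.n_points
        assert out.domain == "frequency"

    def test_transform_round_trip_is_identity(self, noisy_small_series):
        out = specfit.preprocess(noisy_small_series, apod_hz=0.0, zf_factor=1)
        back = out.to_time()
        orig = noisy_small_series.data.copy()
        orig[:, 0] *= 0.5  # the first-point correction is part of the transform
        assert np.max(np.abs(back.data - orig)) < 1e-10

    def test_apodization_reduces_noise_by_matched_filter_factor(self):
        """10 Hz apodization shrinks the spectral noise SD by sqrt(sum w^2 / N)."""
        rng = np.random.default_rng(0)
        n = 1024
        dwell = 2.5e-4
        ratios = []
        for _ in range(10):
            noise = (rng.standard_normal((4, n)) + 1j * rng.standard_normal((4, n)))
            series = _manual_series(noise, dwell)
            raw = specfit.preprocess(series, apod_hz=0.0, zf_factor=1)
            apo = specfit.preprocess(series, apod_hz=10.0, zf_factor=1)
            ratios.append(np.std(apo.data.real) / np.std(raw.data.real))
        t = np.arange(n) * dwell
        w = np.exp(-math.pi * 10.0 * t)
        expected = math.sqrt(np.sum(w**2) / n)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)

    def test_zf_below_one_rejected(self, noisy_small_series):
        with pytest.raises(ValueError):
            specfit.preprocess(noisy_small_series, zf_factor=0)


class TestReferenceAlign:
    def test_constructed_shift_recovered_within_grid_step(self, small_schedule):
        gt = GroundTruth(seed=3, drift_hz_per_min=0.0, outlier_rate=0.0)
        series = generate_series(gt, small_schedule)
        shifted = series.copy_with(
            series.data * np.exp(2j * math.pi * 5.0 * np.arange(series.n_points) * series.dwell_s)
        )
        pre = specfit.preprocess(shifted)
        shift, _, ok = specfit.reference_align(pre, 0)
        step = abs(pre.hz_axis[1] - pre.hz_axis[0])
        assert ok
        assert shift == pytest.approx(5.0, abs=step)

    def test_aligned_spectrum_reports_near_zero_shift(self, noisy_small_series):
        pre = specfit.preprocess(noisy_small_series)
        shift, _, ok = specfit.reference_align(pre, 0)
        step = abs(pre.hz_axis[1] - pre.hz_axis[0])
        assert ok and abs(shift) < step

    def test_alignment_shrinks_peak_position_scatter_under_drift(self, small_schedule):
        gt = GroundTruth(seed=9, drift_hz_per_min=5.0, outlier_rate=0.0)
        series = generate_series(gt, small_schedule)
        pre = specfit.preprocess(series)
        aligned, shifts, _, _ = specfit.align_series(pre)

        def peak_positions(fs):
            win = fs.window_mask(3.03, 0.15)
            idx = np.nonzero(win)[0]
            return fs.hz_axis[idx[np.argmax(np.abs(fs.data[:, idx]), axis=1)]]

        assert np.std(peak_positions(aligned)) < 0.3 * np.std(peak_positions(pre))

    def test_missing_reference_flags_not_fails(self):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((3, 1024)) + 1j * rng.standard_normal((3, 1024))
        pre = specfit.preprocess(_manual_series(0.01 * noise))
        _, _, ok = specfit.reference_align(pre, 0)
        assert not ok


class TestLipidSubtraction:
    def test_lipid_only_spectrum_cleaned_below_5_percent(self):
        gt = GroundTruth(lipid_amp=1.0, snr=1e8, outlier_rate=0.0, drift_hz_per_min=0.0)
        fids = [render_fid(0.0, 0.0, gt.shape, gt) for _ in range(3)]
        pre = specfit.preprocess(_manual_series(fids))
        win_lip = pre.window_mask(1.5, 0.1)
        win_lac = pre.window_mask(1.3, 0.1)
        peak = np.abs(pre.data[0, win_lip].real).max()
        row, rec = specfit.subtract_lipid_residue(pre, 0)
        assert rec is not None
        assert np.abs(row[win_lac].real).max() < 0.05 * peak

    def test_opposite_phase_residue_recovered_within_10_degrees(self):
        gt = GroundTruth(lipid_amp=1.0, lipid_phase_deg=180.0, snr=1e8,
                         outlier_rate=0.0, drift_hz_per_min=0.0)
        fids = [render_fid(0.0, 0.0, gt.shape, gt) for _ in range(3)]
        pre = specfit.preprocess(_manual_series(fids))
        _, rec = specfit.subtract_lipid_residue(pre, 0)
        assert rec is not None
        phase_deg = math.degrees(rec["phase_rad"]) % 360.0
        assert min(abs(phase_deg - 180.0), abs(phase_deg - 180.0 - 360.0)) < 10.0

    def test_no_lipid_is_identity(self):
        gt = GroundTruth(lipid_amp=0.0, snr=1e8, outlier_rate=0.0, drift_hz_per_min=0.0)
        fids = [render_fid(1.0, 0.0, gt.shape, gt) for _ in range(3)]
        pre = specfit.preprocess(_manual_series(fids))
        row, rec = specfit.subtract_lipid_residue(pre, 0)
        assert rec is None
        assert np.array_equal(row, pre.data[0])


@pytest.fixture()
def window():
    f = np.linspace(-420.0, -360.0, 31)  # around 1.3 ppm at 7 T
    shape = VoigtDoubletShape(gauss_fwhm_hz=6.0, lorentz_fwhm_hz=8.0)
    return f, shape


class TestGridFit:

    def test_recovers_self_generated_amplitude_and_frequency(self, window):
        f, shape = window
        amp_grid = np.linspace(-2.0, 2.0, 41)
        freq_grid = np.linspace(-400.0, -380.0, 21)
        y = 1.3 * specfit.doublet_model(f, shape, freq_grid[7])
        amp, freq, cost = specfit.grid_fit_point(y, f, shape, amp_grid, freq_grid)
        assert freq == pytest.approx(freq_grid[7])
        assert amp == pytest.approx(1.3, abs=amp_grid[1] - amp_grid[0])

    def test_matches_brute_force_double_loop_exactly(self, window):
        f, shape = window
        rng = np.random.default_rng(12)
        amp_grid = np.linspace(-1.5, 1.5, 20)
        freq_grid = np.linspace(-405.0, -375.0, 20)
        y = 0.7 * specfit.doublet_model(f, shape, -391.0) + 0.05 * rng.standard_normal(f.size)
        got = specfit.grid_fit_point(y, f, shape, amp_grid, freq_grid)
        best = (np.inf, None, None)
        for f0 in freq_grid:
            m = specfit.doublet_model(f, shape, f0)
            for a in amp_grid:
                c = float(np.sum((y - a * m) ** 2))
                if c < best[0]:
                    best = (c, a, f0)
        assert got[0] == best[1]
        assert got[1] == best[2]
        assert got[2] == pytest.approx(best[0], rel=1e-12)

    def test_vectorized_path_agrees_with_grid_fit_point(self, window):
        f, shape = window
        rng = np.random.default_rng(5)
        amp_grid = np.linspace(-1.5, 1.5, 32)
        freq_grid = np.linspace(-405.0, -375.0, 15)
        y = np.stack([
            a * specfit.doublet_model(f, shape, -392.0) + 0.03 * rng.standard_normal(f.size)
            for a in (1.0, 0.4, -0.6)
        ])
        ai, fi, costs = specfit._series_grid_costs(y, f, shape, amp_grid, freq_grid)
        for s in range(3):
            amp, freq, cost = specfit.grid_fit_point(y[s], f, shape, amp_grid, freq_grid)
            assert amp_grid[ai[s]] == amp
            assert freq_grid[fi[s]] == freq
            assert costs[s] == pytest.approx(cost, rel=1e-9)

    def test_empty_grids_rejected(self, window):
        f, shape = window
        with pytest.raises(ValueError):
            specfit.grid_fit_point(np.zeros(f.size), f, shape, np.array([]), np.array([1.0]))

    def test_all_zero_spectrum_lands_on_smallest_amplitude_cost(self, window):
        f, shape = window
        amp_grid = np.linspace(0.0, 2.0, 21)
        freq_grid = np.linspace(-400.0, -380.0, 5)
        amp, _, cost = specfit.grid_fit_point(np.zeros(f.size), f, shape, amp_grid, freq_grid)
        assert amp == 0.0
        assert cost == 0.0


class TestFitSeries:
    def test_shape_constant_and_splitting_recovered(self, small_schedule):
        """Full pipeline (incl. lipid removal) pins the splitting to ~0.5 Hz."""
        from lacdqf import iocli

        gt = GroundTruth(seed=21, snr=24.0, outlier_rate=0.0)
        series = generate_series(gt, small_schedule)
        table, shape, _ = iocli.fit_spectra(series, seed=2)
        assert len(table) == series.n_spectra
        assert shape.splitting_hz == pytest.approx(gt.shape.splitting_hz, abs=0.5)

    def test_amplitude_scaling_equivariance(self, small_schedule):
        gt = GroundTruth(seed=8, snr=1e6, outlier_rate=0.0, drift_hz_per_min=0.0)
        series = generate_series(gt, small_schedule)
        pre = specfit.preprocess(series)
        k = 3.7
        scaled = pre.copy_with(pre.data * k)
        scaled.provenance.update(pre.provenance)
        _, fit1 = specfit.fit_series(pre, seed=4)
        _, fit2 = specfit.fit_series(scaled, seed=4)
        assert np.allclose(fit2.amplitudes, k * fit1.amplitudes, rtol=1e-3, atol=1e-6)

    def test_deterministic_under_seed(self, small_schedule):
        gt = GroundTruth(seed=13, outlier_rate=0.0)
        pre = specfit.preprocess(generate_series(gt, small_schedule))
        s1, f1 = specfit.fit_series(pre, seed=6)
        s2, f2 = specfit.fit_series(pre, seed=6)
        assert s1 == s2
        assert np.array_equal(f1.amplitudes, f2.amplitudes)

    def test_degenerate_series_rejected(self):
        gt = GroundTruth()
        fids = [render_fid(1.0, 0.0, gt.shape, gt) for _ in range(2)]
        pre = specfit.preprocess(_manual_series(fids))
        with pytest.raises(ValueError):
            specfit.fit_series(pre)


class TestMetrics:
    def test_snr_scales_with_amplitude(self):
        gt = GroundTruth(lipid_amp=0.0)
        rng = np.random.default_rng(2)
        noise = 0.5 * (rng.standard_normal((12, 1024)) + 1j * rng.standard_normal((12, 1024)))

        def series_with(amp):
            fids = [render_fid(amp, 0.0, gt.shape, gt) + n for n in noise]
            return _manual_series(fids)

        s1 = specfit.snr(series_with(40.0))
        s2 = specfit.snr(series_with(80.0))
        assert s2 / s1 == pytest.approx(2.0, rel=0.05)

    def test_lipid_suppression_identity_and_scaling(self):
        ppm = np.linspace(9.0, 0.0, 512)
        spec = np.exp(-((ppm - 1.51) ** 2) / 0.001) + 0.01
        r1, ok1 = specfit.lipid_suppression_factor(spec, spec, ppm)
        assert ok1 and r1 == pytest.approx(1.0)
        r2, ok2 = specfit.lipid_suppression_factor(spec, spec / 1000.0, ppm)
        assert ok2 and r2 == pytest.approx(1000.0)

    def test_near_zero_denominator_flagged(self):
        ppm = np.linspace(9.0, 0.0, 256)
        spec = np.exp(-((ppm - 1.51) ** 2) / 0.001)
        ratio, ok = specfit.lipid_suppression_factor(spec, np.zeros_like(spec), ppm)
        assert not ok
        assert math.isinf(ratio)
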