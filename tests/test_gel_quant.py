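import math

import numpy as np
import pytest

from tailprofiler.gel_quant import (
    LaneProfile,
    average_extension,
    calibrate_sizes,
    density_in_size_space,
    detect_markers,
    quantify_lanes,
    reference_size,
    subtract_background,
    SizeDensity,
)
from tailprofiler.synthetic_data import GelTruth, simulate_lane


class TestBackground:
    def test_constant_lane_goes_to_zero(self):
        out = subtract_background(LaneProfile(np.full(100, 100.0)))
        assert np.all(out.intensities == 0)

    def test_percentile_mean_subtracted_and_clipped(self):
        # P25 = 10, P50 = 20 -> background 15
        lane = LaneProfile(np.array([0.0, 10.0, 20.0, 30.0, 40.0]))
        out = subtract_background(lane)
        np.testing.assert_allclose(out.intensities, [0.0, 0.0, 5.0, 15.0, 25.0])

    def test_all_zero_lane_unchanged(self):
        out = subtract_background(LaneProfile(np.zeros(50)))
        assert np.all(out.intensities == 0)


class TestDetectMarkers:
    def _lane(self, centers, amplitude, n):
        px = np.arange(n, dtype=float)
        lane = np.zeros(n)
        for c in centers:
            lane += amplitude * np.exp(-0.5 * ((px - c) / 4.0) ** 2)
        return LaneProfile(lane)

    def test_five_gaussian_bands_within_one_pixel(self):
        centers = [150.0, 320.0, 500.0, 700.0, 880.0]
        found = detect_markers(self._lane(centers, 20000.0, 1000))
        assert len(found) == 5
        assert np.all(np.abs(found - np.array(centers)) <= 1.0)

    def test_threshold_scales_with_intensity_units(self):
        # the curvature cut is in raw intensity units: a 4x dimmer lane
        # needs a proportionally relaxed threshold to localize the same bands
        centers = [150.0, 320.0, 500.0, 700.0, 880.0]
        lane = self._lane(centers, 5000.0, 1000)
        assert detect_markers(lane).size == 0
        found = detect_markers(lane, d2_threshold=-25.0)
        assert len(found) == 5
        assert np.all(np.abs(found - np.array(centers)) <= 1.0)

    def test_flat_lane_no_detections(self):
        assert detect_markers(LaneProfile(np.zeros(200))).size == 0

    def test_overlapping_bands_merge_into_one(self):
        px = np.arange(400, dtype=float)
        lane = 20000.0 * (
            np.exp(-0.5 * ((px - 200) / 4.0) ** 2)
            + np.exp(-0.5 * ((px - 203) / 4.0) ** 2)
        )
        assert detect_markers(LaneProfile(lane)).size == 1

    def test_fewer_than_expected_raises(self):
        with pytest.raises(ValueError, match="manual"):
            detect_markers(LaneProfile(np.zeros(200)), expected_count=4)

    def test_window_longer_than_lane_raises(self):
        with pytest.raises(ValueError):
            detect_markers(LaneProfile(np.zeros(20)))


class TestCalibration:
    def test_spline_reproduces_knots_exactly(self):
        cal = calibrate_sizes([100, 200, 300, 400], [100.0, 80.0, 70.0, 65.0])
        np.testing.assert_allclose(cal.size_at([100, 200, 300, 400]), [100, 80, 70, 65])

    def test_linear_relation_reproduced_at_midpoints(self):
        pos = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        size = 120.0 - 0.1 * pos
        cal = calibrate_sizes(pos, size)
        assert cal.size_at(250.0) == pytest.approx(95.0)
        assert cal.position_at(95.0) == pytest.approx(250.0)

    def test_log_migration_model_within_half_nt(self):
        sizes = np.array([100.0, 90.0, 80.0, 70.0, 60.0])
        pos = 1400.0 - 900.0 * np.log(sizes)  # increasing position
        cal = calibrate_sizes(pos, sizes)
        mid_pos = 1400.0 - 900.0 * np.log(85.0)
        assert abs(float(cal.size_at(mid_pos)) - 85.0) < 0.5

    def test_non_monotone_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_sizes([1, 3, 2, 4], [90, 80, 70, 60])
        with pytest.raises(ValueError):
            calibrate_sizes([1, 2, 3, 4], [90, 80, 85, 60])
        with pytest.raises(ValueError):
            calibrate_sizes([1, 2, 3], [90, 80, 70])


def _affine_calibration():
    # position = 1400 - 12 * size over markers 60..100 nt
    sizes = [100.0, 90.0, 80.0, 70.0, 60.0]
    pos = [1400.0 - 12.0 * s for s in sizes]
    return calibrate_sizes(pos, sizes)


class TestSizeDensity:
    def test_total_intensity_conserved(self):
        cal = _affine_calibration()
        rng = np.random.default_rng(5)
        lane = LaneProfile(rng.random(2000) * 10)
        # whole-lane resampling conserves total intensity to within 0.1%
        dens_full = density_in_size_space(lane, cal)
        assert dens_full.total() == pytest.approx(lane.intensities.sum(), rel=1e-3)
        # windowed resampling matches the pixel mass inside the window
        # (up to the two half-covered edge pixels)
        dens = density_in_size_space(lane, cal, size_range=(55.0, 105.0))
        inside = lane.intensities[
            (np.arange(2000) >= cal.position_at(105.0))
            & (np.arange(2000) <= cal.position_at(55.0))
        ].sum()
        assert dens.total() == pytest.approx(inside, abs=10.0)

    def test_delta_band_mass_in_one_bin(self):
        cal = _affine_calibration()
        lane = np.zeros(2000)
        lane[int(1400 - 12 * 80.0)] = 1000.0  # single pixel at 80 nt
        # grid offset so the pixel sits wholly inside one 0.1-nt bin
        dens = density_in_size_space(LaneProfile(lane), cal, size_range=(75.05, 85.05))
        assert dens.total() == pytest.approx(1000.0)
        assert dens.density.max() == pytest.approx(1000.0)

    def test_uniform_position_intensity_maps_flat(self):
        cal = _affine_calibration()
        lane = np.zeros(2000)
        lo, hi = int(1400 - 12 * 60.0), int(1400 - 12 * 50.0)
        # uniform over positions mapping linearly onto [50, 60] nt
        lane[int(1400 - 12 * 60.0) : int(1400 - 12 * 50.0)] = 7.0
        dens = density_in_size_space(LaneProfile(lane), cal, size_range=(51.0, 59.0))
        interior = dens.density[5:-5]
        assert interior.std() / interior.mean() < 0.01


class TestAverageExtension:
    def _density(self, masses: dict[float, float]) -> SizeDensity:
        sizes = 70.0 + 0.1 * np.arange(200)  # 70..90 nt
        dens = np.zeros_like(sizes)
        for s, m in masses.items():
            dens[int(round((s - 70.0) / 0.1))] = m
        return SizeDensity(sizes, dens)

    def test_all_mass_at_reference_gives_zero(self):
        assert average_extension(self._density({76.0: 5.0}), r=76.0) == pytest.approx(0.0)

    def test_weighted_mean_of_two_bands(self):
        d = self._density({76.0: 1.0, 80.0: 1.0})
        assert average_extension(d, r=76.0) == pytest.approx(2.0, abs=1e-9)

    def test_degraded_mass_below_cutoff_excluded(self):
        d = self._density({76.0: 1.0, 71.0: 1.0})
        assert average_extension(d, r=76.0) == pytest.approx(0.0)

    def test_all_mass_degraded_returns_missing(self):
        d = self._density({71.0: 1.0})
        assert math.isnan(average_extension(d, r=76.0))

    def test_invariant_under_intensity_scaling(self):
        d = self._density({76.0: 1.0, 77.0: 2.5, 80.0: 0.5})
        scaled = SizeDensity(d.sizes, d.density * 2.0)
        assert average_extension(scaled, 76.0) == average_extension(d, 76.0)

    def test_shift_covariance(self):
        d = self._density({76.0: 1.0, 77.0: 2.5})
        shifted = SizeDensity(d.sizes, np.roll(d.density, 30))  # +3 nt
        assert average_extension(shifted, 76.0) == pytest.approx(
            average_extension(d, 76.0) + 3.0, abs=1e-9
        )


class TestEndToEnd:
    def test_two_band_mixture_recovered_within_tenth_nt(self):
        truth = GelTruth(band_sizes=(76.0, 77.0), band_fractions=(0.4, 0.6))
        ref_truth = GelTruth(band_sizes=(76.0,), band_fractions=(1.0,))
        lane, marker, _ = simulate_lane(truth, seed=1)
        ref_lane, _, _ = simulate_lane(ref_truth, seed=2)
        ext = quantify_lanes([ref_lane, lane], marker, truth.marker_sizes)
        assert abs(ext[0] - 0.0) < 0.05
        assert abs(ext[1] - 0.6) < 0.1

    def test_reference_size_from_peak_position(self):
        truth = GelTruth(band_sizes=(76.0,), band_fractions=(1.0,))
        lane, marker, _ = simulate_lane(truth, seed=3)
        positions = detect_markers(subtract_background(marker))
        cal = calibrate_sizes(sorted(positions), sorted(truth.marker_sizes, reverse=True))
        assert reference_size(subtract_background(lane), cal) == pytest.approx(76.0, abs=0.1)

    def test_band_below_cutoff_reports_missing(self):
        # all product mass 5 nt below the reference size
        ref_truth = GelTruth(band_sizes=(76.0,), band_fractions=(1.0,))
        deg_truth = GelTruth(band_sizes=(71.0,), band_fractions=(1.0,))
        ref_lane, marker, _ = simulate_lane(ref_truth, seed=4)
        deg_lane, _, _ = simulate_lane(deg_truth, seed=4)
        ext = quantify_lanes([ref_lane, deg_lane], marker, ref_truth.marker_sizes)
        assert math.isnan(ext[1])
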