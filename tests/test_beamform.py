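"""Delay-and-sum reconstruction: delay, summation, envelope, localization."""

import numpy as np
import pytest

import flexbeam as fb
from flexbeam.beamform import (
    DelayedRFCube,
    brightest_point,
    das_reconstruct,
    delay_rf,
    envelope_log,
    sum_channels,
)
from flexbeam.curvature import FocalGrid, ToFMap, compute_tof, sample_traces
from flexbeam.geometry import ArrayShape, element_positions
from flexbeam.phantom import PointPhantom, RFChannelData


class TestDelay:
    def test_constant_signal_passes_through(self, desk_spec):
        rf = RFChannelData(np.ones((64, 4, 4)), desk_spec.sampling_rate)
        times = np.full((8, 4, 4), 30 * desk_spec.dt)
        cube = delay_rf(rf, ToFMap(times, "flat"))
        np.testing.assert_allclose(cube.values, 1.0, atol=1e-12)

    def test_impulse_hit_exactly(self, desk_spec):
        x = np.zeros((64, 2, 2))
        x[17, 1, 0] = 3.5
        rf = RFChannelData(x, desk_spec.sampling_rate)
        times = np.full((4, 2, 2), 5 * desk_spec.dt)
        times[2, 1, 0] = 17 * desk_spec.dt
        cube = delay_rf(rf, ToFMap(times, "flat"))
        assert cube.values[2, 1, 0] == pytest.approx(3.5, abs=1e-12)

    def test_out_of_window_reads_are_zero_and_counted(self, desk_spec):
        rf = RFChannelData(np.ones((64, 2, 2)), desk_spec.sampling_rate)
        times = np.full((4, 2, 2), 200 * desk_spec.dt)  # beyond 64 samples
        out, n_out = sample_traces(rf, times, count_out_of_window=True)
        assert not out.any()
        assert n_out == times.size

    def test_matches_loop_oracle(self, desk_rf, desk_spec, desk_grid):
        layout = element_positions(desk_spec, ArrayShape.flat())
        tof = compute_tof(layout, desk_grid)
        cube = delay_rf(desk_rf, tof)
        rng = np.random.default_rng(3)
        x = desk_rf.samples.astype(float)
        fs = desk_spec.sampling_rate
        for _ in range(20):
            f = int(rng.integers(desk_grid.n_focal))
            ch = int(rng.integers(desk_spec.n_elements))
            s = int(rng.integers(desk_spec.n_elements))
            idx = tof.times[f, ch, s] * fs
            if idx > desk_rf.n_axial - 3 or idx < 1:
                continue
            i = int(np.floor(idx))
            t = idx - i
            p = x[i - 1:i + 3, ch, s]
            expect = 0.5 * (2 * p[1] + t * (p[2] - p[0])
                            + t**2 * (2 * p[0] - 5 * p[1] + 4 * p[2] - p[3])
                            + t**3 * (3 * (p[1] - p[2]) + p[3] - p[0]))
            assert cube.values[f, ch, s] == pytest.approx(expect, abs=1e-10)


class TestSum:
    def test_sum_of_ones(self):
        cube = DelayedRFCube(np.ones((8, 128, 4)))
        np.testing.assert_array_equal(sum_channels(cube), 128.0)

    def test_cancellation(self, rng):
        v = rng.normal(size=(8, 6, 4))
        both = DelayedRFCube(np.concatenate([v, -v], axis=1))
        np.testing.assert_allclose(sum_channels(both), 0.0, atol=1e-12)

    def test_matches_loop_summation(self, rng):
        v = rng.normal(size=(5, 7, 3))
        got = sum_channels(DelayedRFCube(v))
        expect = np.zeros((5, 3))
        for f in range(5):
            for s in range(3):
                for ch in range(7):
                    expect[f, s] += v[f, ch, s]
        np.testing.assert_allclose(got, expect, rtol=1e-14)


class TestEnvelope:
    def test_sinusoid_has_flat_envelope(self):
        t = np.arange(256)
        # an integer number of periods keeps the discrete analytic signal exact
        img = np.sin(2 * np.pi * 0.125 * t)[:, None] * np.ones((1, 4))
        b = envelope_log(img, dynamic_range=60.0)
        env_db = b.pixels[32:-32]  # away from Hilbert edge effects
        assert env_db.max() - env_db.min() < 20 * np.log10(1.01)

    def test_scale_invariance(self, rng):
        img = rng.normal(size=(64, 8))
        b1 = envelope_log(img)
        b2 = envelope_log(10.0 * img)
        np.testing.assert_allclose(b1.pixels, b2.pixels, atol=1e-9)
        assert b1.pixels.max() == pytest.approx(0.0)
        assert b1.pixels.min() >= -b1.dynamic_range

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            envelope_log(np.zeros((16, 4)))


class TestReconstruction:
    def test_point_targets_localized_within_1mm(self, desk_rf, desk_spec,
                                                desk_phantom, desk_grid):
        img = das_reconstruct(desk_rf, ArrayShape.flat(), desk_spec, desk_grid)
        lat, dep = brightest_point(img, desk_grid)
        d = np.min(np.linalg.norm(desk_phantom.scatterers[:, :2]
                                  - np.array([lat, dep]), axis=1))
        assert d <= 1.0
        # every scatterer has a nearby local maximum above -20 dB
        pix = img.pixels
        for x, z, _ in desk_phantom.scatterers:
            i = np.argmin(np.abs(desk_grid.depths - z))
            j = np.argmin(np.abs(desk_grid.lateral - x))
            window = pix[max(i - 6, 0):i + 7, max(j - 2, 0):j + 3]
            assert window.max() > -20.0

    def test_gt_cube_das_equals_flat_reference(self, desk_rf, desk_spec, desk_grid):
        """DAS of the ground-truth delayed cube equals delay-and-sum of the
        originating flat RF — same pipeline tail, pixelwise."""
        curved_rf, gt = fb.apply_artificial_curvature(desk_rf, 600.0, desk_spec,
                                                      desk_grid)
        ref = das_reconstruct(desk_rf, ArrayShape.flat(), desk_spec, desk_grid)
        via_gt = envelope_log(sum_channels(gt))
        np.testing.assert_allclose(via_gt.pixels, ref.pixels, atol=1e-9)

    def test_curved_reconstruction_round_trip(self, desk_rf, desk_spec):
        lat = element_positions(desk_spec, ArrayShape.flat()).lateral
        grid = FocalGrid(np.linspace(1.0, 4.6, 128), lat)
        curved_rf, _ = fb.apply_artificial_curvature(desk_rf, 600.0, desk_spec, grid)
        img_flat = das_reconstruct(desk_rf, ArrayShape.flat(), desk_spec, grid)
        img_curved = das_reconstruct(curved_rf, ArrayShape.convex(600.0),
                                     desk_spec, grid)
        rms = np.sqrt(np.mean((img_curved.pixels - img_flat.pixels) ** 2))
        peak_range = img_flat.pixels.max() - img_flat.pixels.min()
        assert rms < 0.02 * peak_range

    def test_wrong_geometry_degrades_localization(self, desk_spec):
        ph = PointPhantom(np.array([[0.0, 3.0, 1.0]]))
        acq = fb.AcquisitionConfig(noise_sigma=0.0, seed=0)
        rf = fb.simulate_acquisition(ph, desk_spec, ArrayShape.flat(), acq)
        lat = element_positions(desk_spec, ArrayShape.flat()).lateral
        grid = FocalGrid(np.linspace(1.0, 4.6, 128), lat)
        curved_rf, _ = fb.apply_artificial_curvature(rf, 300.0, desk_spec, grid)
        target = np.array([0.0, 3.0])

        def peak_err(image):
            return np.linalg.norm(np.array(brightest_point(image, grid)) - target)

        err_right = peak_err(das_reconstruct(curved_rf, ArrayShape.convex(300.0),
                                             desk_spec, grid))
        err_wrong = peak_err(das_reconstruct(curved_rf, ArrayShape.flat(),
                                             desk_spec, grid))
        assert err_wrong > err_right

    def test_linearity_of_delay_and_sum(self, desk_spec, desk_grid, rng):
        layout = element_positions(desk_spec, ArrayShape.flat())
        tof = compute_tof(layout, desk_grid)
        n = (desk_spec.n_axial_samples, desk_spec.n_elements, desk_spec.n_elements)
        a = RFChannelData(rng.normal(size=n), desk_spec.sampling_rate)
        b = RFChannelData(rng.normal(size=n), desk_spec.sampling_rate)
        ab = RFChannelData(a.samples + b.samples, desk_spec.sampling_rate)
        img_ab = sum_channels(delay_rf(ab, tof))
        img_sum = sum_channels(delay_rf(a, tof)) + sum_channels(delay_rf(b, tof))
        np.testing.assert_allclose(img_ab, img_sum, atol=1e-9)
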