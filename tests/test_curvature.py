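"""Time-of-flight maps, delay maps, and the artificial-curvature warp."""

import warnings

import numpy as np
import pytest

import flexbeam as fb
from flexbeam.curvature import (
    FocalGrid,
    compute_tof,
    default_focal_grid,
    delay_map,
    sample_traces,
    sweep_radii,
)
from flexbeam.geometry import ArrayShape, InvalidShapeError, TransducerSpec, element_positions
from flexbeam.phantom import RFChannelData, SPEED_OF_SOUND


def brute_force_tof(layout, lateral, depths, c):
    """Loop-based oracle for the two-way travel-time map."""
    n_f, n_el, n_s = len(depths), layout.n_elements, len(lateral)
    times = np.empty((n_f, n_el, n_s))
    for f in range(n_f):
        for ch in range(n_el):
            for s in range(n_s):
                q = np.array([lateral[s], depths[f]])
                d_tx = np.linalg.norm(layout.positions[s] - q)
                d_rx = np.linalg.norm(q - layout.positions[ch])
                times[f, ch, s] = (d_tx + d_rx) / c
    return times


class TestFocalGrid:
    def test_default_grid_shape(self):
        spec = fb.default_spec()
        grid = default_focal_grid(spec, 1024)
        assert grid.n_focal == 1024
        assert grid.n_scanlines == 128
        assert grid.depths[0] > 0
        assert np.all(np.diff(grid.depths) > 0)

    def test_degenerate_two_point_grid_spans_window(self, desk_spec):
        grid = default_focal_grid(desk_spec, 2)
        c = SPEED_OF_SOUND
        assert grid.depths[0] == pytest.approx(c * desk_spec.dt / 2)
        assert grid.depths[-1] == pytest.approx(c * desk_spec.record_duration / 2)

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            FocalGrid(np.array([1.0, 0.5]), np.zeros(2))
        with pytest.raises(ValueError):
            FocalGrid(np.array([0.0, 1.0]), np.zeros(2))


class TestToF:
    def test_on_axis_hand_computation(self):
        """Focal point 30 mm above the shared tx/rx element: 60 mm round trip."""
        spec = fb.default_spec()
        layout = element_positions(spec, ArrayShape.flat())
        grid = FocalGrid(np.array([15.0, 30.0]), layout.lateral)
        tof = compute_tof(layout, grid, 1.540)
        s = 64  # tx element == receive channel == scanline
        assert tof.times[1, s, s] == pytest.approx(60.0 / 1.540, rel=1e-12)

    def test_mirror_channels_equal_times(self):
        spec = TransducerSpec(n_elements=8, n_axial_samples=64)
        layout = element_positions(spec, ArrayShape.flat())
        grid = FocalGrid(np.array([2.0, 5.0]), layout.lateral)
        tof = compute_tof(layout, grid)
        # scanline between elements 3 and 4 is off-grid; use on-axis focal
        # point of scanline s and channels mirror-symmetric about it
        s = 3
        for off in (1, 2, 3):
            np.testing.assert_allclose(tof.times[:, s - off, s],
                                       tof.times[:, s + off, s], rtol=1e-14)

    def test_monotone_in_depth_for_flat(self, desk_spec, desk_grid):
        layout = element_positions(desk_spec, ArrayShape.flat())
        tof = compute_tof(layout, desk_grid)
        assert np.all(np.diff(tof.times, axis=0) > 0)

    @pytest.mark.parametrize("shape", [ArrayShape.flat(), ArrayShape.convex(600.0)])
    def test_matches_brute_force_on_toy(self, shape):
        spec = TransducerSpec(n_elements=8, n_axial_samples=64)
        layout = element_positions(spec, shape)
        depths = np.linspace(0.5, 6.0, 16)
        grid = FocalGrid(depths, layout.lateral)
        tof = compute_tof(layout, grid)
        oracle = brute_force_tof(layout, layout.lateral, depths, SPEED_OF_SOUND)
        assert np.abs(tof.times - oracle).max() < 1e-12

    def test_rejects_nonpositive_sound_speed(self, desk_spec, desk_grid):
        layout = element_positions(desk_spec, ArrayShape.flat())
        with pytest.raises(ValueError):
            compute_tof(layout, desk_grid, c=0.0)


class TestDelayMap:
    def test_identical_maps_give_zero_and_warn(self, desk_spec, desk_grid):
        layout = element_positions(desk_spec, ArrayShape.flat())
        tof = compute_tof(layout, desk_grid)
        with pytest.warns(UserWarning):
            dm = delay_map(tof, tof, desk_spec.sampling_rate)
        assert not dm.delta_samples.any()

    def test_flat_limit_small(self, desk_spec, desk_grid):
        flat = compute_tof(element_positions(desk_spec, ArrayShape.flat()), desk_grid)
        far = compute_tof(element_positions(desk_spec, ArrayShape.convex(1e9)),
                          desk_grid)
        dm = delay_map(far, flat, desk_spec.sampling_rate)
        assert np.abs(dm.delta_samples).max() < 0.01

    def test_edge_channel_matches_two_path_recomputation(self, desk_spec):
        layout_f = element_positions(desk_spec, ArrayShape.flat())
        layout_c = element_positions(desk_spec, ArrayShape.convex(600.0))
        grid = FocalGrid(np.array([1.0, 2.0]), layout_f.lateral)
        dm = delay_map(compute_tof(layout_c, grid), compute_tof(layout_f, grid),
                       desk_spec.sampling_rate)
        f, ch, s = 0, 0, desk_spec.n_elements - 1  # shallow, edge channel
        q = np.array([grid.lateral[s], grid.depths[f]])
        t_c = (np.linalg.norm(layout_c.positions[s] - q)
               + np.linalg.norm(q - layout_c.positions[ch])) / SPEED_OF_SOUND
        t_f = (np.linalg.norm(layout_f.positions[s] - q)
               + np.linalg.norm(q - layout_f.positions[ch])) / SPEED_OF_SOUND
        expect = (t_c - t_f) * desk_spec.sampling_rate
        assert dm.delta_samples[f, ch, s] == pytest.approx(expect, abs=1e-9)

    def test_monotone_curvature_effect(self, desk_spec, desk_grid):
        flat = compute_tof(element_positions(desk_spec, ArrayShape.flat()), desk_grid)
        prev = 0.0
        for r in (800.0, 600.0, 450.0, 300.0):
            curved = compute_tof(element_positions(desk_spec, ArrayShape.convex(r)),
                                 desk_grid)
            m = np.abs((curved.times - flat.times)
                       * desk_spec.sampling_rate).max()
            assert m > prev
            prev = m


class TestArtificialCurvature:
    def test_flat_limit_identity(self, desk_rf, desk_spec, desk_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curved, _ = fb.apply_artificial_curvature(desk_rf, 1e9, desk_spec,
                                                      desk_grid)
        peak = np.abs(desk_rf.samples).max()
        assert np.abs(curved.samples - desk_rf.samples).max() < 1e-6 * peak

    def test_integer_shift_impulse_train(self, desk_spec):
        """A constant integer-sample delay reduces the warp to index shifts."""
        n = desk_spec.n_axial_samples
        x = np.zeros((n, 1, 1))
        ks = [60, 150, 300]
        for k in ks:
            x[k, 0, 0] = 1.0
        rf = RFChannelData(x, desk_spec.sampling_rate)
        shift = 5  # samples
        t_nodes = np.linspace(0.2, desk_spec.record_duration, 64)
        times_flat = t_nodes[:, None, None]
        times_curved = times_flat + shift / desk_spec.sampling_rate
        from flexbeam.curvature import _warp_trace
        out = _warp_trace(x[:, 0, 0], rf.times, times_curved[:, 0, 0],
                          times_flat[:, 0, 0], desk_spec.sampling_rate, 0.0)
        # warped trace is the source advanced by exactly `shift` samples
        for k in ks:
            assert out[k + shift] == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(np.abs(out) > 1e-12) == len(ks)

    def test_round_trip_consistency(self, desk_rf, desk_spec):
        """Delaying the synthetic curved RF with the curved ToF reproduces the
        flat RF delayed with the flat ToF, on the physically imageable grid
        and within the recorded window."""
        lat = element_positions(desk_spec, ArrayShape.flat()).lateral
        grid = FocalGrid(np.linspace(1.0, 4.8, 128), lat)
        curved_rf, gt = fb.apply_artificial_curvature(desk_rf, 600.0, desk_spec,
                                                      grid)
        tof_c = compute_tof(element_positions(desk_spec, ArrayShape.convex(600.0)),
                            grid)
        tof_f = compute_tof(element_positions(desk_spec, ArrayShape.flat()), grid)
        redelayed = sample_traces(curved_rf, tof_c.times)
        n = desk_rf.n_axial
        fs = desk_spec.sampling_rate
        in_window = (tof_c.times * fs <= n - 1) & (tof_f.times * fs <= n - 1)
        diff = (redelayed - gt.values)[in_window]
        rel_rms = np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(gt.values[in_window]**2))
        assert rel_rms < 1e-2

    def test_energy_preserved_within_interpolation_loss(self, desk_rf, desk_spec,
                                                        desk_grid):
        curved, _ = fb.apply_artificial_curvature(desk_rf, 600.0, desk_spec,
                                                  desk_grid)
        ratio = float(np.sum(curved.samples.astype(float) ** 2)
                      / np.sum(desk_rf.samples.astype(float) ** 2))
        assert 0.95 < ratio < 1.05

    def test_rejects_nonpositive_radius(self, desk_rf, desk_spec, desk_grid):
        with pytest.raises(InvalidShapeError):
            fb.apply_artificial_curvature(desk_rf, -5.0, desk_spec, desk_grid)

    def test_warns_outside_feasible_range(self, desk_rf, desk_spec, desk_grid):
        with pytest.warns(UserWarning):
            fb.apply_artificial_curvature(desk_rf, 1000.0, desk_spec, desk_grid)


class TestSweep:
    @pytest.mark.parametrize(
        "r_min, r_max, step, expect",
        [
            (300.0, 800.0, 5.0, 101),
            (300.0, 300.0, 5.0, 1),
            (300.0, 310.0, 5.0, 3),
        ],
    )
    def test_radius_counts(self, r_min, r_max, step, expect):
        radii = sweep_radii(r_min, r_max, step)
        assert radii.size == expect
        assert radii[0] == r_min
        assert radii[-1] <= r_max

    def test_inclusive_endpoints(self):
        np.testing.assert_allclose(sweep_radii(300.0, 310.0, 5.0),
                                   [300.0, 305.0, 310.0])

    def test_pairs_tagged_and_normalized(self, desk_pairs):
        pairs = desk_pairs[0]
        assert [p.meta["radius_mm"] for p in pairs] == [300.0, 550.0, 800.0]
        for p in pairs:
            assert p.pre_delay.min() >= 0.0 and p.pre_delay.max() <= 1.0
            assert p.post_delay.min() >= 0.0 and p.post_delay.max() <= 1.0
            assert p.pre_delay.shape == p.post_delay.shape
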