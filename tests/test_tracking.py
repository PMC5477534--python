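"""3D bead localization: radial-symmetry XY, radial profiles, LUT z."""

import numpy as np
import pytest

import roadblock_smx as rb

PX = 72.5


def _frame(cfg, x_px=0.0, y_px=0.0, z=0.0, rng=None, t=0.0):
    img = rb.render_bead_image(cfg, x_px * PX, y_px * PX, z, rng=rng)
    return rb.ImageFrame(img, pixel_size=PX, timestamp=t)


class TestLocateXY:
    def test_exact_center_recovered_to_float_precision(self, noiseless_bead_config):
        x, y = rb.locate_xy(_frame(noiseless_bead_config))
        assert x == pytest.approx(31.5, abs=1e-6)
        assert y == pytest.approx(31.5, abs=1e-6)

    def test_subpixel_center_recovered(self, noiseless_bead_config):
        x, y = rb.locate_xy(_frame(noiseless_bead_config, x_px=0.8, y_px=0.2))
        assert x == pytest.approx(32.3, abs=0.02)
        assert y == pytest.approx(31.7, abs=0.02)

    def test_translation_equivariance(self):
        """Shifting a noiseless image by whole pixels shifts the output
        by exactly that amount (compact ring, so rolling moves no
        content across the border)."""
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        r = np.hypot(xx - 30.3, yy - 31.8)
        img = np.exp(-((r - 8.0) ** 2) / (2 * 3.0**2))  # ~0 well inside the frame
        x0, y0 = rb.locate_xy(img)
        shifted = np.roll(img, (3, -2), axis=(0, 1))  # rows +3 (y), cols -2 (x)
        x1, y1 = rb.locate_xy(shifted)
        assert x1 - x0 == pytest.approx(-2.0, abs=1e-6)
        assert y1 - y0 == pytest.approx(3.0, abs=1e-6)

    def test_constant_image_rejected(self):
        with pytest.raises(rb.ValidationError):
            rb.locate_xy(np.ones((32, 32)))

    def test_moderate_noise_rmse_below_tenth_of_a_pixel(self):
        """At the calibration noise level (ring amplitude / noise sd = 5)
        the lateral RMSE stays within 0.1 px (7.25 nm at 72.5 nm/px)."""
        cfg = rb.BeadImageConfig()  # amplitude 1.0, noise_sd 0.2
        rng = np.random.default_rng(6)
        sq = []
        for _ in range(200):
            dx, dy = rng.uniform(-0.5, 0.5, 2)
            img = rb.render_bead_image(cfg, dx * PX, dy * PX, 0.0, rng=rng)
            x, y = rb.locate_xy(img)
            sq.append((x - 31.5 - dx) ** 2 + (y - 31.5 - dy) ** 2)
        rmse = np.sqrt(np.mean(sq) / 2)
        assert rmse <= 0.10


class TestRadialProfile:
    def test_constant_image_gives_flat_profile(self):
        prof = rb.radial_profile(np.full((41, 41), 3.7), (20.0, 20.0))
        np.testing.assert_allclose(prof.intensity, 3.7)

    def test_ring_maximum_at_ring_radius(self):
        yy, xx = np.mgrid[0:41, 0:41].astype(float)
        r = np.hypot(xx - 20, yy - 20)
        img = np.exp(-((r - 8.0) ** 2) / 2.0)  # perfect ring at r0 = 8 px
        prof = rb.radial_profile(img, (20.0, 20.0))
        assert prof.radii[np.argmax(prof.intensity)] == pytest.approx(8.0, abs=1.0)

    def test_rotation_invariance(self, noiseless_bead_config):
        img = rb.render_bead_image(noiseless_bead_config, 0.0, 0.0, 400.0)
        p0 = rb.radial_profile(img, (31.5, 31.5))
        p90 = rb.radial_profile(np.rot90(img), (31.5, 31.5))
        np.testing.assert_allclose(p0.intensity, p90.intensity, atol=1e-10)

    def test_center_outside_frame_rejected(self):
        with pytest.raises(rb.ValidationError):
            rb.radial_profile(np.ones((32, 32)), (100.0, 10.0))


class TestEstimateZ:
    def test_grid_profiles_match_exactly(self, lut):
        """Brute force over every LUT entry: a profile equal to entry k
        returns z_k with zero SSD at k."""
        for k in range(len(lut.z_values)):
            prof = rb.RadialProfile(
                radii=np.arange(lut.profiles.shape[1], dtype=float),
                intensity=lut.profiles[k].copy(),
            )
            z, kk, ssd, at_edge = rb.estimate_z(prof, lut)
            assert kk == k
            assert ssd[k] == pytest.approx(0.0, abs=1e-18)
            assert z == pytest.approx(lut.z_values[k], abs=1e-9)
            assert at_edge == (k in (0, len(lut.z_values) - 1))

    def test_off_grid_heights_within_depth_resolution(self, noiseless_bead_config, lut):
        """Noiseless frames at heights between LUT planes are recovered
        within the 20 nm depth-resolution bound."""
        errs = []
        for zt in np.arange(-850.0, 851.0, 37.0):
            frame = _frame(noiseless_bead_config, z=zt)
            prof = rb.radial_profile(frame, rb.locate_xy(frame))
            z, _, _, at_edge = rb.estimate_z(prof, lut)
            assert not at_edge
            errs.append(z - zt)
        assert np.sqrt(np.mean(np.square(errs))) <= 20.0

    def test_symmetric_neighbors_give_grid_point(self, lut):
        """Equal SSD at both neighbors puts the parabola vertex exactly
        on the grid point (blend of two adjacent LUT profiles)."""
        k = 10
        blend = 0.5 * (lut.profiles[k - 1] + lut.profiles[k + 1])
        prof = rb.RadialProfile(
            radii=np.arange(lut.profiles.shape[1], dtype=float), intensity=blend
        )
        z, kk, ssd, _ = rb.estimate_z(prof, lut, normalize=False)
        assert kk == k
        assert ssd[k - 1] == pytest.approx(ssd[k + 1], rel=1e-9)
        assert z == pytest.approx(lut.z_values[k], abs=1e-6)

    def test_invariant_to_uniform_intensity_scaling(self, noiseless_bead_config, lut):
        frame = _frame(noiseless_bead_config, z=430.0)
        prof = rb.radial_profile(frame, rb.locate_xy(frame))
        scaled = rb.RadialProfile(prof.radii.copy(), 3.0 * prof.intensity + 1.0)
        z0, *_ = rb.estimate_z(prof, lut)
        z1, *_ = rb.estimate_z(scaled, lut)
        assert z1 == pytest.approx(z0, abs=1e-9)

    def test_edge_heights_flagged(self, noiseless_bead_config, lut):
        frame = _frame(noiseless_bead_config, z=-1000.0)
        prof = rb.radial_profile(frame, rb.locate_xy(frame))
        z, k, _, at_edge = rb.estimate_z(prof, lut)
        assert at_edge and k == 0 and z == lut.z_values[0]

    def test_binning_mismatch_rejected(self, lut):
        prof = rb.RadialProfile(
            radii=2.0 * np.arange(10, dtype=float), intensity=np.arange(10, dtype=float),
            bin_width=2.0,
        )
        with pytest.raises(rb.ValidationError, match="binning"):
            rb.estimate_z(prof, lut)

    def test_too_few_planes_rejected(self):
        with pytest.raises(rb.ValidationError):
            rb.LookupTable(
                z_values=np.array([0.0, 100.0]), profiles=np.ones((2, 10)), bin_width=1.0
            )


class TestTrack:
    def test_static_bead_yields_identical_positions(self, noiseless_bead_config, lut):
        frames = [_frame(noiseless_bead_config, z=200.0, t=i / 164.0) for i in range(5)]
        positions = rb.track(frames, lut)
        assert all(p.ok for p in positions)
        assert len({(p.x_nm, p.y_nm, p.z_nm) for p in positions}) == 1

    def test_z_ramp_recovered_monotone(self, noiseless_bead_config, lut):
        z_true = np.arange(-800.0, 801.0, 80.0)
        frames = [_frame(noiseless_bead_config, z=z, t=i / 164.0) for i, z in enumerate(z_true)]
        z_rec = np.array([p.z_nm for p in rb.track(frames, lut)])
        assert np.all(np.diff(z_rec) > 0)
        assert np.sqrt(np.mean((z_rec - z_true) ** 2)) <= 20.0

    def test_lateral_ramp_slope_within_two_percent(self, noiseless_bead_config, lut):
        x_true_px = np.linspace(-1.5, 1.5, 21)
        frames = [
            _frame(noiseless_bead_config, x_px=x, t=i / 164.0)
            for i, x in enumerate(x_true_px)
        ]
        x_rec = np.array([p.x_nm for p in rb.track(frames, lut)]) / PX
        slope = np.polyfit(np.arange(21), x_rec, 1)[0]
        true_slope = np.polyfit(np.arange(21), x_true_px, 1)[0]
        assert slope == pytest.approx(true_slope, rel=0.02)

    def test_failing_frame_flagged_not_dropped(self, noiseless_bead_config, lut):
        frames = [
            _frame(noiseless_bead_config, z=0.0, t=0.0),
            rb.ImageFrame(np.ones((64, 64)), pixel_size=PX, timestamp=1 / 164.0),
        ]
        positions = rb.track(frames, lut)
        assert len(positions) == 2
        assert positions[0].ok and not positions[1].ok
        assert positions[1].message


class TestTetherExtension:
    @staticmethod
    def _series(z_values, fs=164.0):
        return [
            rb.TrackedPosition(t=i / fs, x_nm=0.0, y_nm=0.0, z_nm=float(z), matched_index=0)
            for i, z in enumerate(z_values)
        ]

    def test_identical_series_give_zero(self):
        s = self._series(np.linspace(0, 100, 50))
        trace = rb.tether_extension(s, self._series(np.linspace(0, 100, 50)), sample_rate=164.0)
        np.testing.assert_allclose(trace.extension, 0.0, atol=1e-12)

    def test_reference_ramp_appears_negated(self):
        ramp = np.linspace(0.0, 500.0, 50)
        trace = rb.tether_extension(
            self._series(np.zeros(50)), self._series(ramp), sample_rate=164.0,
            baseline_samples=1,
        )
        np.testing.assert_allclose(trace.extension * 1e3, -ramp, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(rb.ValidationError):
            rb.tether_extension(
                self._series(np.zeros(10)), self._series(np.zeros(9)), sample_rate=164.0
            )


def test_end_to_end_rendered_trace_extension(noiseless_bead_config, lut):
    """Render a shortening tether plus a fixed reference bead, track
    both, and recover the programmed extension within 25 nm RMSE."""
    fs = 10.0
    z_teth = np.linspace(800.0, -800.0, 30)  # bead moving down as DNA shortens
    z_ref = np.full(30, 150.0)
    teth = rb.track([_frame(noiseless_bead_config, z=z, t=i / fs) for i, z in enumerate(z_teth)], lut)
    ref = rb.track([_frame(noiseless_bead_config, z=z, t=i / fs) for i, z in enumerate(z_ref)], lut)
    trace = rb.tether_extension(teth, ref, sample_rate=fs, baseline_samples=1)
    truth_um = (z_teth - z_teth[0]) / 1e3
    rmse_nm = np.sqrt(np.mean((trace.extension - truth_um) ** 2)) * 1e3
    assert rmse_nm <= 25.0
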