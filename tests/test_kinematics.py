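"""Velocity statistics, PIV, correlation profiles, and strain rates."""

import numpy as np
import pytest

from epijam.kinematics import (InsufficientDataError, VelocityField, XiStatus,
                               field_from_vectors, piv, strain_rate,
                               trajectory_velocities, velocity_correlation,
                               vrms, vrms_timecourse)
from epijam.phantoms import advect_texture, random_texture
from epijam.synthetic import (MonolayerConfig, correlated_velocity_field,
                              generate_static)

from oracles import brute_force_correlation


def uniform_field(vx, vy, n=8, spacing=10.0):
    vec = np.zeros((n, n, 2))
    vec[..., 0], vec[..., 1] = vx, vy
    return VelocityField((0.0, 0.0), spacing, vec, np.ones((n, n), bool))


class TestVrms:
    def test_uniform_three_four_field_gives_five(self):
        stats = vrms(uniform_field(3.0, 4.0))
        assert stats.v_rms == pytest.approx(5.0, abs=1e-12)
        assert stats.v_rms_mean_subtracted == pytest.approx(0.0, abs=1e-12)

    def test_zero_field_gives_zero(self):
        assert vrms(uniform_field(0.0, 0.0)).v_rms == 0.0

    def test_two_vector_hand_value(self):
        field = field_from_vectors(np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert vrms(field).v_rms == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_no_valid_vectors_raises(self):
        f = uniform_field(1.0, 0.0)
        f.valid[:] = False
        with pytest.raises(InsufficientDataError):
            vrms(f)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.5])
    def test_rotation_invariance_and_linear_scaling(self, rng, angle):
        vec = rng.normal(size=(6, 6, 2))
        f = VelocityField((0, 0), 5.0, vec, np.ones((6, 6), bool))
        c, s = np.cos(angle), np.sin(angle)
        rot = vec @ np.array([[c, -s], [s, c]]).T
        fr = VelocityField((0, 0), 5.0, rot, np.ones((6, 6), bool))
        assert vrms(fr).v_rms == pytest.approx(vrms(f).v_rms, rel=1e-12)
        f2 = VelocityField((0, 0), 5.0, 3.0 * vec, np.ones((6, 6), bool))
        assert vrms(f2).v_rms == pytest.approx(3.0 * vrms(f).v_rms, rel=1e-12)

    def test_vrms_bounds_spatial_mean(self, rng):
        vec = rng.normal(size=(6, 6, 2)) + 2.0
        f = VelocityField((0, 0), 5.0, vec, np.ones((6, 6), bool))
        stats = vrms(f)
        mean_mag = np.hypot(*vec.reshape(-1, 2).mean(axis=0))
        assert stats.v_rms >= mean_mag - 1e-12


class TestVelocityCorrelation:
    def test_zero_distance_bin_is_one(self, rng):
        f = VelocityField((0, 0), 10.0, rng.normal(size=(10, 10, 2)),
                          np.ones((10, 10), bool))
        prof = velocity_correlation(f)
        assert prof.c[0] == pytest.approx(1.0, abs=1e-6)
        assert np.nanmax(np.abs(prof.c)) <= 1.0 + 1e-6

    def test_uniform_field_is_degenerate(self):
        prof = velocity_correlation(uniform_field(2.0, 1.0))
        assert prof.status is XiStatus.INSUFFICIENT_DATA

    def test_binned_equals_all_pairs_oracle(self, rng):
        f = VelocityField((0, 0), 10.0, rng.normal(size=(12, 12, 2)),
                          np.ones((12, 12), bool))
        prof = velocity_correlation(f, r_max=55.0, bin_width=5.0)
        dv = f.vectors.reshape(-1, 2) - f.vectors.reshape(-1, 2).mean(axis=0)
        pts = f.node_positions().reshape(-1, 2)
        edges = np.arange(0.0, 60.0, 5.0)
        sums, counts = brute_force_correlation(pts, dv, edges)
        norm = np.mean(np.sum(dv ** 2, axis=1))
        expected = np.where(counts > 0, sums / np.maximum(counts, 1) / norm,
                            np.nan)
        assert np.array_equal(counts, prof.counts)
        assert np.allclose(prof.c[counts > 0], expected[counts > 0],
                           atol=1e-10)

    def test_white_noise_length_below_resolution(self):
        xis = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            f = VelocityField((0, 0), 10.0, rng.normal(size=(16, 16, 2)),
                              np.ones((16, 16), bool))
            prof = velocity_correlation(f)
            if prof.status is XiStatus.OK:
                xis.append(prof.xi_v_um)
        assert xis and np.median(xis) <= 1.5 * 10.0

    def test_rotation_invariance(self, rng):
        vec = rng.normal(size=(10, 10, 2))
        f = VelocityField((0, 0), 10.0, vec, np.ones((10, 10), bool))
        c, s = np.cos(0.7), np.sin(0.7)
        fr = VelocityField((0, 0), 10.0, vec @ np.array([[c, -s], [s, c]]).T,
                           np.ones((10, 10), bool))
        a, b = velocity_correlation(f), velocity_correlation(fr)
        assert np.allclose(a.c[a.counts > 0], b.c[b.counts > 0], atol=1e-10)

    def test_imposed_exponential_length_recovered(self):
        xis = []
        for seed in range(10):
            f = correlated_velocity_field(48, 10.0, 40.0, seed=seed)
            prof = velocity_correlation(f, r_max=160.0)
            assert prof.status is XiStatus.OK
            xis.append(prof.xi_v_um)
        assert abs(np.median(xis) - 40.0) / 40.0 < 0.15

    def test_r_max_beyond_half_extent_rejected(self):
        with pytest.raises(ValueError, match="half the field extent"):
            velocity_correlation(uniform_field(1.0, 0.0), r_max=1e4)


class TestStrainRate:
    def grid_field(self, fn, n=9, spacing=2.0):
        vec = np.zeros((n, n, 2))
        for i in range(n):
            for j in range(n):
                vec[i, j] = fn(j * spacing, i * spacing)
        return VelocityField((0.0, 0.0), spacing, vec, np.ones((n, n), bool))

    def test_pure_dilation(self):
        k = 0.3
        f = self.grid_field(lambda x, y: (k * x, k * y))
        sr = strain_rate(f)
        assert np.allclose(sr.isotropic[sr.valid], k, atol=1e-10)
        assert np.allclose(sr.deviatoric[sr.valid], 0.0, atol=1e-10)

    def test_simple_shear_frobenius_convention(self):
        gamma = 0.4
        f = self.grid_field(lambda x, y: (gamma * y, 0.0))
        sr = strain_rate(f)
        assert np.allclose(sr.isotropic[sr.valid], 0.0, atol=1e-10)
        assert np.allclose(sr.deviatoric[sr.valid], gamma / np.sqrt(2),
                           atol=1e-10)

    def test_simple_shear_max_shear_convention(self):
        gamma = 0.4
        f = self.grid_field(lambda x, y: (gamma * y, 0.0))
        sr = strain_rate(f, deviatoric_convention="max_shear")
        assert np.allclose(sr.deviatoric[sr.valid], gamma / 2.0, atol=1e-10)

    def test_rigid_rotation_is_strain_free(self):
        w = 0.25
        f = self.grid_field(lambda x, y: (-w * y, w * x))
        sr = strain_rate(f)
        assert np.allclose(sr.isotropic[sr.valid], 0.0, atol=1e-10)
        assert np.allclose(sr.deviatoric[sr.valid], 0.0, atol=1e-10)

    def test_decomposition_reconstructs_affine_gradient(self):
        # E = iso * I + dev_t must hold; on an affine field the fitted E is
        # exact, so iso and |dev| reconstruct its invariants to round-off
        a, b, c, d = 0.2, -0.1, 0.35, 0.05
        f = self.grid_field(lambda x, y: (a * x + b * y, c * x + d * y))
        sr = strain_rate(f)
        e = np.array([[a, (b + c) / 2], [(b + c) / 2, d]])
        iso = 0.5 * np.trace(e)
        dev = np.sqrt(((e - iso * np.eye(2)) ** 2).sum())
        assert np.allclose(sr.isotropic[sr.valid], iso, atol=1e-10)
        assert np.allclose(sr.deviatoric[sr.valid], dev, atol=1e-10)

    def test_sparse_patch_flagged_invalid(self):
        f = self.grid_field(lambda x, y: (x, y), n=5)
        f.valid[:, :] = False
        f.valid[2, 2] = True
        sr = strain_rate(f)
        assert not sr.valid.any()


class TestPiv:
    def test_identical_frames_give_zero_displacement(self):
        tex = random_texture((128, 128), seed=0, smooth_px=1.5)
        field = piv(tex, tex, window=32)
        v = field.valid_vectors()
        assert len(v) and np.allclose(v, 0.0, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same shape"):
            piv(np.zeros((64, 64)), np.zeros((64, 32)))

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            piv(np.zeros((16, 16)), np.zeros((16, 16)), window=32)

    def test_uniform_integer_shift_recovered(self):
        tex = random_texture((256, 256), seed=1, smooth_px=1.5)
        disp = np.zeros((256, 256, 2))
        disp[..., 0], disp[..., 1] = 3.0, -2.0
        shifted = advect_texture(tex, disp)
        field = piv(tex, shifted, window=32, dt_h=1.0, um_per_px=1.0)
        v = field.valid_vectors()
        # pixel y-down -> physical y-up flips the sign of dy
        err = np.hypot(v[:, 0] - 3.0, v[:, 1] - 2.0)
        assert (err <= 0.2).mean() >= 0.95

    def test_uncorrelated_noise_mostly_invalid(self):
        frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = piv(rng.normal(size=(128, 128)), rng.normal(size=(128, 128)),
                    window=32)
            frac.append(1.0 - f.valid.mean())
        assert np.mean(frac) >= 0.9


class TestVrmsTimecourse:
    def test_static_trajectory_gives_zero_series(self):
        run = generate_static(MonolayerConfig(n_cells=64, box_size=160.0,
                                              mode="static", noise_sigma=0.0,
                                              n_frames=12, seed=0))
        series = vrms_timecourse(run.traj, window=4)
        assert np.allclose(series["v_rms"], 0.0, atol=1e-12)

    def test_window_longer_than_series_rejected(self):
        run = generate_static(MonolayerConfig(n_cells=64, box_size=160.0,
                                              mode="static", n_frames=5,
                                              seed=0))
        with pytest.raises(InsufficientDataError):
            vrms_timecourse(run.traj, window=40)

    def test_constant_speed_fluid_series_is_flat(self, fluid_run):
        series = vrms_timecourse(fluid_run.traj, window=4)
        v0 = fluid_run.config.speed
        assert np.all(np.abs(series["v_rms"] - v0) / v0 < 0.05)


class TestTrajectoryVelocities:
    def test_lag_too_large_rejected(self, fluid_run):
        with pytest.raises(InsufficientDataError):
            trajectory_velocities(fluid_run.traj, lag=10**4)

    def test_periodic_wrap_handled(self):
        import pandas as pd

        from epijam.core import TrajectorySet
        df = pd.DataFrame({
            "frame": [0, 1], "time_h": [0.0, 1.0], "cell_id": [1, 1],
            "x_um": [99.0, 1.0], "y_um": [50.0, 50.0]})
        traj = TrajectorySet(df, box_size=100.0, periodic=True)
        _, vel = trajectory_velocities(traj)
        assert vel[0, 0, 0] == pytest.approx(2.0)
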