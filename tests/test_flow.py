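"""Flow reconstruction, streamlines, tracks, and track averaging."""

import numpy as np
import pytest

from swarmdrop.flow import (CellTrack, FlowField2D, comoving_streamlines,
                            generate_tracks, mean_velocity_field,
                            reconstruct_flow, track_velocities,
                            tracks_to_frame, vortex_summary)
from swarmdrop.grid import Grid1D
from swarmdrop.state import SwarmState


def cap_flow(ref, slip=None, frame="stationary", speed=0.0, U=1.0):
    """A travelling parabolic-cap droplet with TW flux Q = U (h - hs)."""
    from dataclasses import replace

    p = ref if slip is None else replace(ref, slip=slip)
    g = Grid1D.uniform(0.0, 12.0, 481)
    hs = p.precursor
    h = hs + np.clip(1.0 - ((g.x - 6.0) / 3.0) ** 2, 0.0, None)
    st = SwarmState(0.0, h, np.zeros(g.n), np.zeros(g.n))
    q = U * (h - hs)
    return reconstruct_flow(st, q, g, p, frame, speed), g, h, p


class TestReconstruction:
    def test_boundary_conditions_and_depth_average(self, ref):
        """Navier slip at the floor, stress-free surface, depth-average Q/h,
        each verified at 50 random columns to 1e-8."""
        fl, g, h, p = cap_flow(ref)
        rng = np.random.default_rng(5)
        cols = rng.choice(np.flatnonzero(h > 0.2), 50, replace=False)
        dz = 1e-4
        for i in cols:
            x0, h0 = g.x[i], h[i]
            # three-point one-sided stencils are exact for the parabola
            dudz0 = (-3 * fl.u(x0, 0.0) + 4 * fl.u(x0, dz)
                     - fl.u(x0, 2 * dz)) / (2 * dz)
            assert fl.u(x0, 0.0) == pytest.approx(p.slip * dudz0, abs=1e-8)
            dudzh = (3 * fl.u(x0, h0) - 4 * fl.u(x0, h0 - dz)
                     + fl.u(x0, h0 - 2 * dz)) / (2 * dz)
            assert abs(dudzh) < 1e-8
            from scipy.integrate import simpson

            z = np.linspace(0, h0, 101)
            depth_avg = simpson(fl.u(np.full_like(z, x0), z), x=z) / h0
            assert depth_avg == pytest.approx(fl.ubar[i], abs=1e-8)

    def test_noslip_profile_is_poiseuille_like(self, ref):
        fl, g, h, _ = cap_flow(ref, slip=0.0)
        i = int(np.argmax(h))
        assert fl.u(g.x[i], 0.0) == pytest.approx(0.0, abs=1e-12)
        # maximal at the free surface, 3/2 of the depth average
        assert fl.u(g.x[i], h[i]) == pytest.approx(1.5 * fl.ubar[i], rel=1e-9)

    def test_bad_frame_rejected(self, ref):
        with pytest.raises(ValueError):
            cap_flow(ref, frame="galilean")


class TestStreamlines:
    def test_travelling_cap_has_a_vortex(self, ref):
        fl, *_ = cap_flow(ref, frame="comoving", speed=1.0)
        ss = comoving_streamlines(fl, n_seeds=6)
        assert len(ss.stagnation_points) >= 1
        assert len(ss.periods) >= 1
        assert np.isfinite(ss.outer_period)

    def test_uniform_translation_has_no_orbits(self, ref):
        fl, g, h, p = cap_flow(ref, frame="comoving", speed=0.0, U=0.0)
        ss = comoving_streamlines(fl)
        assert ss.periods == [] and not np.isfinite(ss.outer_period)

    def test_orbit_period_tolerance_independent(self, ref):
        """Period changes < 1% across integration tolerances 1e-6..1e-9."""
        fl, *_ = cap_flow(ref, frame="comoving", speed=1.0)
        periods = [comoving_streamlines(fl, n_seeds=4, tol=tol).periods[0]
                   for tol in (1e-6, 1e-9)]
        assert abs(periods[1] - periods[0]) / periods[0] < 0.01

    def test_stationary_frame_rejected(self, ref):
        fl, *_ = cap_flow(ref, frame="stationary")
        with pytest.raises(ValueError):
            comoving_streamlines(fl)


class TestTracks:
    def test_same_seed_bit_identical(self, ref):
        fl, *_ = cap_flow(ref)
        t1 = generate_tracks(fl, 20, 0.3, 0.02, seed=42, t_end=1.0)
        t2 = generate_tracks(fl, 20, 0.3, 0.02, seed=42, t_end=1.0)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions, b.positions)

    def test_zero_motility_follows_streamlines(self, ref):
        """Pure advection: noiseless tracks track the integrated flow."""
        from scipy.integrate import solve_ivp

        fl, *_ = cap_flow(ref, frame="comoving", speed=1.0)
        tracks = generate_tracks(fl, 5, 0.0, 0.002, seed=1, t_end=1.0)
        for tr in tracks[:3]:
            sol = solve_ivp(lambda t, y: [float(fl.u(y[0], y[1])),
                                          float(fl.w(y[0], y[1]))],
                            (0, 1.0), tr.positions[0], rtol=1e-9, atol=1e-11,
                            dense_output=True)
            ref_pos = sol.sol(tr.times[-1])
            assert np.linalg.norm(tr.positions[-1] - ref_pos) < 0.02

    def test_ensemble_mean_matches_flow_displacement(self, ref):
        """Law of large numbers: noisy ensemble mean ~ advective drift."""
        fl, g, h, p = cap_flow(ref)
        x0r = (5.8, 6.2)
        tracks = generate_tracks(fl, 1000, 0.25, 0.01, seed=9, t_end=0.5,
                                 x_range=x0r)
        disp = np.array([tr.positions[-1, 0] - tr.positions[0, 0]
                         for tr in tracks])
        pure = generate_tracks(fl, 1000, 0.0, 0.01, seed=9, t_end=0.5,
                               x_range=x0r)
        drift = np.mean([tr.positions[-1, 0] - tr.positions[0, 0]
                         for tr in pure])
        se = disp.std() / np.sqrt(disp.size)
        assert abs(disp.mean() - drift) < 3 * se + 0.05 * abs(drift)

    def test_cells_stay_inside_film(self, ref):
        fl, g, h, p = cap_flow(ref)
        tracks = generate_tracks(fl, 50, 0.5, 0.01, seed=3, t_end=1.0)
        for tr in tracks:
            hx = np.interp(tr.x, g.x, h)
            assert np.all(tr.z >= -1e-12)
            assert np.all(tr.z <= hx + 1e-9)

    def test_cell_count_conserved(self, ref):
        fl, *_ = cap_flow(ref)
        tracks = generate_tracks(fl, 64, 0.2, 0.01, seed=2, t_end=0.5)
        assert len(tracks) == 64
        frame = tracks_to_frame(tracks)
        assert frame["TRACK_ID"].nunique() == 64


class TestTrackVelocities:
    def test_constant_velocity_exact(self):
        t = np.arange(0, 1, 0.1)
        tr = CellTrack(0, t, np.column_stack([2.0 * t, 0.5 * t]),
                       np.ones(t.size, bool))
        v = track_velocities(tr)
        np.testing.assert_allclose(v["vx"], 2.0, rtol=1e-12)
        np.testing.assert_allclose(v["vz"], 0.5, rtol=1e-12)

    def test_circular_track_speed_second_order(self):
        """Taylor oracle: speed error O(dt^2) against omega*r."""
        omega, r = 2.0, 1.5
        errs = []
        for dt in (0.05, 0.025):
            t = np.arange(0, 2, dt)
            pos = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t)])
            v = track_velocities(CellTrack(0, t, pos, np.ones(t.size, bool)))
            speed = np.hypot(v["vx"], v["vz"])[1:-1]
            errs.append(np.abs(speed - omega * r).max())
        assert errs[1] < 0.3 * errs[0]

    def test_two_point_track_flagged_low_confidence(self):
        tr = CellTrack(0, np.array([0.0, 1.0]),
                       np.array([[0.0, 0.0], [1.0, 0.5]]), np.ones(2, bool))
        v = track_velocities(tr)
        assert v["low_confidence"].all()
        assert v["vx"].iloc[0] == pytest.approx(1.0)


class TestMeanField:
    def test_noiseless_roundtrip_recovers_flow(self, ref):
        """The module's key oracle: tracks generated with zero motility,
        binned relative to the peak, reproduce the input u field within 5%."""
        fl, g, h, p = cap_flow(ref)
        xpk = g.x[int(np.argmax(h))]
        tracks = generate_tracks(fl, 600, 0.0, 0.01, seed=8, t_end=0.15)
        mf = mean_velocity_field(tracks, xpk, window=0.15, t_center=0.075,
                                 x_bins=np.linspace(-2.5, 2.5, 11),
                                 z_bins=np.linspace(0, 1.0, 6))
        # truth: the input flow evaluated at the very same sample positions
        samples = mf["samples"]
        ix = np.digitize(samples["x_rel"], mf["x_edges"]) - 1
        iz = np.digitize(samples["z"], mf["z_edges"]) - 1
        checked = 0
        for i in range(mf["x_edges"].size - 1):
            for j in range(mf["z_edges"].size - 1):
                if np.isnan(mf["u_mean"][i, j]):
                    continue
                m = (ix == i) & (iz == j)
                truth = float(np.mean(fl.u(xpk + samples.loc[m, "x_rel"],
                                           samples.loc[m, "z"])))
                if abs(truth) > 0.12:
                    assert mf["u_mean"][i, j] == pytest.approx(truth, rel=0.05,
                                                               abs=0.02)
                    checked += 1
        assert checked > 10

    def test_sparse_bins_masked_not_zeroed(self, ref):
        fl, g, h, p = cap_flow(ref)
        tracks = generate_tracks(fl, 10, 0.0, 0.01, seed=8, t_end=0.1)
        mf = mean_velocity_field(tracks, 6.0, window=0.1, t_center=0.05,
                                 x_bins=np.linspace(-6, 6, 40),
                                 z_bins=np.linspace(0, 1.0, 12),
                                 min_samples=5)
        assert np.isnan(mf["u_mean"]).any()
        assert not np.any(mf["u_mean"][mf["n_samples"] < 5] == 0.0)

    def test_surface_faster_than_floor_with_noise(self, ref):
        """Treadmilling ordering survives motility noise: top bins lead."""
        fl, g, h, p = cap_flow(ref, slip=0.1)
        xpk = g.x[int(np.argmax(h))]
        tracks = generate_tracks(fl, 800, 0.3, 0.01, seed=12, t_end=0.25)
        mf = mean_velocity_field(tracks, xpk, window=0.25, t_center=0.125,
                                 x_bins=np.linspace(-1.5, 1.5, 4),
                                 z_bins=np.linspace(0, 1.0, 5))
        u = mf["u_mean"]
        top = np.nanmean(np.abs(u[:, -2:]))
        bottom = np.nanmean(np.abs(u[:, :2]))
        assert top > bottom


class TestVortexSummary:
    def test_slab_factors_at_zero_slip(self, ref):
        """Uniform slab, slip = 0: floor curve 0, surface 1.5x mean."""
        from dataclasses import replace

        p = replace(ref, slip=0.0)
        g = Grid1D.uniform(0, 10, 101)
        h = np.full(101, 1.0)
        st = SwarmState(0.0, h, np.zeros(101), np.zeros(101))
        fl = reconstruct_flow(st, np.full(101, 0.8), g, p)
        vs = vortex_summary(fl, with_period=False)
        np.testing.assert_allclose(vs["floor"], 0.0, atol=1e-12)
        np.testing.assert_allclose(vs["surface"], 1.5 * 0.8, rtol=1e-9)
        assert np.all(vs["range"] >= 0)

    def test_comoving_summary_reports_circulation(self, ref):
        fl, *_ = cap_flow(ref, frame="comoving", speed=1.0)
        vs = vortex_summary(fl)
        assert np.isfinite(vs["circulation_period"])
        assert vs["circulation_period"] > 0
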