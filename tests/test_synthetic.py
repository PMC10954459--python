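"""Generator correctness: ideal helices, controlled bends, WLC sampling."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import bisect

import helixbend as hb
from helixbend.bending import bending_angle
from helixbend.forceext import eval_wlc_force


class TestIdealHelix:
    def test_straight_axis_and_length(self):
        f = hb.make_ideal_helix(hb.B_FORM, 11)
        assert np.allclose(f.centers[:, :2], 0.0)
        length = np.linalg.norm(f.centers[-1] - f.centers[0])
        assert length == pytest.approx(10 * hb.B_FORM.rise_nm)

    def test_whole_helix_bending_angle_is_zero(self, ideal_a):
        assert bending_angle(ideal_a) == pytest.approx(0.0, abs=1e-9)

    def test_phosphates_on_stated_radius(self, ideal_b):
        # direct point-to-line distance oracle against the z axis
        for s in range(2):
            p = ideal_b.phosphates[s]
            d = np.linalg.norm(p[:, :2], axis=1)  # axis is the z line
            assert np.all(np.abs(d - hb.B_FORM.radius_nm) < 1e-9)

    def test_consecutive_frames_differ_by_rise_and_twist(self, ideal_b):
        dz = np.diff(ideal_b.centers[:, 2])
        assert np.allclose(dz, hb.B_FORM.rise_nm)
        m = ideal_b.minor_axes
        ang = np.degrees(np.arctan2(
            np.einsum("ij,ij->i", np.cross(m[:-1], m[1:]), ideal_b.normals[:-1]),
            np.einsum("ij,ij->i", m[:-1], m[1:]),
        ))
        assert np.allclose(ang, hb.B_FORM.twist_deg)

    def test_inclination_equals_construction_constant(self, ideal_a, ideal_b):
        assert np.allclose(hb.inclination(ideal_a), 17.0, atol=1e-9)
        assert np.allclose(hb.inclination(ideal_b), -1.0, atol=1e-9)

    def test_too_short_helix_rejected(self):
        with pytest.raises(ValueError):
            hb.make_ideal_helix(hb.B_FORM, 3)


class TestBendHelix:
    def test_zero_bend_is_identity(self, ideal_b):
        out = hb.bend_helix(ideal_b, 0.0, "major")
        assert np.array_equal(out.centers, ideal_b.centers)
        assert np.array_equal(out.phosphates, ideal_b.phosphates)

    @pytest.mark.parametrize("theta", [5.0, 20.0, 40.0])
    @pytest.mark.parametrize("direction", ["major", "minor"])
    def test_measured_bend_matches_request(self, ideal_b, theta, direction):
        bent = hb.bend_helix(ideal_b, theta, direction)
        assert bending_angle(bent) == pytest.approx(theta, abs=0.1)

    def test_kink_mode_measured_angle(self, ideal_b):
        bent = hb.bend_helix(ideal_b, 25.0, "major", mode="kink")
        assert bending_angle(bent) == pytest.approx(25.0, abs=0.1)

    def test_inclination_sign_follows_groove_direction(self, ideal_b):
        piv = ideal_b.n_bp // 2
        inc0 = hb.inclination(ideal_b)[piv]
        up = hb.inclination(hb.bend_helix(ideal_b, 20.0, "major"))[piv]
        dn = hb.inclination(hb.bend_helix(ideal_b, 20.0, "minor"))[piv]
        assert up > inc0
        assert dn < inc0

    @pytest.mark.parametrize("theta", [10.0, 30.0])
    def test_strand_bond_geometry_conserved(self, ideal_b, theta):
        bent = hb.bend_helix(ideal_b, theta, "major")
        for s in range(2):
            d0 = np.linalg.norm(np.diff(ideal_b.phosphates[s], axis=0), axis=1)
            d1 = np.linalg.norm(np.diff(bent.phosphates[s], axis=0), axis=1)
            assert np.max(np.abs(d1 - d0) / d0) < 0.01

    def test_out_of_range_angle_rejected(self, ideal_b):
        with pytest.raises(ValueError):
            hb.bend_helix(ideal_b, 95.0, "major")
        with pytest.raises(ValueError):
            hb.bend_helix(ideal_b, -1.0, "major")


class TestWLCSampler:
    def test_round_trip_recovers_P(self):
        ens = hb.sample_wlc_angles(39.0, 3.3, 200_000, seed=2)
        fit = hb.fit_P_from_pdf(hb.angle_histogram(ens), 3.3)
        assert fit.P_nm == pytest.approx(39.0, rel=0.02)

    def test_stiff_limit_mean_angle_vanishes(self):
        ens = hb.sample_wlc_angles(1e4, 3.3, 20_000, seed=3)
        assert np.mean(ens.angles_deg) < 2.0

    def test_empirical_cdf_matches_quadrature_oracle(self):
        # independent oracle: adaptive quadrature of the target density
        P, Lc, n = 39.0, 3.3, 100_000
        dens = lambda t: np.sin(t) * np.exp(-P * t**2 / (2 * Lc))
        Z, _ = quad(dens, 0.0, np.pi)
        ens = hb.sample_wlc_angles(P, Lc, n, seed=4)
        theta = np.sort(np.radians(ens.angles_deg))
        probe = np.linspace(0.05, 1.2, 25)
        cdf_oracle = np.array([quad(dens, 0.0, t)[0] / Z for t in probe])
        cdf_emp = np.searchsorted(theta, probe) / n
        assert np.max(np.abs(cdf_emp - cdf_oracle)) < 0.005

    def test_seed_determinism(self):
        a = hb.sample_wlc_angles(50.0, 3.3, 1000, seed=9)
        b = hb.sample_wlc_angles(50.0, 3.3, 1000, seed=9)
        assert np.array_equal(a.angles_deg, b.angles_deg)

    def test_unbiased_over_replicates(self):
        # Monte-Carlo bias of the fitted P over independent replicates
        fits = []
        for s in range(20):
            ens = hb.sample_wlc_angles(47.0, 3.3, 20_000, seed=100 + s)
            fits.append(hb.fit_P_from_pdf(hb.angle_histogram(ens), 3.3).P_nm)
        assert abs(np.mean(fits) - 47.0) / 47.0 < 0.02

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hb.sample_wlc_angles(-1.0, 3.3, 10)
        with pytest.raises(ValueError):
            hb.sample_wlc_angles(39.0, 0.0, 10)


class TestTrajectory:
    def test_round_trip_persistence_length(self):
        cfg = hb.GeneratorConfig(seed=7, n_frames=20_000, n_bp=20, form_name="A",
                                 true_P_nm=55.0, bulk_mM=0, ext_occupancy=0,
                                 major_occupancy=0, minor_occupancy=0)
        traj = hb.sample_trajectory(cfg)
        ens = hb.collect_segments(traj, 13)
        fit = hb.fit_P_from_pdf(hb.angle_histogram(ens), ens.segment_Lc_nm)
        assert fit.P_nm == pytest.approx(55.0, rel=0.05)

    def test_single_frame_refuses_downstream_fit(self):
        cfg = hb.GeneratorConfig(seed=1, n_frames=1, n_bp=20, bulk_mM=0,
                                 ext_occupancy=0, major_occupancy=0, minor_occupancy=0)
        traj = hb.sample_trajectory(cfg)
        with pytest.raises(ValueError, match="insufficient"):
            hb.collect_segments(traj, 11)

    def test_same_seed_identical_output(self, quiet_config):
        import dataclasses
        cfg = dataclasses.replace(quiet_config, n_frames=50, bulk_mM=150.0,
                                  ext_occupancy=0.3)
        t1, t2 = hb.sample_trajectory(cfg), hb.sample_trajectory(cfg)
        assert np.array_equal(t1.centers, t2.centers)
        assert np.array_equal(t1.phosphates, t2.phosphates)
        assert np.array_equal(t1.ions.positions, t2.ions.positions)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hb.GeneratorConfig(ext_occupancy=1.5)
        with pytest.raises(ValueError):
            hb.GeneratorConfig(n_bp=2)


class TestForceExtensionGenerator:
    def test_extension_vanishes_at_low_force(self):
        with pytest.warns(UserWarning):
            c = hb.synth_force_extension(
                50.0, 1000.0, np.array([1e-4]), noise_x_nm=0.0
            )
        assert c.extension_nm[0] < 0.01 * 1000.0  # x -> 0 as F -> 0

    def test_solution_matches_bisection_oracle(self):
        P, Lc, T = 47.0, 4675.0, 295.0
        target = eval_wlc_force(P, Lc, 0.5 * Lc, T=T)
        c = hb.synth_force_extension(P, Lc, np.array([target]), noise_x_nm=0.0, T=T)
        # independent bisection on the force equation
        g = lambda u: eval_wlc_force(P, Lc, u * Lc, T=T) - target
        u_star = bisect(g, 1e-9, 1 - 1e-9, xtol=1e-13)
        assert c.extension_nm[0] == pytest.approx(u_star * Lc, abs=1e-8 * Lc)

    def test_forces_outside_window_flagged(self):
        with pytest.warns(UserWarning):
            c = hb.synth_force_extension(50.0, 1000.0, np.array([0.001, 1.0]),
                                         noise_x_nm=0.0)
        assert list(c.valid) == [False, True]


class TestIonPlacementInvariants:
    def test_charge_neutrality(self, ideal_b):
        cfg = hb.GeneratorConfig(seed=5, n_bp=20, ext_occupancy=0.4,
                                 major_occupancy=0.2, minor_occupancy=0.1,
                                 bulk_mM=200.0)
        ions = hb.place_ions(ideal_b, cfg, seed=8)
        _, q, _ = ions.frame(0)
        assert q.sum() + ideal_b.phosphate_charge * ideal_b.n_nt == 0.0

    def test_no_neutrality_constraint_for_neutral_duplex(self):
        frame = hb.make_ideal_helix(hb.B_FORM, 20, phosphate_charge=0.0)
        cfg = hb.GeneratorConfig(seed=5, n_bp=20, ext_occupancy=0.0,
                                 major_occupancy=0.0, minor_occupancy=0.0,
                                 bulk_mM=100.0, neutral_phosphates=True)
        _, q, _ = hb.place_ions(frame, cfg, seed=8).frame(0)
        assert q.sum() == 0.0  # bulk pairs only

    def test_empty_occupancies_give_no_bound_ions(self, ideal_b):
        cfg = hb.GeneratorConfig(seed=5, n_bp=20, ext_occupancy=0.0,
                                 major_occupancy=0.0, minor_occupancy=0.0,
                                 bulk_mM=0.0, neutral_phosphates=True)
        frame = hb.make_ideal_helix(hb.B_FORM, 20, phosphate_charge=0.0)
        ions = hb.place_ions(frame, cfg, seed=8)
        _, q, pos = ions.frame(0)
        assert pos.shape[0] == 0

    def test_box_too_small_raises(self, ideal_b):
        cfg = hb.GeneratorConfig(seed=5, n_bp=20, bulk_mM=150.0,
                                 box_margin_nm=0.1)
        import dataclasses
        cfg = dataclasses.replace(cfg, bulk_mM=50_000.0)
        with pytest.raises(ValueError, match="box too small"):
            hb.place_ions(ideal_b, cfg, seed=8)
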