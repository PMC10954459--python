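"""Inclination, axial groove widths, fluctuations and bend correlations."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import helixbend as hb
from helixbend.constants import HelixForm
from helixbend.geometry import (
    axial_groove_widths,
    fluctuation_profile,
    frame_bending_angles,
    helical_parameters,
    inclination,
    parameter_screen,
)
from conftest import random_rotation


class TestInclination:
    def test_construction_constants_recovered(self, ideal_a, ideal_b):
        assert np.allclose(inclination(ideal_a), 17.0, atol=1e-9)
        assert np.allclose(inclination(ideal_b), -1.0, atol=1e-9)

    def test_major_bend_raises_pivot_inclination(self, ideal_a):
        piv = 10
        bent = hb.bend_helix(ideal_a, 25.0, "major", pivot_step=piv)
        assert inclination(bent)[piv] > inclination(ideal_a)[piv]

    def test_matches_vector_projection_oracle(self, quiet_trajectory):
        frame = quiet_trajectory.frame(3)
        got = inclination(frame)
        # oracle: 90 deg minus angle(long axis, local tangent), signed
        d = np.diff(frame.centers, axis=0)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        t = np.vstack([d[0], (d[:-1] + d[1:]) / 2, d[-1]])
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        want = 90.0 - np.degrees(
            np.arccos(np.clip(np.einsum("ij,ij->i", frame.long_axes, t), -1, 1)))
        assert np.abs(got - want).max() < 1e-6

    def test_rigid_transform_invariance(self, ideal_a, rng):
        R = random_rotation(rng)
        moved = ideal_a.transformed(R, rng.normal(size=3) * 5)
        assert np.allclose(inclination(moved), inclination(ideal_a), atol=1e-9)


class TestGrooveWidths:
    def test_ideal_helix_total_equals_pitch(self, ideal_b):
        g = axial_groove_widths(ideal_b).finite()
        assert np.allclose(g.total_nm, hb.B_FORM.pitch_nm, atol=1e-3)
        assert np.std(g.total_nm) < 1e-9

    def test_groove_fractions_match_form(self, ideal_a, ideal_b):
        for frame, form in ((ideal_a, hb.A_FORM), (ideal_b, hb.B_FORM)):
            g = axial_groove_widths(frame).finite()
            assert np.allclose(g.minor_nm / g.total_nm, form.minor_fraction, atol=1e-6)

    def test_squeezing_minor_groove_preserves_total(self):
        squeezed_form = HelixForm(name="B", rise_nm=0.34, twist_deg=34.3,
                                  inclination_deg=-1.0, radius_nm=1.0,
                                  minor_fraction=0.28)
        base = axial_groove_widths(hb.make_ideal_helix(hb.B_FORM, 20)).finite()
        sq = axial_groove_widths(hb.make_ideal_helix(squeezed_form, 20)).finite()
        assert sq.minor_nm.mean() < base.minor_nm.mean()
        assert sq.major_nm.mean() > base.major_nm.mean()
        assert sq.total_nm.mean() == pytest.approx(base.total_nm.mean(), abs=1e-9)

    def test_perturbed_helix_matches_brute_force_oracle(self, rng):
        frame = hb.make_ideal_helix(hb.B_FORM, 24)
        frame.phosphates = frame.phosphates + rng.normal(0, 0.01, frame.phosphates.shape)
        got = axial_groove_widths(frame)
        # independent oracle: global-z cylindrical coordinates, explicit
        # per-segment crossing search on the unwrapped strand-1 backbone
        a1 = np.unwrap(np.arctan2(frame.phosphates[0, :, 1], frame.phosphates[0, :, 0]))
        a2 = np.unwrap(np.arctan2(frame.phosphates[1, :, 1], frame.phosphates[1, :, 0]))
        a2 += np.round((a1[0] - np.radians(hb.B_FORM.minor_gap_deg) - a2[0])
                       / (2 * np.pi)) * 2 * np.pi
        z1 = frame.phosphates[0, :, 2]
        z2 = frame.phosphates[1, :, 2]

        def crossing(target):
            for j in range(len(a2) - 1):
                if a2[j] <= target <= a2[j + 1]:
                    w = (target - a2[j]) / (a2[j + 1] - a2[j])
                    return z2[j] + w * (z2[j + 1] - z2[j])
            return np.nan

        for i in range(frame.n_bp):
            d_oracle = crossing(a1[i]) - z1[i]
            D_oracle = z1[i] - crossing(a1[i] - 2 * np.pi)
            if np.isfinite(d_oracle):
                assert got.minor_nm[i] == pytest.approx(d_oracle, abs=1e-6)
            if np.isfinite(D_oracle):
                assert got.major_nm[i] == pytest.approx(D_oracle, abs=1e-6)

    def test_short_helix_warns_truncated(self):
        frame = hb.make_ideal_helix(hb.B_FORM, 6)  # less than a turn
        with pytest.warns(UserWarning, match="full turn"):
            axial_groove_widths(frame)


class TestFluctuations:
    def test_rigid_helix_has_zero_fluctuation(self, ideal_b):
        traj = hb.HelixTrajectory(
            centers=np.repeat(ideal_b.centers[None], 3, axis=0),
            long_axes=np.repeat(ideal_b.long_axes[None], 3, axis=0),
            minor_axes=np.repeat(ideal_b.minor_axes[None], 3, axis=0),
            normals=np.repeat(ideal_b.normals[None], 3, axis=0),
            phosphates=np.repeat(ideal_b.phosphates[None], 3, axis=0),
        )
        prof = fluctuation_profile(traj, "total_groove_width")
        assert prof["mean"] == pytest.approx(0.0, abs=1e-9)
        prof = fluctuation_profile(traj, "inclination")
        assert prof["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_axial_noise_matches_direct_sd_oracle(self, rng):
        # axial shifts of strand-0 phosphates subtract exactly from the
        # minor width and add to the major width
        frame = hb.make_ideal_helix(hb.B_FORM, 24)
        delta = rng.normal(0, 0.05, frame.n_bp)
        frame.phosphates[0] += delta[:, None] * np.array([0.0, 0.0, 1.0])
        g = axial_groove_widths(frame)
        ok = np.isfinite(g.minor_nm) & np.isfinite(g.major_nm)
        assert np.std(g.minor_nm[ok], ddof=1) == pytest.approx(
            np.std(delta[ok], ddof=1), rel=1e-6)
        assert np.std(g.total_nm[ok], ddof=1) < 1e-9

    def test_unknown_observable_rejected(self, quiet_trajectory):
        with pytest.raises(ValueError, match="unknown observable"):
            fluctuation_profile(quiet_trajectory, "sugar_pucker")


class TestCorrelations:
    def test_perfect_linear_relations(self, quiet_trajectory):
        theta = frame_bending_angles(quiet_trajectory)
        r_up, _ = pearsonr(theta, 2 * theta + 1)
        r_dn, _ = pearsonr(theta, -theta)
        assert r_up == pytest.approx(1.0)
        assert r_dn == pytest.approx(-1.0)

    def test_report_matches_covariance_formula_oracle(self, quiet_trajectory):
        rep = hb.correlate_with_bend(quiet_trajectory, observables=("inclination",))
        theta = frame_bending_angles(quiet_trajectory)
        sds = fluctuation_profile(quiet_trajectory, "inclination")["per_frame_sd"]
        x, y = theta - theta.mean(), sds - sds.mean()
        oracle = float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))
        assert rep.r("sd_inclination") == pytest.approx(oracle, abs=1e-12)

    def test_constant_series_reported_missing(self, ideal_b):
        traj = hb.HelixTrajectory(
            centers=np.repeat(ideal_b.centers[None], 5, axis=0),
            long_axes=np.repeat(ideal_b.long_axes[None], 5, axis=0),
            minor_axes=np.repeat(ideal_b.minor_axes[None], 5, axis=0),
            normals=np.repeat(ideal_b.normals[None], 5, axis=0),
            phosphates=np.repeat(ideal_b.phosphates[None], 5, axis=0),
        )
        rep = hb.correlate_with_bend(traj, observables=("inclination",))
        assert np.isnan(rep.r("sd_inclination"))

    def test_groove_correlation_hierarchy(self):
        # generator couples bend to the total width: the total-width
        # fluctuation correlates more strongly than major-only, which
        # beats minor-only
        cfg = hb.GeneratorConfig(seed=11, n_frames=4000, n_bp=20, form_name="B",
                                 true_P_nm=48.0, bulk_mM=0, ext_occupancy=0,
                                 major_occupancy=0, minor_occupancy=0,
                                 groove_bend_coupling=6.0,
                                 groove_split_noise_nm=0.10)
        traj = hb.sample_trajectory(cfg)
        rep = hb.correlate_with_bend(traj)
        r_tot = rep.r("sd_total_groove_width")
        r_maj = rep.r("sd_major_groove_width")
        r_min = rep.r("sd_minor_groove_width")
        assert r_tot > r_maj > r_min > 0

    def test_inclination_pcc_scale_recovered(self):
        # default coupling/noise tuned so the inclination-fluctuation
        # correlation sits at the observed ~0.4 scale
        cfg = hb.GeneratorConfig(seed=42, n_frames=50_000, n_bp=20, form_name="B",
                                 true_P_nm=48.0, bulk_mM=0, ext_occupancy=0,
                                 major_occupancy=0, minor_occupancy=0)
        traj = hb.sample_trajectory(cfg)
        sds = fluctuation_profile(traj, "inclination")["per_frame_sd"]
        r, _ = pearsonr(frame_bending_angles(traj), sds)
        assert r == pytest.approx(0.40, abs=0.05)


class TestHelicalParameters:
    def test_ideal_helix_step_parameters(self, ideal_b):
        traj = hb.HelixTrajectory(
            centers=ideal_b.centers[None], long_axes=ideal_b.long_axes[None],
            minor_axes=ideal_b.minor_axes[None], normals=ideal_b.normals[None],
            phosphates=ideal_b.phosphates[None],
        )
        p = helical_parameters(traj)
        assert np.allclose(p["twist_deg"], hb.B_FORM.twist_deg, atol=1e-6)
        assert np.allclose(p["rise_nm"], hb.B_FORM.rise_nm, atol=1e-9)
        assert np.allclose(p["roll_deg"], 0.0, atol=1e-6)
        assert np.allclose(p["tilt_deg"], 0.0, atol=1e-6)
        assert np.allclose(p["shift_nm"], 0.0, atol=1e-9)
        assert np.allclose(p["slide_nm"], 0.0, atol=1e-9)

    def test_screen_reports_sixteen_observables(self, quiet_trajectory):
        rep = parameter_screen(quiet_trajectory)
        assert len(rep.table) == 16
        assert rep.table.r.abs().max() <= 1.0
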