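"""Axis extraction, segment angles, histograms and persistence fits."""

import numpy as np
import pytest

import helixbend as hb
from helixbend.bending import (
    BendingEnsemble,
    bending_angle,
    central_axis,
    collect_segments,
    step_tangents,
)
from conftest import random_rotation


class TestCentralAxis:
    def test_straight_helix_axis_collinear(self, ideal_b):
        ax = central_axis(ideal_b)
        d = ax - ax[0]
        t = d[-1] / np.linalg.norm(d[-1])
        off = d - np.outer(d @ t, t)
        assert np.abs(off).max() < 1e-6

    def test_kinked_helix_axis_has_one_kink_at_pivot(self, ideal_b):
        piv = 10
        bent = hb.bend_helix(ideal_b, 30.0, "major", pivot_step=piv, mode="kink")
        t = step_tangents(central_axis(bent, smooth_bp=1))
        turn = np.degrees(np.arccos(np.clip(
            np.einsum("ij,ij->i", t[:-1], t[1:]), -1, 1)))
        # all the turning is concentrated at the pivot step
        assert turn[piv - 1] + turn[piv] == pytest.approx(30.0, abs=0.1)
        mask = np.ones(turn.size, dtype=bool)
        mask[[piv - 1, piv]] = False
        assert np.abs(turn[mask]).max() < 1e-4

    def test_tangents_match_finite_difference_oracle(self, quiet_trajectory):
        frame = quiet_trajectory.frame(17)
        t = step_tangents(central_axis(frame, smooth_bp=1))
        # oracle: direct normalized differences of raw centers
        d = np.diff(frame.centers, axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", t, d), -1, 1)))
        assert ang.max() < 0.5

    def test_degenerate_centers_rejected(self, ideal_b):
        bad = ideal_b.copy()
        bad.centers[5] = bad.centers[6]
        with pytest.raises(ValueError, match="degenerate"):
            central_axis(bad)


class TestBendingAngle:
    def test_straight_segments_are_zero(self, ideal_a):
        for start, nbp in [(0, 20), (3, 13), (5, 8)]:
            assert bending_angle(ideal_a, start, nbp) == pytest.approx(0.0, abs=1e-9)

    def test_kink_inside_segment_measured(self, ideal_b):
        bent = hb.bend_helix(ideal_b, 25.0, "major", pivot_step=10, mode="kink")
        assert bending_angle(bent, 3, 14) == pytest.approx(25.0, abs=0.5)

    def test_matches_independent_tangent_dot_oracle(self, quiet_trajectory):
        frame = quiet_trajectory.frame(5)
        got = bending_angle(frame, 4, 11)
        c = frame.centers
        t0 = c[5] - c[4]
        t1 = c[14] - c[13]
        oracle = np.degrees(np.arccos(
            np.dot(t0, t1) / np.linalg.norm(t0) / np.linalg.norm(t1)))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_out_of_bounds_segment(self, ideal_b):
        with pytest.raises(IndexError):
            bending_angle(ideal_b, 15, 11)


class TestCollectSegments:
    def _window_oracle(self, n_total, n_seg, excl):
        # enumeration oracle over admissible window starts
        return [s for s in range(n_total)
                if s >= excl and s + n_seg <= n_total - excl]

    @pytest.mark.parametrize("n_seg,expected", [(13, 2), (11, 4)])
    def test_window_count_20bp(self, quiet_trajectory, n_seg, expected):
        ens = collect_segments(quiet_trajectory, n_seg, exclude_terminal=3)
        oracle = self._window_oracle(20, n_seg, 3)
        assert len(oracle) == expected
        assert ens.source["n_windows"] == expected
        assert len(ens) == expected * quiet_trajectory.n_frames

    def test_full_length_single_window(self, quiet_trajectory):
        ens = collect_segments(quiet_trajectory, 20, exclude_terminal=0)
        assert ens.source["n_windows"] == 1

    def test_segment_lc_uses_measured_rise(self, quiet_trajectory):
        ens = collect_segments(quiet_trajectory, 11)
        assert ens.segment_Lc_nm == pytest.approx(
            10 * quiet_trajectory.mean_rise(), rel=1e-12)

    def test_no_eligible_windows_rejected(self, quiet_trajectory):
        with pytest.raises(ValueError, match="no eligible"):
            collect_segments(quiet_trajectory, 15, exclude_terminal=3)

    def test_rotation_translation_invariance(self, rng):
        cfg = hb.GeneratorConfig(seed=5, n_frames=40, n_bp=20, bulk_mM=0,
                                 ext_occupancy=0, major_occupancy=0, minor_occupancy=0)
        traj = hb.sample_trajectory(cfg)
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        moved = hb.HelixTrajectory(
            centers=traj.centers @ R.T + shift,
            long_axes=traj.long_axes @ R.T,
            minor_axes=traj.minor_axes @ R.T,
            normals=traj.normals @ R.T,
            phosphates=traj.phosphates @ R.T + shift,
        )
        a = collect_segments(traj, 11).angles_deg
        b = collect_segments(moved, 11).angles_deg
        assert np.abs(a - b).max() < 1e-9


class TestHistogram:
    def test_normalization(self):
        ens = hb.sample_wlc_angles(47.0, 3.3, 5000, seed=1)
        h = hb.angle_histogram(ens)
        assert h.bin_width_deg == 0.5
        assert np.sum(h.p * h.bin_width_deg) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        ens = BendingEnsemble(angles_deg=np.array([]), segment_Lc_nm=3.3)
        with pytest.raises(ValueError):
            hb.angle_histogram(ens)


class TestPersistenceFits:
    def _analytic_hist(self, P, Lc, n_total=10**7):
        edges = np.arange(0.0, 180.5, 0.5)
        centers = np.radians(0.5 * (edges[:-1] + edges[1:]))
        pdf = np.sin(centers) * np.exp(-P * centers**2 / (2 * Lc))
        pdf /= pdf.sum() * 0.5
        counts = np.round(pdf * 0.5 * n_total).astype(int)
        return hb.AngleHistogram(edges_deg=edges, p=pdf, counts=counts)

    def test_exact_density_recovers_P(self):
        h = self._analytic_hist(39.0, 3.3)
        fit = hb.fit_P_from_pdf(h, 3.3)
        assert fit.P_nm == pytest.approx(39.0, rel=0.005)

    def test_sampled_ensemble_recovers_fixture_P(self):
        truth = hb.load_reference_values()["md_rna_nacl_150mM"]
        ens = hb.sample_wlc_angles(truth, 3.3, 200_000, seed=6)
        fit = hb.fit_P_from_pdf(hb.angle_histogram(ens), 3.3)
        assert fit.P_nm == pytest.approx(truth, rel=0.05)

    def test_uniform_on_sphere_gives_floppy_limit(self, rng):
        # p ~ sin(theta): P = 0 within error
        u = rng.random(200_000)
        theta = np.degrees(np.arccos(1 - 2 * u))
        ens = BendingEnsemble(angles_deg=theta, segment_Lc_nm=3.3)
        fit = hb.fit_P_from_pdf(hb.angle_histogram(ens), 3.3)
        assert abs(fit.P_nm) < 3 * fit.P_se_nm + 0.05

    def test_energy_route_equals_pdf_route(self):
        ens = hb.sample_wlc_angles(48.0, 3.3, 100_000, seed=8)
        h = hb.angle_histogram(ens)
        p1 = hb.fit_P_from_pdf(h, 3.3)
        p2 = hb.fit_P_from_energy(hb.bending_energy(h), 3.3)
        assert p2.P_nm == pytest.approx(p1.P_nm, rel=1e-9)

    def test_estimator_consistency_with_sample_size(self):
        # |bias| decreases in expectation as n grows, averaged over seeds
        biases = []
        for n in (10**3, 10**4, 10**5):
            fits = [
                hb.fit_P_from_pdf(
                    hb.angle_histogram(hb.sample_wlc_angles(47.0, 3.3, n, seed=s)),
                    3.3, min_count=5,
                ).P_nm
                for s in range(200, 220)
            ]
            biases.append(abs(np.mean(fits) - 47.0))
        assert biases[2] < biases[0]

    def test_too_few_bins_rejected(self):
        ens = hb.sample_wlc_angles(47.0, 3.3, 50, seed=1)
        with pytest.raises(ValueError):
            hb.fit_P_from_pdf(hb.angle_histogram(ens), 3.3)


class TestBendingEnergy:
    def test_profile_is_quadratic_for_exact_wlc(self):
        P, Lc = 47.0, 3.3
        edges = np.arange(0.0, 180.5, 0.5)
        centers = np.radians(0.5 * (edges[:-1] + edges[1:]))
        pdf = np.sin(centers) * np.exp(-P * centers**2 / (2 * Lc))
        pdf /= pdf.sum() * 0.5
        h = hb.AngleHistogram(edges_deg=edges, p=pdf,
                              counts=np.full(centers.size, 1000))
        prof = hb.bending_energy(h)
        expected = P * centers**2 / (2 * Lc)
        expected -= expected[np.nanargmin(prof.energy_kBT)]
        # equal up to the common normalization shift
        delta = prof.energy_kBT - expected
        assert np.nanstd(delta) < 1e-9

    def test_doubling_counts_leaves_profile_unchanged(self):
        ens = hb.sample_wlc_angles(47.0, 3.3, 20_000, seed=2)
        h = hb.angle_histogram(ens)
        h2 = hb.AngleHistogram(edges_deg=h.edges_deg, p=h.p, counts=2 * h.counts)
        a = hb.bending_energy(h).energy_kBT
        b = hb.bending_energy(h2).energy_kBT
        assert np.allclose(a, b, equal_nan=True)

    def test_empty_bins_masked_not_interpolated(self):
        ens = hb.sample_wlc_angles(47.0, 3.3, 1000, seed=3)
        prof = hb.bending_energy(hb.angle_histogram(ens))
        assert np.all(np.isnan(prof.energy_kBT[prof.counts == 0]))
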