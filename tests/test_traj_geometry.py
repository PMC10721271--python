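"""Trajectory geometry metrics against constructions and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from myorod import cc_builder as cb
from myorod import synthetic_data as sd
from myorod import traj_geometry as tg


def brute_dcom(ca, i):
    cen_a = ca[0, i - 3 : i + 4].mean(0)
    cen_b = ca[1, i - 3 : i + 4].mean(0)
    return np.linalg.norm(cen_a - cen_b)


def brute_heptad(ca, i):
    per_chain = [
        np.mean([np.linalg.norm(ca[c, j + 7] - ca[c, j]) for j in range(i - 3, i + 4)])
        for c in range(2)
    ]
    return np.mean(per_chain)


def brute_angle(ca, i):
    vals = []
    for c in range(2):
        v1 = ca[c, i - 7] - ca[c, i]
        v2 = ca[c, i + 7] - ca[c, i]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        vals.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return np.mean(vals)


class TestBurnIn:
    def test_zero_discard_is_identity(self, ideal_traj):
        out = tg.burn_in(ideal_traj, 0.0)
        assert out.n_frames == ideal_traj.n_frames

    def test_10ns_removes_first_100_frames_at_100ps(self):
        # 4 fs step, frames every 25,000 steps -> one frame per 100 ps
        assert 4e-3 * 25_000 == pytest.approx(100.0)  # ps
        ca = np.zeros((150, 2, 20, 3))
        traj = tg.CoiledCoilTrajectory(ca, np.arange(20), frame_interval_ps=100.0)
        out = tg.burn_in(traj, 10_000.0)
        assert out.n_frames == 50

    def test_discarding_everything_raises(self, ideal_traj):
        with pytest.raises(ValueError, match="entire trajectory"):
            tg.burn_in(ideal_traj, 1e9)


class TestDcom:
    def test_ideal_build_matches_closed_form(self, ideal_traj, canonical_params):
        # the two local helix axes sit at major_radius, separated by the
        # interchain rotation: D_com = 2 R sin(delta / 2)
        expected = (
            2
            * canonical_params.major_radius
            * np.sin(np.deg2rad(canonical_params.interchain_rotation / 2))
        )
        profile = tg.d_com_profile(ideal_traj)
        assert profile.mean.mean() == pytest.approx(expected, rel=0.01)

    def test_180_degree_dimer_gives_twice_major_radius(self):
        params = cb.CrickParameters(interchain_rotation=180.0)
        traj = sd.make_ideal_trajectory(params, cb.make_pattern(91), 1, 0.0)
        assert tg.d_com_profile(traj).mean.mean() == pytest.approx(9.8, rel=0.01)

    def test_translated_copy_gives_offset_everywhere(self):
        chain = np.cumsum(np.ones((30, 3)), axis=0)  # arbitrary open curve
        ca = np.stack([chain, chain + np.array([5.0, 0, 0])])[None]
        traj = tg.CoiledCoilTrajectory(ca, np.arange(1, 31))
        profile = tg.d_com_profile(traj)
        assert profile.mean == pytest.approx(np.full(24, 5.0))

    def test_static_trajectory_has_zero_sd(self, ideal_traj):
        repeated = tg.CoiledCoilTrajectory(
            np.repeat(ideal_traj.ca, 5, axis=0), ideal_traj.residue_numbers
        )
        assert tg.d_com_profile(repeated).sd == pytest.approx(np.zeros(85), abs=1e-12)

    def test_matches_brute_force(self, ideal_traj):
        mean, _ = tg.d_com(ideal_traj, int(ideal_traj.residue_numbers[45]))
        assert mean == pytest.approx(brute_dcom(ideal_traj.ca[0], 45))


class TestHeptadLength:
    def test_straight_helix_gives_seven_rises(self):
        # zero-supercoil limit: lab periodicity = frame periodicity (3.5),
        # so residues i and i+7 are exactly two turns apart along z
        params = cb.CrickParameters(residues_per_turn=3.5)
        traj = sd.make_ideal_trajectory(params, cb.make_pattern(91), 1, 0.0)
        profile = tg.heptad_length_profile(traj)
        assert profile.mean == pytest.approx(np.full(profile.mean.size, 7 * 1.495))

    def test_canonical_build_constant_and_above_chord_floor(self, ideal_traj):
        profile = tg.heptad_length_profile(ideal_traj)
        assert profile.mean.std() < 1e-6
        assert np.all(profile.mean > 7 * 1.495)

    def test_deletion_build_peaks_at_noncanonical_span(self):
        params = cb.CrickParameters()
        wt = sd.make_ideal_trajectory(params, cb.make_pattern(91), 1, 0.0)
        pattern = cb.make_pattern(91, deletion_sites=(46,))
        mut = sd.make_ideal_trajectory(params, pattern, 1, 0.0)
        wt_prof = tg.heptad_length_profile(wt)
        mut_prof = tg.heptad_length_profile(mut)
        # residue numbering differs downstream; compare deviation from the
        # canonical plateau instead
        plateau = wt_prof.mean.mean()
        deviation = np.abs(mut_prof.mean - plateau)
        span = pattern.noncanonical_spans()[0]
        peak_residue = mut_prof.residue_numbers[np.argmax(deviation)]
        assert span[0] <= peak_residue <= span[1] + 7

    def test_matches_brute_force(self, ideal_traj):
        mean, _ = tg.heptad_length(ideal_traj, 45)
        assert mean == pytest.approx(brute_heptad(ideal_traj.ca[0], 44))


class TestInterheptadAngle:
    def test_collinear_points_180(self):
        chain = np.zeros((30, 3))
        chain[:, 2] = np.arange(30)
        traj = tg.CoiledCoilTrajectory(
            np.stack([chain, chain + [3, 0, 0]])[None], np.arange(1, 31)
        )
        profile = tg.interheptad_angle_profile(traj)
        assert profile.mean == pytest.approx(np.full(16, 180.0))

    def test_right_angle_construction(self):
        chain = np.zeros((15, 3))
        chain[0] = [1, 0, 0]
        chain[14] = [0, 1, 0]
        traj = tg.CoiledCoilTrajectory(
            np.stack([chain, chain])[None], np.arange(1, 16)
        )
        mean, _ = tg.interheptad_angle(traj, 8)
        assert mean == pytest.approx(90.0)

    def test_canonical_build_slightly_below_180(self, ideal_traj):
        profile = tg.interheptad_angle_profile(ideal_traj)
        assert np.all(profile.mean < 180.0)
        assert np.all(profile.mean > 170.0)
        # the minor-helix phase repeats every 7 residues, so the small
        # supercoil-curvature deficit is 7-periodic along the chain
        assert profile.mean[7:] == pytest.approx(profile.mean[:-7], abs=1e-9)

    def test_matches_brute_force(self, ideal_traj):
        mean, _ = tg.interheptad_angle(ideal_traj, 45)
        assert mean == pytest.approx(brute_angle(ideal_traj.ca[0], 44))


class TestHelicity:
    def test_ideal_helix_fully_helical(self):
        traj = sd.make_helical_backbone(30)
        assert tg.helicity(traj) == pytest.approx([1.0, 1.0])

    def test_extended_backbone_not_helical(self):
        traj = sd.make_helical_backbone(30, phi=-120.0, psi=120.0)
        assert tg.helicity(traj) == pytest.approx([0.0, 0.0])

    def test_half_helical_chain(self):
        n = 32
        phi = np.where(np.arange(n) < n // 2, -62.0, -120.0)
        psi = np.where(np.arange(n) < n // 2, -41.0, 120.0)
        traj = sd.make_helical_backbone(n, phi=phi, psi=psi)
        frac = tg.helicity(traj)
        # interior residues only; the boundary residue mixes the two regimes
        assert frac == pytest.approx([0.5, 0.5], abs=2.0 / n)

    def test_requires_backbone(self, ideal_traj):
        with pytest.raises(ValueError, match="backbone"):
            tg.helicity(ideal_traj)


class TestAggregateRuns:
    def test_identical_runs_zero_sd(self, ideal_traj):
        p = tg.d_com_profile(ideal_traj)
        agg = tg.aggregate_runs([p, p, p])
        assert agg.sd == pytest.approx(np.zeros_like(p.sd))
        assert agg.mean == pytest.approx(p.mean)

    def test_hand_arithmetic(self):
        res = np.array([10])
        profiles = [
            tg.GeometryProfile("d_com", res, np.array([float(v)]), np.zeros(1))
            for v in (9, 10, 11)
        ]
        agg = tg.aggregate_runs(profiles)
        assert agg.mean[0] == pytest.approx(10.0)
        assert agg.sd[0] == pytest.approx(1.0)

    def test_between_run_sd_shrinks_with_jitter(self, canonical_params,
                                                canonical_pattern):
        def runs(jitter):
            profs = []
            for seed in range(3):
                traj = sd.make_ideal_trajectory(
                    canonical_params, canonical_pattern, 10, jitter, seed=seed
                )
                profs.append(tg.d_com_profile(traj))
            return tg.aggregate_runs(profs)

        loud = runs(0.5).sd.mean()
        quiet = runs(0.05).sd.mean()
        assert quiet < loud

    def test_mismatched_ranges_rejected(self, ideal_traj):
        p = tg.d_com_profile(ideal_traj)
        q = tg.GeometryProfile("d_com", p.residue_numbers[:-1], p.mean[:-1], p.sd[:-1])
        with pytest.raises(ValueError):
            tg.aggregate_runs([p, q])


class TestRigidBodyInvariance:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_metrics_invariant_under_rigid_transform(self, ideal_traj, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0, 20, 3)
        moved = tg.CoiledCoilTrajectory(
            ideal_traj.ca @ rot.T + shift, ideal_traj.residue_numbers
        )
        for metric in (
            tg.d_com_profile,
            tg.heptad_length_profile,
            tg.interheptad_angle_profile,
        ):
            assert metric(moved).mean == pytest.approx(
                metric(ideal_traj).mean, abs=1e-8
            )


class TestTrajectoryIO:
    def test_multi_model_roundtrip(self, canonical_params, canonical_pattern,
                                   tmp_path):
        traj = sd.make_ideal_trajectory(
            canonical_params, canonical_pattern, 4, 0.2, seed=5
        )
        path = tmp_path / "traj.pdb"
        tg.write_trajectory(traj, path)
        back = tg.read_trajectory(path)
        assert back.n_frames == 4
        assert back.ca == pytest.approx(traj.ca, abs=1.5e-3)
        assert np.array_equal(back.residue_numbers, traj.residue_numbers)

    def test_backbone_roundtrip(self, tmp_path):
        traj = sd.make_helical_backbone(20, n_frames=3, jitter_sd=0.1, seed=2)
        path = tmp_path / "bb.pdb"
        tg.write_trajectory(traj, path)
        back = tg.read_trajectory(path)
        assert back.has_backbone
        assert tg.helicity(back) == pytest.approx(tg.helicity(traj), abs=0.05)
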