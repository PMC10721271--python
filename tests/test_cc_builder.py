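"""Coiled-coil builder: motif-pattern arithmetic and model geometry."""

import numpy as np
import pytest

from myorod import cc_builder as cb


def window_centroids(chain: np.ndarray) -> np.ndarray:
    """Brute-force 7-Calpha window centroids (local helix-axis points)."""
    return np.stack([chain[i - 3 : i + 4].mean(0) for i in range(3, len(chain) - 3)])


class TestMakePattern:
    def test_thirteen_heptads_tile_91_residues(self):
        pattern = cb.make_pattern(91)
        assert len(pattern.motifs) == 13
        assert all(m.kind is cb.MotifKind.CANONICAL for m in pattern.motifs)
        assert pattern.total_length == 91

    def test_skip_motif_replaces_four_heptads_with_29_residues(self):
        pattern = cb.make_pattern(91, skip_sites=(46,))
        skips = [m for m in pattern.motifs if m.kind is cb.MotifKind.SKIP]
        assert len(skips) == 1
        assert skips[0].length == 29 and skips[0].turns == 8
        assert pattern.total_length == 92  # one extra residue vs canonical

    def test_deletion_motif_is_27_residues_one_shorter_than_canonical(self):
        pattern = cb.make_pattern(91, deletion_sites=(46,))
        dels = [m for m in pattern.motifs if m.kind is cb.MotifKind.DELETION]
        assert len(dels) == 1
        assert dels[0].length == 27 and dels[0].turns == 8
        assert pattern.total_length == 90

    def test_remainder_becomes_partial_motif(self):
        pattern = cb.make_pattern(93)
        assert pattern.motifs[-1].kind is cb.MotifKind.PARTIAL
        assert pattern.motifs[-1].length == 2
        assert pattern.total_length == 93

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cb.make_pattern(91, skip_sites=(40,), deletion_sites=(46,))

    def test_site_too_close_to_end_rejected(self):
        with pytest.raises(ValueError, match="too close"):
            cb.make_pattern(14, skip_sites=(7,))


class TestLocalWinding:
    def test_canonical_supercoil_rate_left_handed(self, canonical_params):
        omega0, periodicity = cb.local_winding(cb.make_pattern(91), canonical_params)
        expected = 360.0 * (1.0 / 3.617 - 1.0 / 3.5)  # approx -3.33 deg/res
        assert omega0 == pytest.approx(np.full(91, expected))
        assert np.all(omega0 < 0)  # left-handed
        assert periodicity == pytest.approx(np.full(91, 3.5))

    def test_deletion_motif_overwinds(self, canonical_params):
        pattern = cb.make_pattern(91, deletion_sites=(46,))
        omega0, periodicity = cb.local_winding(pattern, canonical_params)
        span = pattern.noncanonical_spans()[0]
        inside = np.abs(omega0[span[0] : span[1]])
        outside = np.abs(omega0[: span[0]])
        assert np.all(periodicity[span[0] : span[1]] == pytest.approx(27 / 8))
        assert inside.min() > outside.max()

    def test_zero_supercoil_when_frame_matches_lab_periodicity(self):
        params = cb.CrickParameters(residues_per_turn=3.5)
        omega0, _ = cb.local_winding(cb.make_pattern(91), params)
        assert omega0 == pytest.approx(np.zeros(91), abs=1e-12)


class TestBuildGeometry:
    def test_axial_rise_per_residue(self, canonical_model):
        for chain in canonical_model.coords:
            slope = np.polyfit(np.arange(len(chain)), chain[:, 2], 1)[0]
            assert slope == pytest.approx(1.495, rel=1e-6)

    def test_major_radius_from_axis_points(self, canonical_model):
        for chain in canonical_model.coords:
            cen = window_centroids(chain)
            radius = np.hypot(cen[:, 0], cen[:, 1]).mean()
            assert radius == pytest.approx(4.9, rel=0.01)

    def test_interchain_rotation_is_210_degrees(self, canonical_model):
        a, b = canonical_model.coords
        ca, cbn = window_centroids(a), window_centroids(b)
        delta = np.arctan2(cbn[:, 1], cbn[:, 0]) - np.arctan2(ca[:, 1], ca[:, 0])
        mean_offset = np.rad2deg(np.angle(np.exp(1j * delta).mean())) % 360
        assert mean_offset == pytest.approx(210.0, abs=1e-6)

    def test_lab_frame_periodicity_recovered(self, canonical_model):
        chain = canonical_model.coords[0]
        cen = window_centroids(chain)
        d = chain[3:-3] - cen
        theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
        slope = np.polyfit(np.arange(3, len(chain) - 3), theta, 1)[0]
        assert 2 * np.pi / slope == pytest.approx(3.617, rel=0.01)

    def test_radial_distance_periodic_with_frame_periodicity(self, canonical_model):
        # exactly superhelical: |Ca| from the z axis repeats every 7 residues
        # (two full turns of the 3.5-residue frame periodicity)
        r = np.hypot(*canonical_model.coords[0][:, :2].T)
        assert r[7:] == pytest.approx(r[:-7], abs=1e-9)

    def test_consecutive_ca_distances_physical(self, canonical_model):
        for chain in canonical_model.coords:
            d = np.linalg.norm(np.diff(chain, axis=0), axis=1)
            assert np.all(np.abs(d - 3.8) < 0.3)

    def test_major_helix_azimuth_decreases(self, canonical_model):
        chain = canonical_model.coords[0]
        cen = window_centroids(chain)
        theta = np.unwrap(np.arctan2(cen[:, 1], cen[:, 0]))
        assert np.polyfit(np.arange(len(theta)), theta, 1)[0] < 0

    def test_deletion_build_identical_upstream_of_span(self):
        params = cb.CrickParameters(smoothing_b=0.0)
        wt = cb.build(params, cb.make_pattern(91))
        mut_pattern = cb.make_pattern(91, deletion_sites=(60,))
        mut = cb.build(params, mut_pattern)
        start = mut_pattern.noncanonical_spans()[0][0]
        assert mut.coords[:, :start] == pytest.approx(wt.coords[:, :start])
        assert not np.allclose(
            mut.coords[:, start : start + 27], wt.coords[:, start : start + 27]
        )

    def test_smoothing_perturbs_only_near_motif_boundaries(self):
        # with b = 0.03 the Gaussian width is ~2.7 residues: far upstream of
        # the noncanonical span the build still matches the canonical one
        params = cb.CrickParameters()
        wt = cb.build(params, cb.make_pattern(91))
        mut_pattern = cb.make_pattern(91, deletion_sites=(74,))
        mut = cb.build(params, mut_pattern)
        start = mut_pattern.noncanonical_spans()[0][0]
        far = start - 15  # > 5 kernel widths upstream
        assert mut.coords[:, :far] == pytest.approx(wt.coords[:, :far], abs=1e-3)

    def test_nonphysical_minor_radius_warns_not_raises(self):
        with pytest.warns(UserWarning, match="minor_radius"):
            cb.CrickParameters(minor_radius=6.0)


class TestModelIO:
    def test_roundtrip_preserves_coordinates(self, canonical_model, tmp_path):
        path = tmp_path / "model.pdb"
        cb.write_model(canonical_model, path)
        coords, numbers = cb.read_model(path)
        assert coords == pytest.approx(canonical_model.coords, abs=1.5e-3)
        assert numbers.tolist() == canonical_model.residue_numbers.tolist()

    def test_atom_records_and_chain_ids(self, canonical_model, tmp_path):
        path = tmp_path / "model.pdb"
        cb.write_model(canonical_model, path)
        lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
        assert len(lines) == 182  # 91-residue dimer, one CA per residue
        chains = [l[21] for l in lines]
        assert sorted(set(chains)) == ["A", "B"]
        assert chains == ["A"] * 91 + ["B"] * 91
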