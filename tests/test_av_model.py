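"""Accessible-volume simulation and the rigid-body rotation scan."""

import warnings

import numpy as np
import pytest

from rotafret.av_model import (
    AccessibleVolume,
    AvError,
    DyeModel,
    Structure,
    compute_av,
    default_rotation_axis,
    load_structure,
    mean_fret_distance,
    rotate_about_axis,
    rotation_scan,
)

TOY_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  N   ALA A   1       2.500   2.000   3.000  1.00  0.00           N
ATOM      3  O   ALA A   2       4.000   2.000   3.000  1.00  0.00           O
"""

TOY_PDB_UNKNOWN = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
HETATM    2  XX  UNK A   2       4.000   2.000   3.000  1.00  0.00            X
"""


def small_dye(attachment=0, L=6.0):
    return DyeModel(linker_length=L, linker_width=2.0, radii=(0.5, 0.5, 0.5), attachment=attachment)


class TestLoadStructure:
    def test_toy_pdb_atoms_and_coordinates(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        s = load_structure(p)
        assert s.n_atoms == 3
        np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
        assert list(s.elements) == ["C", "N", "O"]
        assert s.radii[0] == 1.70 and s.radii[1] == 1.55

    def test_unknown_element_default_radius_with_warning(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB_UNKNOWN)
        with pytest.warns(UserWarning, match="unknown element"):
            s = load_structure(p)
        assert s.radii[1] == 1.5


class TestComputeAv:
    def test_unobstructed_volume_close_to_ball(self):
        """With no obstructing atoms the AV is a ball of the linker length."""
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0]])
        dye = DyeModel(10.0, 2.0, (0.5, 0.5, 0.5), 0)
        av = compute_av(s, dye, grid_spacing=0.5)
        ideal = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(av.volume() - ideal) / ideal < 0.05

    def test_wall_confines_av_to_half_space(self):
        grid = np.arange(-10, 11, 1.5)
        wall = [[2.5, y, z] for y in grid for z in grid]
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0]] + wall)
        av = compute_av(s, small_dye(), grid_spacing=1.0)
        # wall atoms (C, vdW 1.7) at x=2.5 block everything past ~0.3
        assert av.points[:, 0].max() < 1.0
        assert av.n_points > 0

    def test_brute_force_constraint_oracle(self):
        """Every AV point satisfies both defining constraints, checked
        exhaustively: clash-free against every atom, inside the linker-length
        ball, and never beyond an impassable wall even where clash-free."""
        grid = np.arange(-12, 13, 1.5)
        wall = [[3.0, y, z] for y in grid for z in grid]
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0]] + wall)
        dye = small_dye(L=8.0)
        av = compute_av(s, dye, grid_spacing=1.0)
        attach = s.coords[0]
        for pt in av.points:
            assert np.linalg.norm(pt - attach) <= 8.0 + 1e-9  # geodesic >= Euclid
            for coord, radius in zip(s.coords[1:], s.radii[1:]):
                assert np.linalg.norm(pt - coord) >= radius + 0.5 - 1e-9
            assert pt[0] < 3.0  # nothing tunnels through the wall

    def test_volume_monotone_in_linker_length(self):
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        vols = [
            compute_av(s, small_dye(L=L), grid_spacing=1.0).volume()
            for L in (4.0, 6.0, 8.0)
        ]
        assert vols[0] < vols[1] < vols[2]

    def test_volume_monotone_in_dye_radius(self):
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        av_small = compute_av(
            s, DyeModel(6.0, 2.0, (0.5, 0.5, 0.5), 0), grid_spacing=1.0
        )
        av_big = compute_av(s, DyeModel(6.0, 2.0, (2.0, 2.0, 2.0), 0), grid_spacing=1.0)
        assert av_big.volume() <= av_small.volume()

    def test_buried_attachment_raises(self):
        # attachment completely enclosed in a tight cage of atoms
        cage = [
            [d * s, 0, 0] for d in (1.2,) for s in (-1, 1)
        ] + [[0, d * s, 0] for d in (1.2,) for s in (-1, 1)] + [
            [0, 0, d * s] for d in (1.2,) for s in (-1, 1)
        ]
        corners = [[sx * 1.0, sy * 1.0, sz * 1.0] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        s = Structure.from_arrays(coords=[[0.0, 0.0, 0.0]] + cage + corners)
        with pytest.raises(AvError, match="buried|blocked"):
            compute_av(s, DyeModel(6.0, 6.0, (3.0, 3.0, 3.0), 0), grid_spacing=1.0)


class TestMeanFretDistance:
    def point_av(self, xyz):
        return AccessibleVolume(
            points=np.asarray([xyz], dtype=float),
            weights=np.ones(1),
            attachment_point=np.asarray(xyz, dtype=float),
            grid_spacing=1.0,
        )

    def test_single_points_at_r0(self):
        res = mean_fret_distance(self.point_av([0, 0, 0]), self.point_av([67.4, 0, 0]), 67.4)
        assert np.isclose(res.e_avg, 0.5)
        assert np.isclose(res.r_da_e, 67.4)

    def test_distant_compact_clouds_near_centroid_distance(self, rng):
        pts_a = rng.normal(0, 1.0, (200, 3))
        pts_b = rng.normal(0, 1.0, (200, 3)) + np.array([60.0, 0, 0])
        av_a = AccessibleVolume(pts_a, np.ones(200), np.zeros(3), 1.0)
        av_b = AccessibleVolume(pts_b, np.ones(200), np.zeros(3), 1.0)
        res = mean_fret_distance(av_a, av_b, 55.0, n_pairs=30_000, seed=1)
        assert abs(res.r_da_e - 60.0) < 2.0  # within the cloud spread

    def test_symmetric_in_donor_acceptor_exchange(self, rng):
        pts_a = rng.uniform(0, 5, (50, 3))
        pts_b = rng.uniform(40, 45, (50, 3))
        av_a = AccessibleVolume(pts_a, np.ones(50), np.zeros(3), 1.0)
        av_b = AccessibleVolume(pts_b, np.ones(50), np.zeros(3), 1.0)
        r1 = mean_fret_distance(av_a, av_b, 50.0)
        r2 = mean_fret_distance(av_b, av_a, 50.0)
        assert np.isclose(r1.e_avg, r2.e_avg)

    def test_coincident_clouds_short_distance(self, rng):
        pts = rng.uniform(0, 4, (80, 3))
        av = AccessibleVolume(pts, np.ones(80), np.zeros(3), 1.0)
        res = mean_fret_distance(av, av, 60.0)
        assert res.r_da_e < 15.0  # far below R0, dominated by short pairs


def two_arm_structure():
    """Rotating arm at (-10, 0, 5), fixed arm at (10, 0, -5); axis = z."""
    coords = [[-10.0, 0.0, 5.0], [10.0, 0.0, -5.0]]
    return Structure.from_arrays(coords=coords, chains=["B", "A"])


class TestRotationScan:
    def scan(self, structure, step=90.0, **kw):
        mask = structure.chains == "B"
        return rotation_scan(
            structure,
            mask,
            (np.zeros(3), np.array([0.0, 0.0, 1.0])),
            step,
            dye_rotating=small_dye(0, L=4.0),
            dye_fixed=small_dye(1, L=4.0),
            r0=40.0,
            grid_spacing=1.0,
            n_pairs=5000,
            seed=0,
            **kw,
        )

    def test_rigid_rotation_preserves_intra_half_distances(self, rng):
        coords = rng.uniform(-5, 5, (20, 3))
        rotated = rotate_about_axis(coords, np.array([1.0, 2.0, 0.0]), np.array([0, 0, 1.0]), 73.0)
        d0 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        d1 = np.linalg.norm(rotated[:, None] - rotated[None, :], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_profile_periodic_and_anchored_at_zero(self):
        profile = self.scan(two_arm_structure(), step=90.0)
        assert profile.angles[0] == 0 and profile.angles[-1] == 360
        # 360° equals 0° within grid tolerance
        assert abs(profile.r_da_e[-1] - profile.r_da_e[0]) < 0.5
        # and 0° equals the unrotated geometry computed directly
        s = two_arm_structure()
        av_r = compute_av(s, small_dye(0, L=4.0), 1.0)
        av_f = compute_av(s, small_dye(1, L=4.0), 1.0)
        direct = mean_fret_distance(av_r, av_f, 40.0, n_pairs=5000, seed=0)
        assert abs(profile.r_da_e[0] - direct.r_da_e) < 1e-9

    def test_arms_closest_at_180_degrees(self):
        profile = self.scan(two_arm_structure(), step=45.0)
        assert profile.angles[np.argmax(profile.e_avg)] == 180
        assert profile.angles[np.argmin(profile.r_da_e)] == 180

    def test_asymmetric_scene_breaks_mirror_symmetry(self):
        """An off-axis obstruction makes 0-180° differ from 180-360°."""
        s = two_arm_structure()
        blob = [[0.0, 7.0, 5.0], [1.5, 7.0, 5.0], [-1.5, 7.0, 5.0],
                [0.0, 8.5, 5.0], [0.0, 7.0, 6.5], [0.0, 7.0, 3.5]]
        coords = np.vstack([s.coords, np.asarray(blob)])
        s2 = Structure.from_arrays(
            coords=coords, chains=list(s.chains) + ["A"] * len(blob)
        )
        profile = self.scan(s2, step=45.0)
        fwd = profile.r_da_e[profile.angles == 90.0][0]
        rev = profile.r_da_e[profile.angles == 270.0][0]
        assert abs(fwd - rev) > 0.1

    def test_bad_selection_rejected(self):
        s = two_arm_structure()
        with pytest.raises(AvError, match="two non-empty halves"):
            self.scan_with_mask(s, np.ones(2, dtype=bool))

    def scan_with_mask(self, structure, mask):
        return rotation_scan(
            structure, mask, (np.zeros(3), np.array([0.0, 0.0, 1.0])), 90.0,
            small_dye(0, L=4.0), small_dye(1, L=4.0), 40.0,
        )

    def test_default_axis_heuristic(self):
        s = two_arm_structure()
        point, direction = default_rotation_axis(s, s.chains == "B")
        np.testing.assert_allclose(point, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            direction / np.linalg.norm(direction), [-0.894, 0.0, 0.447], atol=1e-3
        )
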