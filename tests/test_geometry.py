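"""Structural descriptors: attack angles, H-bonds, RMSD, puckering,
series statistics and hydrophobicity mapping."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import pmfkit as pk
from pmfkit.geometry import EISENBERG_SCALE, pocket_hydrophobicity, series_stats
from pmfkit.io import Trajectory

from conftest import make_frame, random_rotation


def measure(fx):
    return pk.attack_geometry(
        fx.frame, fx.roles["nucleophile"], fx.roles["electrophile"],
        fx.roles["carbonyl_oxygen"], fx.roles["substituent1"],
        fx.roles["substituent2"],
    )


class TestAttackGeometry:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        d=st.floats(0.8, 4.0),
        bd=st.floats(15.0, 165.0),
        frac=st.floats(-0.95, 0.95),
    )
    def test_fixture_measurement_roundtrip(self, d, bd, frac):
        # alpha_fl constrained to the reachable range |sin fl| <= sin bd
        fl = math.degrees(math.asin(frac * math.sin(math.radians(bd))))
        fx = pk.make_attack_fixture(d, bd, fl)
        g = measure(fx)
        assert g.d_nu_c == pytest.approx(d, abs=1e-6)
        assert g.alpha_bd == pytest.approx(bd, abs=1e-6)
        assert g.alpha_fl == pytest.approx(fl, abs=1e-6)

    def test_in_plane_nucleophile_has_zero_fl(self):
        fx = pk.make_attack_fixture(2.2, 107.0, 0.0)
        assert measure(fx).alpha_fl == pytest.approx(0.0, abs=1e-9)

    def test_nucleophile_on_oc_extension_is_180(self):
        fx = pk.make_attack_fixture(1.5, 180.0, 0.0)
        assert measure(fx).alpha_bd == pytest.approx(180.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        fx = pk.make_attack_fixture(2.46, 102.0, 9.0)
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        shift = np.array([3.0, -7.0, 11.0])
        moved = fx.frame.rotated(rot).translated(shift)
        g0 = measure(fx)
        g1 = pk.attack_geometry(moved, 4, 0, 1, 2, 3)
        assert g1.d_nu_c == pytest.approx(g0.d_nu_c, abs=1e-9)
        assert g1.alpha_bd == pytest.approx(g0.alpha_bd, abs=1e-9)
        assert g1.alpha_fl == pytest.approx(g0.alpha_fl, abs=1e-9)

    def test_collinear_plane_atoms_raise(self):
        frame = make_frame([[0, 0, 0], [1.2, 0, 0], [2.4, 0, 0], [3.6, 0, 0],
                            [0, 2, 0]])
        with pytest.raises(ValueError, match="collinear"):
            pk.attack_geometry(frame, 4, 0, 1, 2, 3)

    def test_duplicate_atoms_rejected(self):
        frame = make_frame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            pk.attack_geometry(frame, 0, 0, 1, 2, 3)


class TestHBondDetection:
    def detect(self, fx, **kw):
        return pk.detect_hbonds(
            Trajectory([fx.frame]), [fx.roles["donor"]], [fx.roles["acceptor"]], **kw
        )

    def test_clear_hbond_detected(self):
        records, occupancy = self.detect(pk.make_hbond_fixture(2.9, 160.0))
        assert len(records) == 1
        assert occupancy[(0, 2)] == 1.0
        assert records[0].d_da == pytest.approx(2.9, abs=1e-9)

    def test_boundary_values_inclusive(self):
        # exactly 3.0 Å and exactly 135.0° still count
        records, _ = self.detect(pk.make_hbond_fixture(3.0, 135.0))
        assert len(records) == 1

    def test_distance_criterion_excludes(self):
        records, occupancy = self.detect(pk.make_hbond_fixture(3.1, 160.0))
        assert records == []
        assert occupancy[(0, 2)] == 0.0

    def test_angle_criterion_excludes(self):
        records, _ = self.detect(pk.make_hbond_fixture(2.8, 120.0))
        assert records == []

    def test_donor_without_hydrogen_warns_not_raises(self):
        frame = make_frame([[0, 0, 0], [2.8, 0, 0]], elements=["N", "O"])
        with pytest.warns(UserWarning, match="no attached hydrogen"):
            records, occupancy = pk.detect_hbonds(Trajectory([frame]), [0], [1])
        assert records == []

    def test_occupancy_over_frames(self):
        from pmfkit.io import CoordinateFrame

        near = pk.make_hbond_fixture(2.9, 160.0).frame
        far_coords = near.coords.copy()
        far_coords[2] += [5.0, 0.0, 0.0]  # acceptor pulled out of range
        far = CoordinateFrame(near.atoms, far_coords)
        traj = Trajectory([near, far, near, near])
        records, occupancy = pk.detect_hbonds(traj, [0], [2])
        assert occupancy[(0, 2)] == pytest.approx(0.75)


class TestRMSD:
    def test_identity_is_zero(self):
        frame = make_frame(np.random.default_rng(1).normal(size=(5, 3)))
        assert pk.rmsd_series(Trajectory([frame]), frame, "all")[0] == 0.0

    def test_rigid_translation_without_alignment(self):
        ref = make_frame(np.random.default_rng(2).normal(size=(6, 3)))
        moved = ref.translated([3.0, 4.0, 0.0])
        assert pk.rmsd_series(Trajectory([moved]), ref, "all")[0] == pytest.approx(5.0)

    def test_alignment_removes_rigid_motion(self):
        rng = np.random.default_rng(3)
        ref = make_frame(rng.normal(size=(8, 3)))
        rot = random_rotation(rng)
        moved = ref.rotated(rot).translated([1.0, -2.0, 0.5])
        r = pk.rmsd_series(Trajectory([moved]), ref, "all", align_selection="all")
        assert r[0] == pytest.approx(0.0, abs=1e-9)

    def test_heavy_selection_excludes_hydrogens(self):
        coords = np.zeros((4, 3))
        coords[3] = [100.0, 0, 0]  # displaced hydrogen must not contribute
        ref = make_frame(coords, elements=["C", "N", "O", "H"])
        moved = make_frame(np.array(coords) + [0, 3, 0], elements=["C", "N", "O", "H"])
        r = pk.rmsd_series(Trajectory([moved]), ref, "heavy")
        assert r[0] == pytest.approx(3.0)

    def test_atom_count_mismatch_raises(self):
        ref = make_frame(np.zeros((3, 3)))
        other = make_frame(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            pk.rmsd_series(Trajectory([other]), ref, "all")


class TestDihedralSeries:
    @staticmethod
    def pucker_frame(angle_deg):
        """Four ring-like atoms whose a-b-c-d torsion equals angle_deg."""
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.5, 0.0, 0.0])
        a = np.array([-0.5, 1.4, 0.0])
        d0 = np.array([2.0, 1.4, 0.0])  # cis (torsion 0)
        rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([1.0, 0, 0]))
        d = c + rot.apply(d0 - c)
        return make_frame([a, b, c, d])

    def test_planar_frames_are_zero(self):
        traj = Trajectory([self.pucker_frame(0.0)] * 3)
        assert np.allclose(pk.dihedral_series(traj, 0, 1, 2, 3), 0.0, atol=1e-9)

    def test_constructed_pucker_roundtrip(self):
        # the puckering magnitude seen at the tetrahedral intermediate
        frame = self.pucker_frame(11.0)
        val = pk.dihedral_series(Trajectory([frame]), 0, 1, 2, 3)[0]
        assert abs(val) == pytest.approx(11.0, abs=1e-6)

    def test_sign_flips_under_mirror(self):
        frame = self.pucker_frame(11.0)
        mirrored = make_frame(frame.coords * np.array([1.0, 1.0, -1.0]))
        v = pk.dihedral_series(Trajectory([frame]), 0, 1, 2, 3)[0]
        vm = pk.dihedral_series(Trajectory([mirrored]), 0, 1, 2, 3)[0]
        assert vm == pytest.approx(-v, abs=1e-9)

    def test_puckering_inversion_detectable(self):
        # sign change along a series marks the ring flip
        traj = Trajectory([self.pucker_frame(a) for a in (11.0, 5.0, -3.0)])
        series = pk.dihedral_series(traj, 0, 1, 2, 3)
        assert (series[0] > 0) != (series[-1] > 0)


class TestSeriesStats:
    def test_constant_series(self):
        s = series_stats([4.2] * 10, bins=5)
        assert s.mean == pytest.approx(4.2, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_arithmetic(self):
        s = series_stats([3.2, 3.4], bins=4)
        assert s.mean == pytest.approx(3.3)
        assert s.sd == pytest.approx(0.1414, abs=1e-4)

    def test_histogram_counts_sum_to_length(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=257)
        s = series_stats(data, bins=16)
        assert s.counts.sum() == 257

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            series_stats([])


class TestHydrophobicity:
    def test_printed_scale_values(self):
        values = pk.hydrophobicity_map(["LYS", "THR"])
        assert values["LYS"] == -1.5
        assert values["THR"] == -0.05

    def test_hydrophobic_pocket_residue_range(self):
        # the apolar pocket residues fall in the printed +1.08..+1.38 band
        for res in ("ILE", "VAL", "PHE"):
            assert 1.08 <= EISENBERG_SCALE[res] <= 1.38

    def test_unknown_residue_raises_with_name(self):
        with pytest.raises(ValueError, match="XYZ"):
            pk.hydrophobicity_map(["ALA", "XYZ"])

    def test_pocket_aggregate_is_mean(self):
        agg = pocket_hydrophobicity(["ILE", "VAL"])
        assert agg == pytest.approx((1.38 + 1.08) / 2)

    def test_frame_interface(self):
        frame = make_frame(np.zeros((2, 3)), elements=["N", "C"],
                           res_names=["LYS", "THR"])
        out = pk.hydrophobicity_map(frame)
        assert out[("A", 1)] == -1.5
        assert out[("A", 2)] == -0.05
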