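"""Site–heme distances, H-bond/lipophilic features, pose fractions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somcyp.chemio import Bond, InputError, LigandPose, Molecule
from somcyp.active_site import ActiveSiteModel
from somcyp.pose_features import (
    HBondCriteria,
    LipophilicCriteria,
    detect_hydrogen_bonds,
    detect_lipophilic_contacts,
    qualifying_pose_fraction,
    site_heme_distance,
)
from somcyp.fixtures import rotation_about_axis

from conftest import make_poses


def bare_site(fe=(0, 0, 0), ser_og=None, waters=None, phe=None, heme=None):
    """Minimal in-memory active-site model for constructed geometries."""
    return ActiveSiteModel(
        fe_position=np.asarray(fe, float),
        hbond_residues=(
            {"Ser119": [("OG", np.asarray(ser_og, float))]} if ser_og is not None else {}
        ),
        waters={k: np.asarray(v, float) for k, v in (waters or {}).items()},
        phe_cluster=(
            {"Phe108": [(f"C{k}", p) for k, p in enumerate(np.asarray(phe, float))]}
            if phe is not None else {}
        ),
        heme_atoms=[(f"X{k}", p) for k, p in enumerate(np.asarray(heme, float))]
        if heme is not None else [],
    )


def single_carbon_pose(position):
    m = Molecule(["C", "H", "H", "H", "H"],
                 np.asarray(position, float) + np.array(
                     [[0, 0, 0], [0.63, 0.63, 0.63], [0.63, -0.63, -0.63],
                      [-0.63, 0.63, -0.63], [-0.63, -0.63, 0.63]]),
                 [Bond(0, k, 1.0) for k in (1, 2, 3, 4)], name="probe")
    return LigandPose(m, rank=1)


class TestSiteHemeDistance:
    @pytest.mark.parametrize(
        "fe, carbon, expected",
        [((0, 0, 0), (0, 0, 5), 5.0),
         ((1, 1, 1), (1, 1, 1), 0.0),
         ((0, 0, 0), (3, 4, 0), 5.0)],
    )
    def test_euclidean_distance(self, fe, carbon, expected):
        site = bare_site(fe=fe)
        pose = single_carbon_pose(carbon)
        assert site_heme_distance(pose, 0, site) == pytest.approx(expected, abs=1e-12)

    def test_non_carbon_rejected(self):
        site = bare_site()
        pose = single_carbon_pose((0, 0, 3))
        with pytest.raises(InputError, match="not carbon"):
            site_heme_distance(pose, 1, site)


def hydroxyl_pose(o_pos, h_pos):
    """Methanol-like fragment with a free O-H for donor geometry tests."""
    m = Molecule(
        ["C", "O", "H", "H", "H", "H"],
        np.array([
            np.asarray(o_pos) + [0.0, -1.43, 0.0],
            o_pos, h_pos,
            np.asarray(o_pos) + [1.02, -1.80, 0.0],
            np.asarray(o_pos) + [-1.02, -1.80, 0.0],
            np.asarray(o_pos) + [0.0, -2.1, 0.9],
        ]),
        [Bond(0, 1, 1.0), Bond(1, 2, 1.0), Bond(0, 3, 1.0),
         Bond(0, 4, 1.0), Bond(0, 5, 1.0)],
        name="hydroxyl-probe",
    )
    return LigandPose(m, rank=1)


class TestHydrogenBonds:
    def test_aligned_donor_inside_criteria(self):
        # O at origin, H on +z, OG 1.9 A beyond the H (angle 180)
        pose = hydroxyl_pose([0, 0, 0], [0, 0, 0.97])
        site = bare_site(ser_og=[0, 0, 0.97 + 1.9])
        feats = detect_hydrogen_bonds(pose, site)
        assert len(feats) == 1
        f = feats[0]
        assert f.partner == "Ser119:OG"
        assert f.ligand_is_donor
        assert f.angle == pytest.approx(180.0, abs=1e-6)
        assert f.distance == pytest.approx(2.87, abs=1e-9)

    def test_stretched_pair_gives_nothing(self):
        pose = hydroxyl_pose([0, 0, 0], [0, 0, 0.97])
        site = bare_site(ser_og=[0, 0, 4.2])
        assert detect_hydrogen_bonds(pose, site) == []

    def test_misaligned_donor_gives_nothing(self):
        # OG at 3.0 A but on the far side of the O from the H: angle ~ 0
        pose = hydroxyl_pose([0, 0, 0], [0, 0, 0.97])
        site = bare_site(ser_og=[0, 0, -3.0])
        assert detect_hydrogen_bonds(pose, site) == []

    def test_carbonyl_oxygen_accepts_from_water(self, cyclohexanone):
        o_idx = cyclohexanone.symbols.index("O")
        site = bare_site(waters={623: cyclohexanone.coords[o_idx] + [0, 0, 2.9]})
        feats = detect_hydrogen_bonds(LigandPose(cyclohexanone, 1), site)
        assert len(feats) == 1
        assert feats[0].partner == "HOH-623:O"
        assert feats[0].angle is None
        assert feats[0].distance == pytest.approx(2.9, abs=1e-9)

    def test_enlarging_cutoff_never_removes_features(self):
        pose = hydroxyl_pose([0, 0, 0], [0, 0, 0.97])
        site = bare_site(ser_og=[1.2, 0.4, 2.9], waters={623: [0.5, 3.0, 0.4]})
        tight = detect_hydrogen_bonds(pose, site, HBondCriteria(3.0, 130.0))
        loose = detect_hydrogen_bonds(pose, site, HBondCriteria(3.6, 120.0))
        tight_keys = {(f.ligand_atom, f.partner) for f in tight}
        loose_keys = {(f.ligand_atom, f.partner) for f in loose}
        assert tight_keys <= loose_keys


class TestLipophilicContacts:
    def test_phe_cluster_contact(self):
        pose = single_carbon_pose((0, 0, 0))
        ring = [[3.9, 0, 0], [3.9, 0.6, 0.3], [3.9, -0.6, 0.3]]
        site = bare_site(phe=ring)
        feats = detect_lipophilic_contacts(
            pose, site, LipophilicCriteria(max_contact_distance=4.5, min_contact_count=3)
        )
        assert [f.partner for f in feats] == ["Phe-cluster"]

    def test_everything_far_gives_empty(self):
        pose = single_carbon_pose((0, 0, 0))
        site = bare_site(phe=[[8, 0, 0]], heme=[[0, 9, 0]])
        assert detect_lipophilic_contacts(pose, site) == []

    def test_heme_only_contact(self, cyclohexanone):
        pose = LigandPose(cyclohexanone, 1)
        heme = [cyclohexanone.coords[c] + [0, 0, 3.5] for c in (1, 2, 3, 4, 5)]
        site = bare_site(heme=heme, phe=[[40, 0, 0]])
        feats = detect_lipophilic_contacts(
            pose, site, LipophilicCriteria(max_contact_distance=4.0, min_contact_count=3)
        )
        assert [f.partner for f in feats] == ["heme"]

    def test_heme_contact_restricted_to_candidate_carbons(self, cyclohexanone):
        pose = LigandPose(cyclohexanone, 1)
        heme = [cyclohexanone.coords[0] + [0.0, 0.0, 1.5]]
        site = bare_site(heme=heme)
        crit = LipophilicCriteria(max_contact_distance=2.0, min_contact_count=1)
        all_feats = detect_lipophilic_contacts(pose, site, crit)
        restricted = detect_lipophilic_contacts(
            pose, site, crit, heme_carbons={3, 4}
        )
        assert [f.partner for f in all_feats] == ["heme"]  # carbonyl C counts
        assert restricted == []  # C3/C4 are far from that heme atom


class TestPoseFraction:
    def test_uniform_fraction_is_count_over_n(self, methane, tmp_path):
        distances = [3.0, 4.0, 5.0, 7.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0]
        poses = make_poses(methane, distances, tmp_path)
        site = bare_site()
        frac = qualifying_pose_fraction(0, poses, site)
        assert frac == pytest.approx(4 / 10, abs=1e-12)

    def test_no_pose_in_window_is_zero(self, methane, tmp_path):
        poses = make_poses(methane, [9.0, 10.0, 11.0], tmp_path)
        assert qualifying_pose_fraction(0, poses, bare_site()) == 0.0

    def test_linear_rank_weights(self, methane, tmp_path):
        distances = [5.0, 6.0, 7.0] + [9.0] * 7
        poses = make_poses(methane, distances, tmp_path)
        frac = qualifying_pose_fraction(0, poses, bare_site(), weights="linear_rank")
        assert frac == pytest.approx(27 / 55, abs=1e-12)

    def test_all_poses_qualify_gives_one(self, methane, tmp_path):
        poses = make_poses(methane, [3.0, 4.0, 5.0, 6.0], tmp_path)
        for scheme in ("uniform", "linear_rank"):
            assert qualifying_pose_fraction(
                0, poses, bare_site(), weights=scheme
            ) == pytest.approx(1.0, abs=1e-12)

    def test_empty_pose_set_rejected(self):
        with pytest.raises(InputError):
            qualifying_pose_fraction(0, [], bare_site())

    def test_widening_window_never_reduces_fraction(self, methane, tmp_path):
        poses = make_poses(methane, [2.0, 4.0, 6.0, 8.0, 10.0], tmp_path)
        site = bare_site()
        narrow = qualifying_pose_fraction(0, poses, site, window=(3.0, 7.0))
        wide = qualifying_pose_fraction(0, poses, site, window=(2.0, 9.0))
        assert wide >= narrow


class TestRigidMotionInvariance:
    @settings(max_examples=20, deadline=None)
    @given(
        axis=st.tuples(*[st.floats(-1, 1).filter(lambda v: abs(v) > 1e-3)] * 3),
        angle=st.floats(0, 360),
        shift=st.tuples(*[st.floats(-20, 20)] * 3),
    )
    def test_features_invariant_under_common_rigid_motion(self, axis, angle, shift):
        rot = rotation_about_axis(np.array(axis), angle)
        t = np.array(shift)
        pose = hydroxyl_pose([0, 0, 0], [0, 0, 0.97])
        og = np.array([1.2, 0.4, 2.9])
        fe = np.array([0.0, 1.0, -4.0])
        site = bare_site(fe=fe, ser_og=og, waters={623: [0.5, 3.0, 0.4]})
        moved_pose = LigandPose(pose.molecule.transformed(rot, t), rank=1)
        moved_site = bare_site(
            fe=rot @ fe + t, ser_og=rot @ og + t,
            waters={623: rot @ np.array([0.5, 3.0, 0.4]) + t},
        )
        d0 = site_heme_distance(pose, 0, site)
        d1 = site_heme_distance(moved_pose, 0, moved_site)
        assert abs(d0 - d1) < 1e-9
        f0 = detect_hydrogen_bonds(pose, site)
        f1 = detect_hydrogen_bonds(moved_pose, moved_site)
        assert [(f.ligand_atom, f.partner) for f in f0] \
            == [(f.ligand_atom, f.partner) for f in f1]
        for a, b in zip(f0, f1):
            assert abs(a.distance - b.distance) < 1e-9
            if a.angle is not None:
                assert abs(a.angle - b.angle) < 1e-6
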