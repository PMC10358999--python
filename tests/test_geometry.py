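"""Geometric primitives against independent oracles and symmetry laws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import thermoscreen as ts
from thermoscreen.geometry import ContactRule, HBondCriteria

from .oracles import (
    brute_force_contacts,
    dihedral_normals,
    quaternion_rotation,
    quaternion_superpose_rmsd,
)


def random_cloud(rng, n=6, scale=5.0):
    return rng.normal(scale=scale, size=(n, 3))


class TestKabsch:
    def test_identity(self, rng):
        pts = random_cloud(rng)
        res = ts.kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-6)

    def test_pure_rotation_recovered(self, rng):
        pts = random_cloud(rng)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = pts @ Rz.T
        res = ts.kabsch_superpose(mobile, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.rotation, Rz.T, atol=1e-8)  # inverse of the applied 90°

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(200):
            a, b = random_cloud(rng), random_cloud(rng)
            assert ts.kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-8
            )

    def test_rotation_matches_quaternion_oracle(self, rng):
        for _ in range(50):
            a, b = random_cloud(rng), random_cloud(rng)
            R = ts.kabsch_superpose(a, b).rotation
            assert np.allclose(R, quaternion_rotation(a, b), atol=1e-7)

    def test_no_reflection_even_for_mirrored_input(self, rng):
        pts = random_cloud(rng)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        res = ts.kabsch_superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_invariant_under_common_rigid_transform(self, rng):
        from scipy.spatial.transform import Rotation

        a, b = random_cloud(rng), random_cloud(rng)
        base = ts.kabsch_superpose(a, b).rmsd
        for seed in range(5):
            R = Rotation.random(random_state=seed).as_matrix()
            t = rng.normal(size=3)
            moved = ts.kabsch_superpose(a @ R.T + t, b @ R.T + t).rmsd
            assert moved == pytest.approx(base, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ts.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            ts.kabsch_superpose(line, line)


class TestDihedral:
    def test_cis_is_zero(self):
        assert ts.dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_trans_is_plus_180(self):
        ang = ts.dihedral([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])
        assert ang == pytest.approx(180.0, abs=1e-9)
        assert ang > 0  # convention: trans maps to +180, not -180

    def test_matches_normal_vector_oracle(self, rng):
        for _ in range(300):
            pts = rng.normal(scale=3.0, size=(4, 3))
            try:
                mine = ts.dihedral(*pts)
            except ValueError:
                continue
            diff = (mine - dihedral_normals(*pts) + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-9

    def test_matches_mdanalysis_sign_convention(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(50):
            pts = rng.normal(scale=3.0, size=(4, 3))
            ref = float(np.degrees(calc_dihedrals(*(p[None, :] for p in pts))[0]))
            mine = ts.dihedral(*pts)
            diff = (mine - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-3  # MDAnalysis works in float32

    @given(st.integers(0, 10_000))
    def test_reversal_preserves_and_mirror_flips_sign(self, seed):
        # torsion angles are invariant under atom-order reversal and
        # change sign under a mirror reflection of the coordinates
        pts = np.random.default_rng(seed).normal(scale=3.0, size=(4, 3))
        try:
            fwd = ts.dihedral(*pts)
        except ValueError:
            return
        assert ts.dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(abs(fwd) - 180.0) > 1e-9 and abs(fwd) > 1e-9:
            assert ts.dihedral(*mirrored) == pytest.approx(-fwd, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            ts.dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])

    def test_collinear_triple_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ts.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestPhi:
    def test_interior_residues_report_the_built_phi(self):
        h = ts.make_helix(10, phi=-57.0, psi=-47.0)
        for res in h.residues[1:]:
            assert ts.phi_of_residue(h, res.key) == pytest.approx(-57.0, abs=1e-3)

    def test_left_handed_phi_positive_branch(self):
        h = ts.make_helix(8, phi=60.0, psi=40.0)
        assert ts.phi_of_residue(h, h.residues[4].key) == pytest.approx(60.0, abs=1e-3)

    def test_chain_start_has_no_phi(self, helix12):
        with pytest.raises(ValueError, match="no phi"):
            ts.phi_of_residue(helix12, helix12.residues[0].key)

    def test_missing_backbone_atom_named(self, helix12):
        res = helix12.residues[5]
        stripped = ts.StructureModel([
            r if r.key != res.key else
            ts.Residue(r.key, [a for a in r.atoms if a.name != "N"])
            for r in helix12.residues
        ])
        with pytest.raises(ValueError, match=r"\bN\b"):
            ts.phi_of_residue(stripped, res.key)


def two_residue_toy(distance):
    """Two alanines whose CB atoms sit exactly `distance` apart."""
    def res(num, x):
        key = ts.ResidueKey("A", num, "", "ALA")
        atoms = [
            ts.AtomRecord(1, "CA", "C", [x, 2.0, 0.0]),
            ts.AtomRecord(2, "CB", "C", [x, 0.0, 0.0]),
        ]
        return ts.Residue(key, atoms)
    return ts.StructureModel([res(1, 0.0), res(2, distance)])


class TestContacts:
    def test_below_threshold_is_contact(self):
        s = two_residue_toy(2.5)
        rule = ContactRule(3.0)
        assert len(ts.contact_partners(s, s.residues[0].key, rule)) == 1
        assert len(ts.contact_partners(s, s.residues[1].key, rule)) == 1

    def test_boundary_is_not_contact(self):
        # "less than" is strict: a pair at exactly the threshold is out
        s = two_residue_toy(3.0)
        assert ts.contact_partners(s, s.residues[0].key, ContactRule(3.0)) == []

    def test_glycine_falls_back_to_ca(self):
        s = two_residue_toy(10.0)
        gly = ts.Residue(ts.ResidueKey("A", 3, "", "GLY"),
                         [ts.AtomRecord(5, "CA", "C", [0.0, 2.0, 1.0])])
        s2 = ts.StructureModel(s.residues + [gly])
        partners = ts.contact_partners(s2, gly.key, ContactRule(3.0))
        assert [p.resnum for p in partners] == [1]  # CA(gly)–CB(res1) = 1.0+2.0 dist

    def test_matches_brute_force_on_random_cluster(self, rng):
        coords = rng.uniform(0, 8, size=(10, 3))
        residues = [
            ts.Residue(ts.ResidueKey("A", i + 1, "", "ALA"),
                       [ts.AtomRecord(i + 1, "CB", "C", c),
                        ts.AtomRecord(100 + i, "CA", "C", c + [0, 0, 0.5])])
            for i, c in enumerate(coords)
        ]
        s = ts.StructureModel(residues)
        rule = ContactRule(4.0)
        adj = brute_force_contacts(coords, 4.0)
        counts = ts.contact_counts(s, rule)
        for i, res in enumerate(s.residues):
            assert counts[res.key] == adj[i].sum()
            partners = ts.contact_partners(s, res.key, rule)
            assert sorted(p.resnum for p in partners) == \
                   sorted(int(j) + 1 for j in np.nonzero(adj[i])[0])

    def test_symmetric_and_irreflexive(self, rng):
        coords = rng.uniform(0, 6, size=(8, 3))
        residues = [
            ts.Residue(ts.ResidueKey("A", i + 1, "", "ALA"),
                       [ts.AtomRecord(i + 1, "CB", "C", c)])
            for i, c in enumerate(coords)
        ]
        s = ts.StructureModel(residues)
        rule = ContactRule(3.5)
        for res in s.residues:
            partners = ts.contact_partners(s, res.key, rule)
            assert res.key not in partners
            for p in partners:
                assert res.key in ts.contact_partners(s, p, rule)

    def test_residue_without_representative_atom(self):
        bare = ts.Residue(ts.ResidueKey("A", 1, "", "ALA"),
                          [ts.AtomRecord(1, "N", "N", [0, 0, 0])])
        s = ts.StructureModel([bare])
        with pytest.raises(ValueError, match="neither CB nor CA"):
            ts.contact_partners(s, bare.key, ContactRule())


def nh_oc_geometry(n_o_dist, angle_deg=175.0):
    """Donor residue (with explicit H) and acceptor carbonyl at a set
    N···O distance and D–H–A angle."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.01, 0.0, 0.0])
    theta = np.radians(180.0 - angle_deg)
    o = h + (n_o_dist - 1.01) * np.array([np.cos(theta), np.sin(theta), 0.0])
    donor = ts.Residue(ts.ResidueKey("A", 1, "", "ALA"), [
        ts.AtomRecord(1, "N", "N", n),
        ts.AtomRecord(2, "H", "H", h),
        ts.AtomRecord(3, "CA", "C", [-0.9, 1.1, 0.0]),
    ])
    acceptor = ts.Residue(ts.ResidueKey("A", 5, "", "ALA"), [
        ts.AtomRecord(4, "C", "C", o + [1.23, 0.0, 0.0]),
        ts.AtomRecord(5, "O", "O", o),
    ])
    return ts.StructureModel([donor, acceptor])


class TestHBonds:
    def test_ideal_geometry_counts_one_bond(self):
        s = nh_oc_geometry(2.9, 175.0)
        bonds = ts.detect_hbonds(s, HBondCriteria())
        assert len(bonds) == 1
        assert (bonds[0][0].resnum, bonds[0][1].resnum) == (1, 5)

    def test_stretched_geometry_counts_zero(self):
        s = nh_oc_geometry(4.5, 175.0)
        assert ts.detect_hbonds(s, HBondCriteria()) == []

    def test_bent_geometry_counts_zero(self):
        s = nh_oc_geometry(2.9, 120.0)
        assert ts.detect_hbonds(s, HBondCriteria()) == []

    def test_helix_shows_i_to_i_minus_4_pattern(self, helix12):
        bonds = ts.detect_hbonds(helix12, HBondCriteria())
        pairs = sorted((d.resnum, a.resnum) for d, a in bonds)
        assert pairs == [(i, i - 4) for i in range(5, 13)]
        assert len(bonds) == 12 - 4

    def test_helix_count_matches_exhaustive_pair_check(self, helix12):
        crit = HBondCriteria()
        # independent exhaustive check over every built-H donor / O pair
        from thermoscreen.geometry import _amide_hydrogen

        expected = set()
        for i, donor in enumerate(helix12.residues[1:], start=1):
            h = _amide_hydrogen(helix12.residues[i - 1], donor)
            n = donor.atom("N").coords
            for acc in helix12.residues:
                if acc.key == donor.key:
                    continue
                o = acc.atom("O").coords
                if np.linalg.norm(n - o) > crit.max_donor_acceptor_dist:
                    continue
                cosang = np.dot(n - h, o - h) / (
                    np.linalg.norm(n - h) * np.linalg.norm(o - h))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= crit.min_dha_angle:
                    expected.add((donor.key.resnum, acc.key.resnum))
        got = {(d.resnum, a.resnum) for d, a in ts.detect_hbonds(helix12, crit)}
        assert got == expected

    def test_count_invariant_under_rigid_transform(self, helix12, rng):
        from scipy.spatial.transform import Rotation

        base = len(ts.detect_hbonds(helix12))
        R = Rotation.random(random_state=7).as_matrix()
        moved = helix12.with_coords(helix12.all_coords() @ R.T + rng.normal(size=3))
        assert len(ts.detect_hbonds(moved)) == base
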