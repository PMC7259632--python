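import numpy as np
import pytest

from turnprint.fingerprint import (InteractionCutoffs, InterfaceSplit,
                                   detect_aromatic_aromatic,
                                   detect_aromatic_sulphur, detect_cation_pi,
                                   detect_hbonds, detect_hydrophobic,
                                   detect_ionic, fingerprint,
                                   label_salt_bridges)
from turnprint.structure import Atom, Residue, Structure

import oracles
from conftest import AB_SPLIT

CUTOFFS = InteractionCutoffs()


def build(residue_specs):
    """Structure from [(chain, seq, name, [(atom, element, coord), ...])]."""
    residues = []
    serial = 0
    for chain, seq, name, atoms in residue_specs:
        r = Residue(chain, seq, name)
        for atom_name, element, coord in atoms:
            serial += 1
            r.atoms.append(Atom(serial, atom_name, element, np.asarray(coord, float)))
        residues.append(r)
    return Structure(residues)


def _unordered(records):
    return {
        (rec.kind,
         frozenset([(rec.partner_a.residue_key, rec.partner_a.group),
                    (rec.partner_b.residue_key, rec.partner_b.group)]),
         round(rec.distance, 6))
        for rec in records
    }


def assert_matches_oracle(structure, cutoffs=CUTOFFS):
    """Compare every detector against the brute-force all-pairs oracle."""
    split = AB_SPLIT
    a, b = {"A"}, {"B"}

    got = {(frozenset([(r.partner_a.residue_key, r.partner_a.group),
                       (r.partner_b.residue_key, r.partner_b.group)]),
            round(r.distance, 6))
           for r in detect_hbonds(structure, split, cutoffs)}
    want = {(frozenset([(d[0], d[1]), (d[2], d[3])]), d[4])
            for d in oracles.oracle_hbonds(structure, a, b, cutoffs.hbond)}
    assert got == want, "hbond mismatch"

    got = {(r.partner_a.residue_key, r.partner_b.residue_key, round(r.distance, 6))
           for r in detect_hydrophobic(structure, split, cutoffs)}
    assert got == oracles.oracle_hydrophobic(structure, a, b, cutoffs.hydrophobic)

    impl_ionic = detect_ionic(structure, split, cutoffs)
    got = {(frozenset([r.partner_a.residue_key, r.partner_b.residue_key]),
            round(r.distance, 6)) for r in impl_ionic}
    oracle_ionic = oracles.oracle_ionic(structure, a, b, cutoffs.ionic)
    want = {(frozenset([d[0], d[2]]), d[4]) for d in oracle_ionic}
    assert got == want, "ionic mismatch"

    got = {(r.partner_a.residue_key, r.partner_a.group,
            r.partner_b.residue_key, r.partner_b.group, round(r.distance, 6))
           for r in detect_aromatic_aromatic(structure, split, cutoffs)}
    assert got == oracles.oracle_aromatic_aromatic(
        structure, a, b, cutoffs.aromatic_min, cutoffs.aromatic_max)

    got = {(frozenset([(r.partner_a.residue_key, r.partner_a.group),
                       (r.partner_b.residue_key, r.partner_b.group)]),
            round(r.distance, 6))
           for r in detect_aromatic_sulphur(structure, split, cutoffs)}
    want = {(frozenset([(d[0], d[1]), (d[2], d[3])]), d[4])
            for d in oracles.oracle_aromatic_sulphur(structure, a, b,
                                                     cutoffs.aromatic_sulphur)}
    assert got == want, "aromatic-sulphur mismatch"

    got = {(frozenset([(r.partner_a.residue_key, r.partner_a.group),
                       (r.partner_b.residue_key, r.partner_b.group)]),
            round(r.distance, 6))
           for r in detect_cation_pi(structure, split, cutoffs)}
    want = {(frozenset([(d[0], d[1]), (d[2], d[3])]), d[4])
            for d in oracles.oracle_cation_pi(structure, a, b, cutoffs.cation_pi)}
    assert got == want, "cation-pi mismatch"

    impl_sb = label_salt_bridges(detect_hbonds(structure, split, cutoffs), impl_ionic)
    got = {frozenset([r.partner_a.residue_key, r.partner_b.residue_key])
           for r in impl_sb}
    want = {frozenset(p) for p in oracles.oracle_salt_bridge_pairs(
        oracles.oracle_hbonds(structure, a, b, cutoffs.hbond), oracle_ionic)}
    assert got == want, "salt-bridge mismatch"


class TestHbonds:
    def test_backbone_pair_within_cutoff(self):
        s = build([("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))]),
                   ("B", 1, "GLY", [("O", "O", (0, 3.0, 0)), ("CA", "C", (1.5, 3, 0))])])
        records = detect_hbonds(s, AB_SPLIT)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(3.0)
        assert records[0].partner_a.mainchain and records[0].partner_b.mainchain

    def test_beyond_cutoff_empty(self):
        s = build([("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (1.5, 0, 0))]),
                   ("B", 1, "GLY", [("O", "O", (0, 3.6, 0)), ("CA", "C", (1.5, 3.6, 0))])])
        assert detect_hbonds(s, AB_SPLIT) == []

    def test_angle_gate_with_explicit_hydrogens(self):
        # linear D-H...A passes; H pointing away fails the 120 degree gate
        good = build([("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("H", "H", (0, 1.0, 0))]),
                      ("B", 1, "GLY", [("O", "O", (0, 3.0, 0))])])
        assert len(detect_hbonds(good, AB_SPLIT)) == 1
        bad = build([("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("H", "H", (0, -1.0, 0))]),
                     ("B", 1, "GLY", [("O", "O", (0, 3.0, 0))])])
        assert detect_hbonds(bad, AB_SPLIT) == []

    def test_proline_backbone_n_not_donor(self):
        s = build([("A", 1, "GLY", [("CA", "C", (-4, 0, 0))]),
                   ("A", 2, "PRO", [("N", "N", (0, 0, 0))]),
                   ("A", 3, "GLY", [("CA", "C", (4, 0, 0))]),
                   ("B", 1, "GLY", [("O", "O", (0, 3.0, 0))])])
        assert detect_hbonds(s, AB_SPLIT) == []

    def test_nonpolar_selection_empty(self):
        s = build([("A", 1, "ALA", [("CB", "C", (0, 0, 0))]),
                   ("B", 1, "ALA", [("CB", "C", (0, 3.0, 0))])])
        assert detect_hbonds(s, AB_SPLIT) == []


class TestHydrophobic:
    def test_leu_val_contact(self):
        s = build([("A", 1, "LEU", [("CD1", "C", (0, 0, 0))]),
                   ("B", 1, "VAL", [("CG1", "C", (0, 4.2, 0))])])
        records = detect_hydrophobic(s, AB_SPLIT)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(4.2)

    def test_serine_not_apolar(self):
        s = build([("A", 1, "LEU", [("CD1", "C", (0, 0, 0))]),
                   ("B", 1, "SER", [("CB", "C", (0, 4.2, 0))])])
        assert detect_hydrophobic(s, AB_SPLIT) == []

    def test_reports_minimum_distance(self):
        s = build([("A", 1, "LEU", [("CD1", "C", (0, 0, 0)), ("CD2", "C", (0, 1, 0))]),
                   ("B", 1, "VAL", [("CG1", "C", (0, 4.8, 0))])])
        records = detect_hydrophobic(s, AB_SPLIT)
        assert records[0].distance == pytest.approx(3.8)


class TestIonic:
    def test_lys_glu_within_cutoff(self):
        s = build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                   ("B", 1, "GLU", [("OE1", "O", (0, 4.0, 0))])])
        assert len(detect_ionic(s, AB_SPLIT)) == 1

    def test_beyond_cutoff(self):
        s = build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                   ("B", 1, "GLU", [("OE1", "O", (0, 6.5, 0))])])
        assert detect_ionic(s, AB_SPLIT) == []

    def test_cterminal_carboxylate_is_anionic(self):
        s = build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                   ("B", 41, "GLY", [("CA", "C", (2, 3.5, 0))]),
                   ("B", 42, "ALA", [("O", "O", (0, 3.5, 0)), ("OXT", "O", (1, 4.2, 0))])])
        records = detect_ionic(s, AB_SPLIT)
        assert len(records) == 1
        assert records[0].partner_b.group == "-Cterm"
        assert records[0].distance == pytest.approx(3.5)

    def test_histidine_neutral_by_default(self):
        s = build([("A", 5, "HIS", [("NE2", "N", (0, 0, 0))]),
                   ("A", 4, "GLY", [("CA", "C", (-4, 0, 0))]),
                   ("A", 6, "GLY", [("CA", "C", (4, 0, 0))]),
                   ("B", 1, "GLU", [("OE1", "O", (0, 4.0, 0))])])
        assert detect_ionic(s, AB_SPLIT) == []
        his_on = InteractionCutoffs(include_his_cation=True)
        assert len(detect_ionic(s, AB_SPLIT, his_on)) == 1


def _phe(chain, seq, center, phase=0.0):
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    atoms = []
    for k, name in enumerate(names):
        ang = phase + k * np.pi / 3
        atoms.append((name, "C", np.asarray(center, float)
                      + 1.39 * np.array([np.cos(ang), 0.0, np.sin(ang)])))
    return (chain, seq, "PHE", atoms)


class TestAromatic:
    @pytest.mark.parametrize("d,n", [(5.5, 1), (4.0, 0), (7.5, 0)])
    def test_centroid_band(self, d, n):
        s = build([_phe("A", 1, (0, 0, 0)), _phe("B", 1, (0, d, 0))])
        assert len(detect_aromatic_aromatic(s, AB_SPLIT)) == n

    def test_incomplete_ring_skipped(self, caplog):
        chain, seq, name, atoms = _phe("A", 1, (0, 0, 0))
        s = build([(chain, seq, name, atoms[:-1]), _phe("B", 1, (0, 5.5, 0))])
        with caplog.at_level("WARNING"):
            assert detect_aromatic_aromatic(s, AB_SPLIT) == []
        assert "missing atom" in caplog.text

    def test_trp_contributes_two_rings(self):
        trp_atoms = [(n, "C" if not n.startswith("N") else "N", c) for n, c in [
            ("CG", (0, 0, 0)), ("CD1", (1.1, 0, 0.8)), ("CD2", (1.1, 0, -0.8)),
            ("NE1", (2.2, 0, 0.5)), ("CE2", (2.2, 0, -0.5)),
            ("CE3", (1.4, 0, -2.1)), ("CZ2", (3.2, 0, -1.3)),
            ("CZ3", (2.4, 0, -2.9)), ("CH2", (3.4, 0, -2.6))]]
        s = build([("A", 1, "TRP", trp_atoms), _phe("B", 1, (0, 5.5, 0))])
        assert len(detect_aromatic_aromatic(s, AB_SPLIT)) == 2


class TestAromaticSulphur:
    @pytest.mark.parametrize("d,n", [(4.0, 1), (4.5, 0)])
    def test_met_sd_vs_ring(self, d, n):
        s = build([("A", 1, "MET", [("SD", "S", (0, 0, 0))]),
                   _phe("B", 1, (0, d, 0))])
        assert len(detect_aromatic_sulphur(s, AB_SPLIT)) == n


class TestCationPi:
    def test_lys_nz_vs_ring(self):
        s = build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                   _phe("B", 1, (0, 5.0, 0))])
        records = detect_cation_pi(s, AB_SPLIT)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(5.0)

    def test_arg_guanidinium_centroid_beyond(self):
        s = build([("A", 1, "ARG", [("CZ", "C", (0, 0.1, 0)),
                                    ("NH1", "N", (1, -0.1, 0)),
                                    ("NH2", "N", (-1, 0.0, 0))]),
                   _phe("B", 1, (0, 6.3, 0))])
        assert detect_cation_pi(s, AB_SPLIT) == []


class TestSaltBridges:
    def _lys_asp(self, d):
        return build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                      ("B", 1, "ASP", [("OD1", "O", (0, d, 0)),
                                       ("CA", "C", (2, d + 1, 0))])])

    def test_close_pair_is_salt_bridge(self):
        s = self._lys_asp(2.9)
        hb = detect_hbonds(s, AB_SPLIT)
        ionic = detect_ionic(s, AB_SPLIT)
        bridges = label_salt_bridges(hb, ionic)
        assert len(bridges) == 1
        assert bridges[0].kind == "salt_bridge"
        assert bridges[0].distance == pytest.approx(2.9)  # the ionic distance
        assert len(hb) == 1 and len(ionic) == 1  # inputs unmodified

    def test_ionic_only_is_not_salt_bridge(self):
        s = self._lys_asp(5.5)
        bridges = label_salt_bridges(detect_hbonds(s, AB_SPLIT),
                                     detect_ionic(s, AB_SPLIT))
        assert bridges == []

    def test_bridge_set_subset_of_both(self):
        s = oracles.random_interface(3, n_per_side=15)
        hb = detect_hbonds(s, AB_SPLIT)
        ionic = detect_ionic(s, AB_SPLIT)
        bridges = label_salt_bridges(hb, ionic)
        hb_pairs = {frozenset([r.partner_a.residue_key, r.partner_b.residue_key])
                    for r in hb}
        ionic_pairs = {frozenset([r.partner_a.residue_key, r.partner_b.residue_key])
                      for r in ionic}
        for rec in bridges:
            pair = frozenset([rec.partner_a.residue_key, rec.partner_b.residue_key])
            assert pair in hb_pairs and pair in ionic_pairs


class TestFingerprint:
    def test_far_apart_interface_empty(self):
        s = build([("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
                   ("B", 1, "GLU", [("OE1", "O", (0, 30, 0))])])
        assert fingerprint(s, AB_SPLIT) == []

    def test_anchored_lysine_complex(self):
        from turnprint.synth import make_contact_interface
        s = make_contact_interface(
            [("salt_bridge", 2.9), ("hbond", 3.0), ("hbond", 3.2)], seed=6)
        records = fingerprint(s, AB_SPLIT)
        kinds = {}
        for r in records:
            kinds[r.kind] = kinds.get(r.kind, 0) + 1
        assert kinds == {"salt_bridge": 1, "hbond": 3, "ionic": 1}

    def test_deterministic_ordering(self):
        s = oracles.random_interface(4, n_per_side=10)
        assert fingerprint(s, AB_SPLIT) == fingerprint(s, AB_SPLIT)
        kinds = [r.kind for r in fingerprint(s, AB_SPLIT)]
        assert kinds == sorted(kinds)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_interface_matches_oracle(self, seed):
        assert_matches_oracle(oracles.random_interface(seed, n_per_side=20))


class TestProperties:
    @pytest.mark.parametrize("seed", range(4))
    def test_swap_symmetry(self, seed):
        s = oracles.random_interface(10 + seed, n_per_side=12)
        forward = fingerprint(s, AB_SPLIT)
        backward = fingerprint(s, AB_SPLIT.swapped())
        assert _unordered(forward) == _unordered(backward)

    @pytest.mark.parametrize("seed", range(4))
    def test_rigid_invariance(self, seed, rigid_transform):
        s = oracles.random_interface(20 + seed, n_per_side=12)
        R, t = rigid_transform(seed)
        moved = s.transform(R, t)
        a = {(r.kind, r.partner_a, r.partner_b, round(r.distance, 6))
             for r in fingerprint(s, AB_SPLIT)}
        b = {(r.kind, r.partner_a, r.partner_b, round(r.distance, 6))
             for r in fingerprint(moved, AB_SPLIT)}
        assert {x[:3] for x in a} == {x[:3] for x in b}
        for ra, rb in zip(sorted(a), sorted(b)):
            assert ra[3] == pytest.approx(rb[3], abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_cutoff_monotonicity(self, seed):
        s = oracles.random_interface(30 + seed, n_per_side=12)
        tight = InteractionCutoffs()
        loose = InteractionCutoffs(hbond=4.0, hydrophobic=6.0, ionic=7.0,
                                   aromatic_max=8.0, aromatic_sulphur=5.0,
                                   cation_pi=7.0)
        for detector in (detect_hbonds, detect_hydrophobic, detect_ionic,
                         detect_aromatic_sulphur, detect_cation_pi):
            small = {(r.partner_a, r.partner_b) for r in detector(s, AB_SPLIT, tight)}
            big = {(r.partner_a, r.partner_b) for r in detector(s, AB_SPLIT, loose)}
            assert small <= big, detector.__name__

    def test_records_within_cutoffs(self):
        s = oracles.random_interface(40, n_per_side=15)
        bounds = {"hbond": CUTOFFS.hbond, "hydrophobic": CUTOFFS.hydrophobic,
                  "ionic": CUTOFFS.ionic, "aromatic_sulphur": CUTOFFS.aromatic_sulphur,
                  "cation_pi": CUTOFFS.cation_pi, "salt_bridge": CUTOFFS.ionic}
        for rec in fingerprint(s, AB_SPLIT):
            if rec.kind == "aromatic_aromatic":
                assert CUTOFFS.aromatic_min <= rec.distance <= CUTOFFS.aromatic_max
            else:
                assert rec.distance <= bounds[rec.kind]


class TestValidation:
    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            InterfaceSplit(frozenset("AB"), frozenset("BC"))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            InterfaceSplit(frozenset(), frozenset("B"))

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            InteractionCutoffs(hbond=-1.0)
        with pytest.raises(ValueError):
            InteractionCutoffs(aromatic_min=7.0, aromatic_max=4.5)
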