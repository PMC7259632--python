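"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive pure-Python/loop code with its own
literal typing tables, kept free of imports from the implementation
modules' internals (only the data model is shared).
"""

from __future__ import annotations

import math
from itertools import product

# --- independent typing tables (literal, not imported) -----------------

ORACLE_DONORS = {
    "backbone": ["N"],
    "ARG": ["NE", "NH1", "NH2"],
    "ASN": ["ND2"],
    "GLN": ["NE2"],
    "HIS": ["ND1", "NE2"],
    "LYS": ["NZ"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TRP": ["NE1"],
    "TYR": ["OH"],
}
ORACLE_ACCEPTORS = {
    "backbone": ["O"],
    "ASN": ["OD1"],
    "ASP": ["OD1", "OD2"],
    "GLN": ["OE1"],
    "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
}
ORACLE_APOLAR = ["ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"]
ORACLE_RINGS = {
    "PHE": [("ring6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("ring6", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TRP": [("ring5", ["CG", "CD1", "CD2", "NE1", "CE2"]),
            ("ring6", ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"])],
    "HIS": [("ring5", ["CG", "ND1", "CD2", "CE1", "NE2"])],
}
ORACLE_CATIONS = {"LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"]}
ORACLE_ANIONS = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
BACKBONE_NAMES = ["N", "CA", "C", "O", "OXT"]


def dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _chain_map(frame, chain_ids):
    return [r for r in frame.residues if r.chain_id in chain_ids]


def _termini(frame):
    first, last = set(), set()
    by_chain = {}
    for r in frame.residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for residues in by_chain.values():
        first.add(residues[0].key)
        last.add(residues[-1].key)
    return first, last


def _coord(residue, name):
    atom = residue.atom(name)
    return None if atom is None else tuple(atom.coord)


def _donor_atoms(residue, is_nterm):
    names = []
    if _coord(residue, "N") is not None and (residue.res_name != "PRO" or is_nterm):
        names.append("N")
    for n in ORACLE_DONORS.get(residue.res_name, []):
        if _coord(residue, n) is not None:
            names.append(n)
    return names


def _acceptor_atoms(residue, is_cterm):
    names = []
    if _coord(residue, "O") is not None:
        names.append("O")
    if is_cterm and _coord(residue, "OXT") is not None:
        names.append("OXT")
    for n in ORACLE_ACCEPTORS.get(residue.res_name, []):
        if _coord(residue, n) is not None:
            names.append(n)
    return names


def oracle_hbonds(frame, chains_a, chains_b, cutoff=3.5):
    """{(donor_key, donor_atom, acceptor_key, acceptor_atom, d)} over both
    donor orientations (hydrogen-free structures only)."""
    first, last = _termini(frame)
    out = set()
    side_a = _chain_map(frame, chains_a)
    side_b = _chain_map(frame, chains_b)
    for donors, acceptors in ((side_a, side_b), (side_b, side_a)):
        for rd, ra in product(donors, acceptors):
            for dn in _donor_atoms(rd, rd.key in first):
                for an in _acceptor_atoms(ra, ra.key in last):
                    d = dist(_coord(rd, dn), _coord(ra, an))
                    if d <= cutoff:
                        out.add((rd.key, dn, ra.key, an, round(d, 6)))
    return out


def oracle_hydrophobic(frame, chains_a, chains_b, cutoff=5.0):
    out = set()
    for ra in _chain_map(frame, chains_a):
        if ra.res_name not in ORACLE_APOLAR:
            continue
        ca_atoms = [a for a in ra.atoms
                    if a.element == "C" and a.name not in BACKBONE_NAMES]
        for rb in _chain_map(frame, chains_b):
            if rb.res_name not in ORACLE_APOLAR:
                continue
            cb_atoms = [a for a in rb.atoms
                        if a.element == "C" and a.name not in BACKBONE_NAMES]
            best = None
            for x, y in product(ca_atoms, cb_atoms):
                d = dist(x.coord, y.coord)
                if best is None or d < best:
                    best = d
            if best is not None and best <= cutoff:
                out.add((ra.key, rb.key, round(best, 6)))
    return out


def _cat_groups(residue, is_nterm):
    groups = []
    names = ORACLE_CATIONS.get(residue.res_name)
    if names:
        coords = [_coord(residue, n) for n in names if _coord(residue, n)]
        if coords:
            groups.append(("side", coords))
    if is_nterm and _coord(residue, "N"):
        groups.append(("nterm", [_coord(residue, "N")]))
    return groups


def _an_groups(residue, is_cterm):
    groups = []
    names = ORACLE_ANIONS.get(residue.res_name)
    if names:
        coords = [_coord(residue, n) for n in names if _coord(residue, n)]
        if coords:
            groups.append(("side", coords))
    if is_cterm:
        coords = [_coord(residue, n) for n in ("O", "OXT") if _coord(residue, n)]
        if coords:
            groups.append(("cterm", coords))
    return groups


def oracle_ionic(frame, chains_a, chains_b, cutoff=6.0):
    """{(cation_key, cation_group, anion_key, anion_group, d)} both ways."""
    first, last = _termini(frame)
    out = set()
    side_a = _chain_map(frame, chains_a)
    side_b = _chain_map(frame, chains_b)
    for cations, anions in ((side_a, side_b), (side_b, side_a)):
        for rc, ran in product(cations, anions):
            for gc, coords_c in _cat_groups(rc, rc.key in first):
                for ga, coords_a in _an_groups(ran, ran.key in last):
                    best = min(dist(p, q) for p, q in product(coords_c, coords_a))
                    if best <= cutoff:
                        out.add((rc.key, gc, ran.key, ga, round(best, 6)))
    return out


def _ring_centroids(residue):
    out = []
    for label, names in ORACLE_RINGS.get(residue.res_name, []):
        coords = [_coord(residue, n) for n in names]
        if all(c is not None for c in coords):
            centroid = tuple(sum(c[i] for c in coords) / len(coords) for i in range(3))
            out.append((label, centroid))
    return out


def oracle_aromatic_aromatic(frame, chains_a, chains_b, lo=4.5, hi=7.0):
    out = set()
    for ra in _chain_map(frame, chains_a):
        for la, ca in _ring_centroids(ra):
            for rb in _chain_map(frame, chains_b):
                for lb, cb in _ring_centroids(rb):
                    d = dist(ca, cb)
                    if lo <= d <= hi:
                        out.add((ra.key, la, rb.key, lb, round(d, 6)))
    return out


def oracle_aromatic_sulphur(frame, chains_a, chains_b, cutoff=4.3):
    sulphur = {"CYS": "SG", "MET": "SD"}
    out = set()
    side_a = _chain_map(frame, chains_a)
    side_b = _chain_map(frame, chains_b)
    for s_side, ring_side in ((side_a, side_b), (side_b, side_a)):
        for rs in s_side:
            name = sulphur.get(rs.res_name)
            if name is None or _coord(rs, name) is None:
                continue
            for rr in ring_side:
                for label, centroid in _ring_centroids(rr):
                    d = dist(_coord(rs, name), centroid)
                    if d <= cutoff:
                        out.add((rs.key, name, rr.key, label, round(d, 6)))
    return out


def oracle_cation_pi(frame, chains_a, chains_b, cutoff=6.0):
    out = set()
    side_a = _chain_map(frame, chains_a)
    side_b = _chain_map(frame, chains_b)
    for cation_side, ring_side in ((side_a, side_b), (side_b, side_a)):
        for rc in cation_side:
            points = []
            if rc.res_name == "LYS" and _coord(rc, "NZ"):
                points.append(("NZ", _coord(rc, "NZ")))
            elif rc.res_name == "ARG":
                coords = [_coord(rc, n) for n in ("CZ", "NH1", "NH2")]
                if all(c is not None for c in coords):
                    centroid = tuple(sum(c[i] for c in coords) / 3 for i in range(3))
                    points.append(("guanidinium", centroid))
            for label_c, point in points:
                for rr in ring_side:
                    for label_r, centroid in _ring_centroids(rr):
                        d = dist(point, centroid)
                        if d <= cutoff:
                            out.add((rc.key, label_c, rr.key, label_r, round(d, 6)))
    return out


def oracle_salt_bridge_pairs(hbond_set, ionic_set):
    """Residue pairs present in both oracle hbond and ionic sets (orientation
    as produced by the ionic oracle: cation first)."""
    hb_pairs = {frozenset((h[0], h[2])) for h in hbond_set}
    return {(i[0], i[2]) for i in ionic_set if frozenset((i[0], i[2])) in hb_pairs}


# --- quaternion-parameterized superposition oracle ---------------------

def quaternion_rmsd_oracle(mobile, reference, n_steps=60):
    """Minimum RMSD over proper rotations+translations, found by numeric
    minimization over a quaternion parameterization with multiple restarts."""
    import numpy as np
    from scipy.optimize import minimize

    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])

    def cost(q):
        return float(np.mean(np.sum((Pc @ rot(q).T - Qc) ** 2, axis=1)))

    rng = np.random.default_rng(12345)
    best = math.inf
    for _ in range(12):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
        best = min(best, res.fun)
    return math.sqrt(best)


# --- random-interface generator for oracle comparisons -----------------

SIDECHAINS = {
    "GLY": [],
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "PRO": ["CB", "CG", "CD"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "CYS": ["CB", "SG"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
}


def random_interface(seed, n_per_side=20, box=12.0, gap=-2.0):
    """Two-chain structure with residues scattered near the x=0 plane.

    Atom positions are random within 2.5 Å of the residue center, so all
    interaction kinds occur with useful frequency. ``gap`` shifts the two
    slabs apart (negative values interleave them).
    """
    import numpy as np
    from turnprint.structure import Atom, Residue, Structure

    rng = np.random.default_rng(seed)
    names = list(SIDECHAINS)
    residues = []
    serial = 0
    for chain_id, sign in (("A", -1.0), ("B", 1.0)):
        for i in range(n_per_side):
            res_name = names[rng.integers(len(names))]
            center = np.array([
                sign * (gap / 2.0 + rng.uniform(0, box / 2.0)),
                rng.uniform(0, box), rng.uniform(0, box)])
            residue = Residue(chain_id, i + 1, res_name)
            for atom_name in ["N", "CA", "C", "O"] + SIDECHAINS[res_name]:
                serial += 1
                coord = center + rng.uniform(-2.5, 2.5, size=3)
                element = atom_name[0] if atom_name[0] in "NOCS" else "C"
                residue.atoms.append(Atom(serial, atom_name, element, coord))
            residues.append(residue)
    return Structure(residues, source=f"random_interface seed={seed}")
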