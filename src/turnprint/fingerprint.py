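"""Six-class non-covalent interaction detection across a two-sided interface.

Distance criteria: hydrogen bonds at 3.5 Å between heavy donor/acceptor
atoms (plus a 120° donor–H–acceptor angle test when explicit hydrogens are
present), hydrophobic side-chain carbon contacts at 5 Å, ionic group
contacts at 6 Å, aromatic ring-centroid pairs within 4.5–7 Å,
aromatic–sulphur at 4.3 Å and cation–π at 6 Å. A residue pair linked by
both a hydrogen bond and an ionic interaction is additionally labeled a
salt bridge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .structure import Residue, Structure

__all__ = [
    "InteractionCutoffs",
    "InterfaceSplit",
    "Partner",
    "InteractionRecord",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_ionic",
    "detect_aromatic_aromatic",
    "detect_aromatic_sulphur",
    "detect_cation_pi",
    "label_salt_bridges",
    "fingerprint",
    "APOLAR_RESIDUES",
    "SIDECHAIN_DONORS",
    "SIDECHAIN_ACCEPTORS",
    "AROMATIC_RINGS",
]

logger = logging.getLogger(__name__)

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: apolar residues considered for hydrophobic side-chain contacts
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}

#: side-chain hydrogen-bond donor heavy atoms per residue type
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

#: side-chain hydrogen-bond acceptor heavy atoms per residue type
SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}

#: aromatic ring atom sets (all atoms required to form a centroid)
AROMATIC_RINGS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "PHE": [("ring6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("ring6", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TRP": [("ring5", ("CG", "CD1", "CD2", "NE1", "CE2")),
            ("ring6", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"))],
    "HIS": [("ring5", ("CG", "ND1", "CD2", "CE1", "NE2"))],
}

CATIONIC_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
HIS_CATIONIC_ATOMS: tuple[str, ...] = ("ND1", "NE2")

ANIONIC_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class InteractionCutoffs:
    """Distance cutoffs (Å) for the interaction classes."""

    hbond: float = 3.5
    hydrophobic: float = 5.0
    ionic: float = 6.0
    aromatic_min: float = 4.5
    aromatic_max: float = 7.0
    aromatic_sulphur: float = 4.3
    cation_pi: float = 6.0
    hbond_angle_min: float = 120.0  # degrees, applied only with explicit H
    include_his_cation: bool = False  # neutral histidine at pH 7

    def __post_init__(self) -> None:
        for name in ("hbond", "hydrophobic", "ionic", "aromatic_min",
                     "aromatic_max", "aromatic_sulphur", "cation_pi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")
        if self.aromatic_min >= self.aromatic_max:
            raise ValueError("aromatic_min must be below aromatic_max")


@dataclass(frozen=True)
class InterfaceSplit:
    """Two disjoint chain-id sets defining the interface sides."""

    selection_a: frozenset[str]
    selection_b: frozenset[str]

    def __post_init__(self) -> None:
        a = frozenset(self.selection_a)
        b = frozenset(self.selection_b)
        object.__setattr__(self, "selection_a", a)
        object.__setattr__(self, "selection_b", b)
        if not a or not b:
            raise ValueError("both selections must be non-empty")
        if a & b:
            raise ValueError(f"selections overlap: {sorted(a & b)}")

    def swapped(self) -> "InterfaceSplit":
        return InterfaceSplit(self.selection_b, self.selection_a)


@dataclass(frozen=True, order=True)
class Partner:
    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    group: str
    mainchain: bool

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


@dataclass(frozen=True, order=True)
class InteractionRecord:
    kind: str
    partner_a: Partner
    partner_b: Partner
    distance: float


def _sides(frame: Structure, split: InterfaceSplit
           ) -> tuple[list[Residue], list[Residue]]:
    side_a = [r for r in frame.residues if r.chain_id in split.selection_a]
    side_b = [r for r in frame.residues if r.chain_id in split.selection_b]
    return side_a, side_b


def _terminal_residues(frame: Structure) -> tuple[set[tuple[str, int, str]],
                                                  set[tuple[str, int, str]]]:
    """Residue keys of the first (N-terminal) and last (C-terminal) residue
    of each chain."""
    ntermini: set[tuple[str, int, str]] = set()
    ctermini: set[tuple[str, int, str]] = set()
    for residues in frame.chains.values():
        ntermini.add(residues[0].key)
        ctermini.add(residues[-1].key)
    return ntermini, ctermini


def _partner(residue: Residue, group: str, mainchain: bool) -> Partner:
    return Partner(residue.chain_id, residue.res_seq, residue.insertion_code,
                   residue.res_name, group, mainchain)


def _bonded_hydrogens(residue: Residue, donor_name: str) -> list[np.ndarray]:
    donor = residue.atom(donor_name)
    if donor is None:
        return []
    out = []
    for atom in residue.atoms:
        if atom.is_hydrogen and np.linalg.norm(atom.coord - donor.coord) < 1.25:
            out.append(atom.coord)
    return out


def _donors(residue: Residue, is_nterm: bool) -> list[tuple[str, bool]]:
    names: list[tuple[str, bool]] = []
    if residue.atom("N") is not None and (residue.res_name != "PRO" or is_nterm):
        names.append(("N", True))
    for name in sorted(SIDECHAIN_DONORS.get(residue.res_name, ())):
        if residue.atom(name) is not None:
            names.append((name, False))
    return names


def _acceptors(residue: Residue, is_cterm: bool) -> list[tuple[str, bool]]:
    names: list[tuple[str, bool]] = []
    if residue.atom("O") is not None:
        names.append(("O", True))
    if is_cterm and residue.atom("OXT") is not None:
        names.append(("OXT", True))
    for name in sorted(SIDECHAIN_ACCEPTORS.get(residue.res_name, ())):
        if residue.atom(name) is not None:
            names.append((name, False))
    return names


def detect_hbonds(frame: Structure, split: InterfaceSplit,
                  cutoffs: InteractionCutoffs = InteractionCutoffs()
                  ) -> list[InteractionRecord]:
    """Cross-interface donor/acceptor heavy-atom pairs within the cutoff.

    When the donor carries explicit hydrogens, at least one donor–H–acceptor
    angle must reach ``cutoffs.hbond_angle_min``; without hydrogens the
    criterion is distance-only.
    """
    side_a, side_b = _sides(frame, split)
    ntermini, ctermini = _terminal_residues(frame)
    records: list[InteractionRecord] = []

    def scan(donor_side: list[Residue], acceptor_side: list[Residue],
             a_is_donor: bool) -> None:
        for res_d in donor_side:
            for donor_name, d_main in _donors(res_d, res_d.key in ntermini):
                donor = res_d.atom(donor_name)
                hydrogens = _bonded_hydrogens(res_d, donor_name)
                for res_a in acceptor_side:
                    for acc_name, a_main in _acceptors(res_a, res_a.key in ctermini):
                        acceptor = res_a.atom(acc_name)
                        dist = float(np.linalg.norm(donor.coord - acceptor.coord))
                        if dist > cutoffs.hbond:
                            continue
                        if hydrogens and not _angle_ok(donor.coord, hydrogens,
                                                      acceptor.coord,
                                                      cutoffs.hbond_angle_min):
                            continue
                        pd = _partner(res_d, donor_name, d_main)
                        pa = _partner(res_a, acc_name, a_main)
                        if a_is_donor:
                            records.append(InteractionRecord("hbond", pd, pa, dist))
                        else:
                            records.append(InteractionRecord("hbond", pa, pd, dist))

    scan(side_a, side_b, True)
    scan(side_b, side_a, False)
    return sorted(set(records))


def _angle_ok(donor: np.ndarray, hydrogens: list[np.ndarray],
              acceptor: np.ndarray, min_angle: float) -> bool:
    for h in hydrogens:
        v1 = donor - h
        v2 = acceptor - h
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        angle = np.degrees(np.arccos(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)))
        if angle >= min_angle:
            return True
    return False


def _sidechain_carbons(residue: Residue) -> list[np.ndarray]:
    return [a.coord for a in residue.atoms
            if a.element.upper() == "C" and a.name not in MAINCHAIN_ATOMS]


def detect_hydrophobic(frame: Structure, split: InterfaceSplit,
                       cutoffs: InteractionCutoffs = InteractionCutoffs()
                       ) -> list[InteractionRecord]:
    """Apolar residue pairs with any side-chain carbon contact within cutoff."""
    side_a, side_b = _sides(frame, split)
    records = []
    for res_a in side_a:
        if res_a.res_name not in APOLAR_RESIDUES:
            continue
        carbons_a = _sidechain_carbons(res_a)
        if not carbons_a:
            continue
        ca = np.array(carbons_a)
        for res_b in side_b:
            if res_b.res_name not in APOLAR_RESIDUES:
                continue
            carbons_b = _sidechain_carbons(res_b)
            if not carbons_b:
                continue
            cb = np.array(carbons_b)
            d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2))
            dmin = float(d.min())
            if dmin <= cutoffs.hydrophobic:
                records.append(InteractionRecord(
                    "hydrophobic",
                    _partner(res_a, "sidechain", False),
                    _partner(res_b, "sidechain", False),
                    dmin))
    return sorted(records)


def _cationic_groups(residue: Residue, is_nterm: bool, include_his: bool,
                     include_termini: bool = True
                     ) -> list[tuple[str, np.ndarray, bool]]:
    """(group label, member atom coords, mainchain flag) for cationic groups."""
    groups: list[tuple[str, np.ndarray, bool]] = []
    atom_names = CATIONIC_SIDECHAINS.get(residue.res_name)
    if atom_names is None and include_his and residue.res_name == "HIS":
        atom_names = HIS_CATIONIC_ATOMS
    if atom_names:
        coords = [residue.atom(n).coord for n in atom_names
                  if residue.atom(n) is not None]
        if coords:
            groups.append(("+" + "/".join(atom_names), np.array(coords), False))
    if include_termini and is_nterm and residue.atom("N") is not None:
        groups.append(("+Nterm", np.array([residue.atom("N").coord]), True))
    return groups


def _anionic_groups(residue: Residue, is_cterm: bool
                    ) -> list[tuple[str, np.ndarray, bool]]:
    groups: list[tuple[str, np.ndarray, bool]] = []
    atom_names = ANIONIC_SIDECHAINS.get(residue.res_name)
    if atom_names:
        coords = [residue.atom(n).coord for n in atom_names
                  if residue.atom(n) is not None]
        if coords:
            groups.append(("-" + "/".join(atom_names), np.array(coords), False))
    if is_cterm:
        coords = [residue.atom(n).coord for n in ("O", "OXT")
                  if residue.atom(n) is not None]
        if coords:
            groups.append(("-Cterm", np.array(coords), True))
    return groups


def detect_ionic(frame: Structure, split: InterfaceSplit,
                 cutoffs: InteractionCutoffs = InteractionCutoffs()
                 ) -> list[InteractionRecord]:
    """Cross-interface (cationic group, anionic group) pairs within cutoff."""
    side_a, side_b = _sides(frame, split)
    ntermini, ctermini = _terminal_residues(frame)
    records = []

    def scan(cation_side: list[Residue], anion_side: list[Residue],
             cation_is_a: bool) -> None:
        for res_c in cation_side:
            for label_c, coords_c, main_c in _cationic_groups(
                    res_c, res_c.key in ntermini, cutoffs.include_his_cation):
                for res_an in anion_side:
                    for label_a, coords_a, main_a in _anionic_groups(
                            res_an, res_an.key in ctermini):
                        d = np.sqrt(((coords_c[:, None, :] - coords_a[None, :, :]) ** 2
                                     ).sum(axis=2))
                        dmin = float(d.min())
                        if dmin > cutoffs.ionic:
                            continue
                        pc = _partner(res_c, label_c, main_c)
                        pa = _partner(res_an, label_a, main_a)
                        if cation_is_a:
                            records.append(InteractionRecord("ionic", pc, pa, dmin))
                        else:
                            records.append(InteractionRecord("ionic", pa, pc, dmin))

    scan(side_a, side_b, True)
    scan(side_b, side_a, False)
    return sorted(set(records))


def _rings(residue: Residue) -> list[tuple[str, np.ndarray]]:
    """(label, centroid) for each complete aromatic ring of the residue."""
    out = []
    for label, atom_names in AROMATIC_RINGS.get(residue.res_name, ()):
        coords = []
        for name in atom_names:
            atom = residue.atom(name)
            if atom is None:
                logger.warning("skipping %s ring of %s %s%s: missing atom %s",
                               label, residue.res_name, residue.chain_id,
                               residue.res_seq, name)
                coords = None
                break
            coords.append(atom.coord)
        if coords:
            out.append((label, np.mean(coords, axis=0)))
    return out


def detect_aromatic_aromatic(frame: Structure, split: InterfaceSplit,
                             cutoffs: InteractionCutoffs = InteractionCutoffs()
                             ) -> list[InteractionRecord]:
    """Ring pairs with centroid separation inside [aromatic_min, aromatic_max]."""
    side_a, side_b = _sides(frame, split)
    records = []
    for res_a in side_a:
        for label_a, centroid_a in _rings(res_a):
            for res_b in side_b:
                for label_b, centroid_b in _rings(res_b):
                    dist = float(np.linalg.norm(centroid_a - centroid_b))
                    if cutoffs.aromatic_min <= dist <= cutoffs.aromatic_max:
                        records.append(InteractionRecord(
                            "aromatic_aromatic",
                            _partner(res_a, label_a, False),
                            _partner(res_b, label_b, False),
                            dist))
    return sorted(records)


_SULPHUR_ATOMS = {"CYS": "SG", "MET": "SD"}


def detect_aromatic_sulphur(frame: Structure, split: InterfaceSplit,
                            cutoffs: InteractionCutoffs = InteractionCutoffs()
                            ) -> list[InteractionRecord]:
    """Sulphur (CYS SG / MET SD) to aromatic-ring-centroid pairs within cutoff."""
    side_a, side_b = _sides(frame, split)
    records = []

    def scan(s_side: list[Residue], ring_side: list[Residue], s_is_a: bool) -> None:
        for res_s in s_side:
            s_name = _SULPHUR_ATOMS.get(res_s.res_name)
            if s_name is None or res_s.atom(s_name) is None:
                continue
            s_coord = res_s.atom(s_name).coord
            for res_r in ring_side:
                for label, centroid in _rings(res_r):
                    dist = float(np.linalg.norm(s_coord - centroid))
                    if dist > cutoffs.aromatic_sulphur:
                        continue
                    ps = _partner(res_s, s_name, False)
                    pr = _partner(res_r, label, False)
                    if s_is_a:
                        records.append(InteractionRecord("aromatic_sulphur", ps, pr, dist))
                    else:
                        records.append(InteractionRecord("aromatic_sulphur", pr, ps, dist))

    scan(side_a, side_b, True)
    scan(side_b, side_a, False)
    return sorted(set(records))


def _cation_points(residue: Residue, include_his: bool
                   ) -> list[tuple[str, np.ndarray]]:
    """Cation positions for cation-π: LYS NZ; ARG guanidinium centroid
    (CZ/NH1/NH2); optionally the HIS ring centroid. Termini excluded."""
    out = []
    if residue.res_name == "LYS" and residue.atom("NZ") is not None:
        out.append(("NZ", residue.atom("NZ").coord))
    elif residue.res_name == "ARG":
        coords = [residue.atom(n).coord for n in ("CZ", "NH1", "NH2")
                  if residue.atom(n) is not None]
        if len(coords) == 3:
            out.append(("guanidinium", np.mean(coords, axis=0)))
    elif include_his and residue.res_name == "HIS":
        rings = _rings(residue)
        if rings:
            out.append(("ring5", rings[0][1]))
    return out


def detect_cation_pi(frame: Structure, split: InterfaceSplit,
                     cutoffs: InteractionCutoffs = InteractionCutoffs()
                     ) -> list[InteractionRecord]:
    """Cationic side-chain group to aromatic-ring-centroid pairs within cutoff."""
    side_a, side_b = _sides(frame, split)
    records = []

    def scan(cation_side: list[Residue], ring_side: list[Residue],
             cation_is_a: bool) -> None:
        for res_c in cation_side:
            for label_c, point in _cation_points(res_c, cutoffs.include_his_cation):
                for res_r in ring_side:
                    for label_r, centroid in _rings(res_r):
                        dist = float(np.linalg.norm(point - centroid))
                        if dist > cutoffs.cation_pi:
                            continue
                        pc = _partner(res_c, label_c, False)
                        pr = _partner(res_r, label_r, False)
                        if cation_is_a:
                            records.append(InteractionRecord("cation_pi", pc, pr, dist))
                        else:
                            records.append(InteractionRecord("cation_pi", pr, pc, dist))

    scan(side_a, side_b, True)
    scan(side_b, side_a, False)
    return sorted(set(records))


def label_salt_bridges(hbonds: list[InteractionRecord],
                       ionic: list[InteractionRecord]
                       ) -> list[InteractionRecord]:
    """One salt_bridge record per residue pair present in both input sets.

    The reported distance is the ionic record's distance; inputs are not
    modified.
    """
    hbond_pairs = {(r.partner_a.residue_key, r.partner_b.residue_key)
                   for r in hbonds}
    seen: set[tuple] = set()
    out = []
    for rec in ionic:
        pair = (rec.partner_a.residue_key, rec.partner_b.residue_key)
        if pair in hbond_pairs and pair not in seen:
            seen.add(pair)
            out.append(replace(rec, kind="salt_bridge"))
    return sorted(out)


def fingerprint(frame: Structure, split: InterfaceSplit,
                cutoffs: InteractionCutoffs = InteractionCutoffs()
                ) -> list[InteractionRecord]:
    """All seven interaction kinds across the interface, deterministically
    ordered by (kind, partner identities)."""
    hbonds = detect_hbonds(frame, split, cutoffs)
    ionic = detect_ionic(frame, split, cutoffs)
    records = (
        hbonds
        + ionic
        + detect_hydrophobic(frame, split, cutoffs)
        + detect_aromatic_aromatic(frame, split, cutoffs)
        + detect_aromatic_sulphur(frame, split, cutoffs)
        + detect_cation_pi(frame, split, cutoffs)
        + label_salt_bridges(hbonds, ionic)
    )
    return sorted(records)
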