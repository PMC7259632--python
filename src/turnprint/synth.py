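"""Deterministic, seeded generators for every fixture class the analyses need.

Generated structures are geometric stand-ins, not chemically minimized
models: detectors operate on atom typing and distances only, so backbones
are built from idealized 3.8 Å Cα virtual bonds and side chains are placed
along straight directions. Identical arguments (including seed) produce
byte-identical PDB output.
"""

from __future__ import annotations

import math
import string

import numpy as np
from scipy.optimize import brentq

from .errors import FeasibilityError, PlacementError
from .fingerprint import InteractionCutoffs
from .structure import Atom, Residue, Structure, Trajectory

__all__ = [
    "make_turn_peptide",
    "make_contact_interface",
    "make_occupancy_trajectory",
    "make_multimer_stack",
    "expected_fingerprint_kinds",
    "contact_distance_range",
]

CA_STEP = 3.8  # Å between consecutive Cα positions

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _random_rigid_transform(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-10.0, 10.0, size=3)
    return Q, t


def _arc_theta(span_target: float, n_steps: int) -> float:
    """Step angle of a circular Cα arc whose end-to-end chord over
    ``n_steps`` virtual bonds equals ``span_target``."""
    max_span = CA_STEP * n_steps

    def chord(theta: float) -> float:
        radius = (CA_STEP / 2.0) / math.sin(theta / 2.0)
        return 2.0 * radius * math.sin(n_steps * theta / 2.0)

    if not (0.5 < span_target < max_span - 1e-6):
        raise FeasibilityError(
            f"span {span_target} Å is not realizable with {n_steps} virtual "
            f"bonds of {CA_STEP} Å (feasible range ~(0.5, {max_span:.2f}))")
    lo, hi = 1e-6, 2.0 * math.pi / n_steps - 1e-6
    return float(brentq(lambda th: chord(th) - span_target, lo, hi, xtol=1e-12))


def _lysine_sidechain(ca: np.ndarray, direction: np.ndarray,
                      nz_target: np.ndarray | None = None) -> list[tuple[str, np.ndarray]]:
    """CB..NZ along ``direction``; with ``nz_target`` the chain is rescaled
    so NZ lands exactly there."""
    names = ["CB", "CG", "CD", "CE", "NZ"]
    if nz_target is None:
        nz_target = ca + 6.0 * direction
    start = ca + 1.5 * direction
    return [(name, start + (nz_target - start) * (i / (len(names) - 1)))
            for i, name in enumerate(names)]


def _aspartate_sidechain(ca: np.ndarray, direction: np.ndarray,
                         up: np.ndarray) -> list[tuple[str, np.ndarray]]:
    return [("CB", ca + 1.5 * direction),
            ("CG", ca + 2.8 * direction),
            ("OD1", ca + 3.6 * direction + 0.6 * up),
            ("OD2", ca + 3.6 * direction - 0.6 * up)]


def make_turn_peptide(span_target: float, n_res: int = 5, seed: int = 0, *,
                      chain_id: str = "A", start_res: int = 25,
                      span_between: tuple[int, int] | None = None,
                      key_res: int | None = None, key_dir: str = "out",
                      asp_res: int | None = None,
                      asp_dir: str = "out") -> Structure:
    """Peptide chain whose Cα(span) distance hits ``span_target`` ± 0.05 Å.

    Residues of the span window sit on a circular arc; flanking residues
    continue along the arc tangents. All residues carry N/CA/C/O backbone
    atoms; ``key_res`` (default: fourth residue of the window, i.e. 28 for
    the 25–29 default) is a lysine with a full CB–NZ side chain pointing
    ``key_dir`` ('out' radially, 'in', 'up', or 'cterm' toward the chain's
    C-terminal carbonyl). ``asp_res`` optionally makes that residue an
    aspartate with a carboxylate side chain. A seeded rigid-body transform
    is applied, so spans and contacts are seed-invariant but absolute
    coordinates are not.
    """
    if n_res < 2:
        raise FeasibilityError("need at least 2 residues")
    end_res = start_res + n_res - 1
    if span_between is None:
        span_between = (start_res, end_res)
    lo, hi = span_between
    if not (start_res <= lo < hi <= end_res):
        raise ValueError(f"span_between {span_between} outside residue range")
    if key_res is None:
        candidate = lo + 3
        key_res = candidate if candidate <= end_res else None

    theta = _arc_theta(span_target, hi - lo)
    radius = (CA_STEP / 2.0) / math.sin(theta / 2.0)

    # window residues on the arc, flanks along the end tangents
    def arc_point(angle: float) -> np.ndarray:
        return np.array([radius * math.cos(angle), radius * math.sin(angle), 0.0])

    def tangent(angle: float) -> np.ndarray:
        return np.array([-math.sin(angle), math.cos(angle), 0.0])

    ca_coords: dict[int, np.ndarray] = {}
    for k, res in enumerate(range(lo, hi + 1)):
        ca_coords[res] = arc_point(k * theta)
    for i, res in enumerate(range(lo - 1, start_res - 1, -1), start=1):
        ca_coords[res] = arc_point(0.0) - i * CA_STEP * tangent(0.0)
    end_angle = (hi - lo) * theta
    for i, res in enumerate(range(hi + 1, end_res + 1), start=1):
        ca_coords[res] = arc_point(end_angle) + i * CA_STEP * tangent(end_angle)

    up = np.array([0.0, 0.0, 1.0])
    residues: list[Residue] = []
    atom_serial = 0
    cterm_o: np.ndarray | None = None

    def direction_vector(mode: str, ca: np.ndarray) -> np.ndarray:
        radial = ca - np.array([0.0, 0.0, ca[2]])
        norm = np.linalg.norm(radial)
        radial = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        if mode == "out":
            return radial
        if mode == "in":
            return -radial
        if mode == "up":
            return up
        raise ValueError(f"unknown direction {mode!r}")

    order = list(range(start_res, end_res + 1))
    for res_seq in order:
        ca = ca_coords[res_seq]
        nxt = ca_coords.get(res_seq + 1)
        prv = ca_coords.get(res_seq - 1)
        if nxt is not None:
            forward = nxt - ca
        else:
            forward = ca - prv
        forward = forward / np.linalg.norm(forward)
        res_name = "GLY"
        if res_seq == key_res:
            res_name = "LYS"
        elif res_seq == asp_res:
            res_name = "ASP"
        atoms: list[tuple[str, np.ndarray]] = [
            ("N", ca - 1.2 * forward + 0.5 * up),
            ("CA", ca),
            ("C", ca + 1.2 * forward + 0.5 * up),
            ("O", ca + 1.4 * forward + 1.6 * up),
        ]
        if res_seq == end_res:
            atoms.append(("OXT", ca + 2.4 * forward + 0.8 * up))
            cterm_o = atoms[3][1]
        residue = Residue(chain_id, res_seq, res_name)
        for name, coord in atoms:
            atom_serial += 1
            element = name[0] if name[0] in "NOCS" else "C"
            residue.atoms.append(Atom(atom_serial, name, element, coord))
        residues.append(residue)

    # side chains placed after the backbone so 'cterm' can target the real O
    for residue in residues:
        ca = residue.atom("CA").coord
        if residue.res_name == "LYS":
            if key_dir == "cterm":
                target_o = residues[-1].atom("O").coord
                u = target_o - ca
                u = u / np.linalg.norm(u)
                placement = _lysine_sidechain(ca, u, nz_target=target_o - 3.0 * u)
            else:
                placement = _lysine_sidechain(ca, direction_vector(key_dir, ca))
        elif residue.res_name == "ASP":
            placement = _aspartate_sidechain(ca, direction_vector(asp_dir, ca), up)
        else:
            continue
        for name, coord in placement:
            atom_serial += 1
            element = name[0]
            residue.atoms.append(Atom(atom_serial, name, element, coord))

    structure = Structure(residues, source=f"turn_peptide span={span_target}")
    R, t = _random_rigid_transform(seed)
    return structure.transform(R, t)


#: contact kinds the interface generator can plant, with the residue
#: templates used for each (chosen so no side-effect contacts of any
#: plantable kind arise; e.g. HIS carries the aromatic ring for
#: aromatic-aromatic contacts because PHE/TYR/TRP would add a hydrophobic
#: side-chain-carbon contact at short range)
PLANTABLE_KINDS = ("hbond", "ionic", "salt_bridge", "hydrophobic",
                   "aromatic_aromatic", "aromatic_sulphur", "cation_pi")


def contact_distance_range(kind: str,
                           cutoffs: InteractionCutoffs = InteractionCutoffs()
                           ) -> tuple[float, float]:
    """Closed feasible [min, max] planting distance for a contact kind."""
    ranges = {
        "hbond": (2.4, cutoffs.hbond),
        "salt_bridge": (2.5, cutoffs.hbond),
        "ionic": (cutoffs.hbond + 0.15, cutoffs.ionic),
        "hydrophobic": (2.0, cutoffs.hydrophobic),
        "aromatic_aromatic": (cutoffs.aromatic_min, cutoffs.aromatic_max),
        "aromatic_sulphur": (2.5, cutoffs.aromatic_sulphur),
        "cation_pi": (2.5, cutoffs.cation_pi),
    }
    if kind not in ranges:
        raise PlacementError(f"unknown contact kind {kind!r}")
    return ranges[kind]


def _hexagon(center: np.ndarray, radius: float = 1.39, phase: float = 0.0
             ) -> list[np.ndarray]:
    """Six points in the xz-plane around ``center`` (ring normal along y)."""
    pts = []
    for k in range(6):
        ang = phase + k * math.pi / 3.0
        pts.append(center + radius * np.array([math.cos(ang), 0.0, math.sin(ang)]))
    return pts


def _pentagon(center: np.ndarray, radius: float = 1.17) -> list[np.ndarray]:
    pts = []
    for k in range(5):
        ang = k * 2.0 * math.pi / 5.0
        pts.append(center + radius * np.array([math.cos(ang), 0.0, math.sin(ang)]))
    return pts


def _backbone(base: np.ndarray) -> list[tuple[str, np.ndarray]]:
    return [("N", base + np.array([-1.2, 0.0, 0.0])),
            ("CA", base),
            ("C", base + np.array([1.2, 0.0, 0.0])),
            ("O", base + np.array([1.2, 0.0, 1.2]))]


def _site_residues(kind: str, x: float, d: float) -> tuple[tuple[str, list], tuple[str, list]]:
    """Residue templates (res_name, [(atom_name, coord), ...]) for one planted
    contact along the +y axis at slab position ``x``."""
    a_base = np.array([x, -3.0, 0.0])
    b_base = np.array([x, d + 3.0, 0.0])
    a_site = np.array([x, 0.0, 0.0])
    b_site = np.array([x, d, 0.0])

    if kind == "hbond":  # SER OG donor -> backbone O acceptor
        res_a = ("SER", _backbone(a_base) + [("CB", a_base + [0, 1.5, 0]),
                                             ("OG", a_site)])
        res_b = ("GLY", [("N", b_base + [-1.2, 0, 0]), ("CA", b_base),
                         ("C", b_base + [1.2, 0, 0]), ("O", b_site)])
        return res_a, res_b
    if kind in ("ionic", "salt_bridge"):  # LYS NZ vs GLU carboxylate
        res_a = ("LYS", _backbone(a_base)
                 + [("CB", a_base + [0, 0.8, 0]), ("CG", a_base + [0, 1.5, 0]),
                    ("CD", a_base + [0, 2.0, 0]), ("CE", a_base + [0, 2.5, 0]),
                    ("NZ", a_site)])
        res_b = ("GLU", _backbone(b_base)
                 + [("CB", b_base + [0, -0.8, 0]), ("CG", b_base + [0, -1.5, 0]),
                    ("CD", b_base + [0, -2.2, 0]), ("OE1", b_site),
                    ("OE2", b_site + [0, 1.2, 1.5])])
        return res_a, res_b
    if kind == "hydrophobic":  # LEU CD1 vs VAL CG1
        res_a = ("LEU", _backbone(a_base) + [("CB", a_base + [0, 1.0, 0]),
                                             ("CG", a_base + [0, 2.0, 0]),
                                             ("CD1", a_site),
                                             ("CD2", a_base + [0.9, 2.4, 0.9])])
        res_b = ("VAL", _backbone(b_base) + [("CB", b_base + [0, -1.5, 0]),
                                             ("CG1", b_site),
                                             ("CG2", b_base + [0.9, -2.0, 0.9])])
        return res_a, res_b
    if kind == "aromatic_aromatic":  # HIS ring vs HIS ring (HIS is not apolar)
        ring_a = _pentagon(a_site)
        ring_b = _pentagon(b_site)
        names = ("CG", "ND1", "CD2", "CE1", "NE2")
        res_a = ("HIS", _backbone(a_base) + [("CB", a_base + [0, 1.2, 0])]
                 + list(zip(names, ring_a)))
        res_b = ("HIS", _backbone(b_base) + [("CB", b_base + [0, -1.2, 0])]
                 + list(zip(names, ring_b)))
        return res_a, res_b
    if kind == "aromatic_sulphur":  # CYS SG vs HIS ring centroid
        res_a = ("CYS", _backbone(a_base) + [("CB", a_base + [0, 1.5, 0]),
                                             ("SG", a_site)])
        names = ("CG", "ND1", "CD2", "CE1", "NE2")
        res_b = ("HIS", _backbone(b_base) + [("CB", b_base + [0, -1.2, 0])]
                 + list(zip(names, _pentagon(b_site))))
        return res_a, res_b
    if kind == "cation_pi":  # LYS NZ vs PHE ring centroid
        res_a = ("LYS", _backbone(a_base)
                 + [("CB", a_base + [0, 0.8, 0]), ("CG", a_base + [0, 1.5, 0]),
                    ("CD", a_base + [0, 2.0, 0]), ("CE", a_base + [0, 2.5, 0]),
                    ("NZ", a_site)])
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        res_b = ("PHE", _backbone(b_base) + [("CB", b_base + [0, -1.2, 0])]
                 + list(zip(names, _hexagon(b_site))))
        return res_a, res_b
    raise PlacementError(f"unknown contact kind {kind!r}")


def make_contact_interface(contacts: list[tuple[str, float]], seed: int = 0,
                           cutoffs: InteractionCutoffs = InteractionCutoffs()
                           ) -> Structure:
    """Two-chain structure whose fingerprint is exactly the planted contacts.

    ``contacts`` is a list of (kind, distance) pairs; sites are laid out
    30 Å apart so planted contacts cannot interfere, and padding glycines
    keep the charged chain termini remote from every site. Distances are
    validated against :func:`contact_distance_range`. A seeded rigid-body
    transform is applied to the assembled structure.
    """
    if not contacts:
        raise PlacementError("at least one contact is required")
    for kind, d in contacts:
        lo, hi = contact_distance_range(kind, cutoffs)
        if not (lo <= d <= hi):
            raise PlacementError(
                f"{kind} at {d} Å is outside the plantable range [{lo}, {hi}]")

    chain_a: list[tuple[str, list]] = []
    chain_b: list[tuple[str, list]] = []
    n = len(contacts)
    # N-terminal pads (carry the charged N-terminus, far from all sites)
    chain_a.append(("GLY", _backbone(np.array([-40.0, -5.0, 0.0]))))
    chain_b.append(("GLY", _backbone(np.array([-40.0, 5.0, 0.0]))))
    for i, (kind, d) in enumerate(contacts):
        res_a, res_b = _site_residues(kind, 30.0 * i, d)
        chain_a.append(res_a)
        chain_b.append(res_b)
    xmax = 30.0 * (n - 1) + 40.0
    chain_a.append(("GLY", _backbone(np.array([xmax, -5.0, 0.0]))))
    chain_b.append(("GLY", _backbone(np.array([xmax, 5.0, 0.0]))))

    residues = []
    serial = 0
    for chain_id, entries in (("A", chain_a), ("B", chain_b)):
        for res_seq, (res_name, atoms) in enumerate(entries, start=1):
            residue = Residue(chain_id, res_seq, res_name)
            for name, coord in atoms:
                serial += 1
                element = name[0] if name[0] in "NOCS" else "C"
                residue.atoms.append(Atom(serial, name, element, np.asarray(coord, float)))
            residues.append(residue)
    structure = Structure(residues, source=f"contact_interface n={n}")
    R, t = _random_rigid_transform(seed)
    return structure.transform(R, t)


def expected_fingerprint_kinds(contacts: list[tuple[str, float]]) -> dict[str, int]:
    """Record counts per kind that fingerprint() must report for a structure
    built by :func:`make_contact_interface`."""
    counts: dict[str, int] = {}

    def add(kind: str, n: int = 1) -> None:
        counts[kind] = counts.get(kind, 0) + n

    for kind, _ in contacts:
        if kind == "salt_bridge":
            add("hbond")
            add("ionic")
            add("salt_bridge")
        else:
            add(kind)
    return counts


def make_occupancy_trajectory(base: Structure, mobile: tuple[str, int],
                              n_frames: int | None = None,
                              mask: list[bool] | None = None,
                              p: float | None = None, seed: int = 0,
                              displacement: float = 40.0) -> Trajectory:
    """Multi-frame trajectory in which the residue ``mobile`` is displaced
    far beyond every cutoff in masked-out frames.

    Exactly one of ``mask`` (explicit per-frame presence) or ``p`` with
    ``n_frames`` (seeded Bernoulli presence) must be given.
    """
    if mask is None:
        if p is None or n_frames is None:
            raise ValueError("provide mask, or p together with n_frames")
        rng = np.random.default_rng(seed)
        mask = [bool(v) for v in rng.random(n_frames) < p]
    chain_id, res_seq = mobile
    if base.get_residue(chain_id, res_seq) is None:
        raise ValueError(f"mobile residue {mobile} absent from base structure")
    offset = np.array([0.0, 0.0, displacement])
    frames = []
    for present in mask:
        frame = base.copy()
        if not present:
            residue = frame.get_residue(chain_id, res_seq)
            for atom in residue.atoms:
                atom.coord = atom.coord + offset
        frames.append(frame)
    return Trajectory(frames)


def make_multimer_stack(unit: Structure, n_chains: int, spacing: float,
                        seed: int = 0, axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
                        ) -> Structure:
    """``n_chains`` translated copies of a single-chain unit along one axis.

    Chains are relabeled A, B, C, …; equivalent-atom spacing between
    consecutive copies equals ``spacing`` exactly (pure translation).
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_chains > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} chains supported")
    axis_v = np.asarray(axis, float)
    axis_v = axis_v / np.linalg.norm(axis_v)
    residues = []
    serial = 0
    for k in range(n_chains):
        shift = k * spacing * axis_v
        for res in unit.residues:
            new = Residue(_CHAIN_IDS[k], res.res_seq, res.res_name, res.insertion_code)
            for atom in res.atoms:
                serial += 1
                new.atoms.append(Atom(serial, atom.name, atom.element,
                                      atom.coord + shift, atom.alt_loc,
                                      atom.occupancy, atom.is_hetatm))
            residues.append(new)
    return Structure(residues, source=f"multimer_stack n={n_chains} spacing={spacing}")
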