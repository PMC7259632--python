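"""Distance, turn-span, superposition, RMSD/RMSF and SASA computations.

Turn sharpness is measured as the Cα–Cα distance between the first and
last residues of the turn window and binned into sharp/wide/extended by
configurable thresholds (defaults 8.5 Å and 13.5 Å, placed between the
observed clusters of sharp and non-sharp exemplars).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, RadiusError, SelectionError, TopologyError
from .structure import Residue, Structure, Trajectory, select

__all__ = [
    "TurnSpan",
    "RmsdSeries",
    "RmsfProfile",
    "SasaResult",
    "DEFAULT_SHARP_MAX",
    "DEFAULT_WIDE_MAX",
    "BONDI_RADII",
    "ca_span",
    "classify_turn",
    "turn_span",
    "kabsch_superpose",
    "lrmsd_series",
    "rmsf_profile",
    "shrake_rupley_sasa",
    "sidechain_sasa",
    "is_solvent_exposed",
]

DEFAULT_SHARP_MAX = 8.5
DEFAULT_WIDE_MAX = 13.5

#: Bondi van der Waals radii (Å) by element symbol.
BONDI_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "FE": 1.50, "MG": 1.73, "NA": 2.27, "CA": 2.31, "K": 2.75,
}

#: backbone atom names; everything else in a residue counts as side chain
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


@dataclass(frozen=True)
class TurnSpan:
    chain_id: str
    start_res: int
    end_res: int
    span: float
    turn_class: str


@dataclass
class RmsdSeries:
    values: list[float]
    selection: str


@dataclass
class RmsfProfile:
    residues: list[tuple[str, int, str]]
    values: list[float]
    atom_name: str = "CA"


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible surface areas (Å²)."""

    atom_areas: dict[tuple[str, int, str, str], float]
    residue_areas: dict[tuple[str, int, str], float] = field(default_factory=dict)
    probe_radius: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if not self.residue_areas:
            for (c, s, i, _name), area in self.atom_areas.items():
                key = (c, s, i)
                self.residue_areas[key] = self.residue_areas.get(key, 0.0) + area

    @property
    def total(self) -> float:
        return float(sum(self.atom_areas.values()))


def ca_span(structure: Structure, chain: str, res_i: int, res_j: int) -> float:
    """Euclidean Cα(res_i)–Cα(res_j) distance within one chain, in Å."""
    coords = []
    for res_seq in (res_i, res_j):
        residue = structure.get_residue(chain, res_seq)
        if residue is None:
            raise SelectionError(f"residue {res_seq} absent from chain {chain!r}")
        ca = residue.atom("CA")
        if ca is None:
            raise SelectionError(f"residue {res_seq} of chain {chain!r} has no CA atom")
        coords.append(ca.coord)
    return float(np.linalg.norm(coords[0] - coords[1]))


def classify_turn(span: float,
                  sharp_max: float = DEFAULT_SHARP_MAX,
                  wide_max: float = DEFAULT_WIDE_MAX) -> str:
    """Bin a span into 'sharp' (≤ sharp_max), 'wide' (≤ wide_max) or 'extended'."""
    if span < 0:
        raise ValueError(f"span must be non-negative, got {span}")
    if not (0 < sharp_max < wide_max):
        raise ValueError("thresholds must satisfy 0 < sharp_max < wide_max")
    if span <= sharp_max:
        return "sharp"
    if span <= wide_max:
        return "wide"
    return "extended"


def turn_span(structure: Structure, chain: str, res_i: int, res_j: int,
              sharp_max: float = DEFAULT_SHARP_MAX,
              wide_max: float = DEFAULT_WIDE_MAX) -> TurnSpan:
    span = ca_span(structure, chain, res_i, res_j)
    return TurnSpan(chain, res_i, res_j, span, classify_turn(span, sharp_max, wide_max))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` minimizing the RMSD over all
    rigid-body transforms; apply as ``mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need at least 3 atoms, got {n}")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    P = mobile - mob_center
    Q = reference - ref_center
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise DegenerateInputError("mobile coordinates are collinear")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    translation = ref_center - R @ mob_center
    moved = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, translation, rmsd


def _frame_coords(frame: Structure, chain: str | None,
                  res_range: tuple[int, int] | None,
                  atom_names: set[str] | None) -> np.ndarray:
    pairs = select(frame, chain, res_range, atom_names, include_hydrogens=False)
    return np.array([a.coord for _, a in pairs], dtype=float).reshape(-1, 3)


def lrmsd_series(traj: Trajectory, chain: str | None = None,
                 res_range: tuple[int, int] | None = None,
                 atom_names: set[str] | None = frozenset({"CA"})) -> RmsdSeries:
    """Per-frame RMSD onto frame 0 after optimal superposition of the selection."""
    atom_names = set(atom_names) if atom_names is not None else None
    reference = _frame_coords(traj[0], chain, res_range, atom_names)
    if reference.shape[0] == 0:
        raise TopologyError("selection is empty in the reference frame")
    values = [0.0]
    for k, frame in enumerate(traj.frames[1:], start=1):
        coords = _frame_coords(frame, chain, res_range, atom_names)
        if coords.shape != reference.shape:
            raise TopologyError(f"selection absent or resized in frame {k}")
        _, _, rmsd = kabsch_superpose(coords, reference)
        values.append(rmsd)
    desc = f"chain={chain or 'any'} res={res_range or 'any'} atoms={sorted(atom_names) if atom_names else 'any'}"
    return RmsdSeries(values=values, selection=desc)


def rmsf_profile(traj: Trajectory, chain: str | None = None,
                 atom_name: str = "CA",
                 fit_atom_names: set[str] | None = None) -> RmsfProfile:
    """Per-residue RMSF of ``atom_name`` about its mean position.

    Every frame is first superposed onto frame 0 over the fit selection
    (default: the full Cα set).
    """
    if len(traj) < 2:
        raise DegenerateInputError("RMSF requires at least 2 frames")
    fit_names = set(fit_atom_names) if fit_atom_names else {"CA"}
    fit_ref = _frame_coords(traj[0], None, None, fit_names)
    if fit_ref.shape[0] < 3:
        raise DegenerateInputError("fit selection has fewer than 3 atoms")

    sel = select(traj[0], chain, None, {atom_name}, include_hydrogens=False)
    keys = [(r.chain_id, r.res_seq, r.insertion_code) for r, _ in sel]
    stacked = np.empty((len(traj), len(keys), 3))
    for f, frame in enumerate(traj):
        fit_coords = _frame_coords(frame, None, None, fit_names)
        R, t, _ = kabsch_superpose(fit_coords, fit_ref)
        coords = _frame_coords(frame, chain, None, {atom_name})
        stacked[f] = coords @ R.T + t
    mean = stacked.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((stacked - mean) ** 2, axis=2), axis=0))
    return RmsfProfile(residues=keys, values=[float(v) for v in rmsf], atom_name=atom_name)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960,
                       radii: dict[str, float] | None = None,
                       fallback_radius: float | None = None) -> SasaResult:
    """Probe-sphere-sampled solvent-accessible surface area.

    Hydrogens are excluded both as occluders and as scored atoms so that
    files with and without explicit hydrogens are treated consistently.
    """
    radii = radii or BONDI_RADII
    entries = [(r, a) for r, a in structure.atoms() if not a.is_hydrogen]
    if not entries:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.coord for _, a in entries])
    rads = np.empty(len(entries))
    for i, (_, a) in enumerate(entries):
        r = radii.get(a.element.upper())
        if r is None:
            if fallback_radius is None:
                raise RadiusError(f"no van der Waals radius for element {a.element!r}")
            r = fallback_radius
        rads[i] = r + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_rad = rads.max()
    atom_areas: dict[tuple[str, int, str, str], float] = {}
    for i, (residue, atom) in enumerate(entries):
        pts = coords[i] + rads[i] * sphere
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], rads[i] + max_rad)
                        if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > rads[j] ** 2
        frac = accessible.mean()
        area = 4.0 * np.pi * rads[i] ** 2 * frac
        atom_areas[(residue.chain_id, residue.res_seq, residue.insertion_code,
                    atom.name)] = float(area)
    return SasaResult(atom_areas=atom_areas, probe_radius=probe, n_points=n_points)


def sidechain_sasa(sasa: SasaResult, residue: Residue) -> float:
    """Summed side-chain SASA of one residue (backbone atoms excluded)."""
    total = 0.0
    for atom in residue.atoms:
        if atom.name in BACKBONE_ATOMS or atom.is_hydrogen:
            continue
        key = (residue.chain_id, residue.res_seq, residue.insertion_code, atom.name)
        total += sasa.atom_areas.get(key, 0.0)
    return total


def is_solvent_exposed(sasa: SasaResult, residue: Residue,
                       threshold: float = 20.0) -> bool:
    """True iff the residue's summed side-chain SASA reaches ``threshold`` Å²."""
    return sidechain_sasa(sasa, residue) >= threshold
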