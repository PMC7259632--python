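"""PDB reading/writing and the structure/trajectory data model.

A multi-model PDB file is the trajectory format: one frame per MODEL
record, all frames sharing one topology. Author residue numbering is kept
verbatim; insertion codes are part of residue identity; HETATM records are
parsed as ordinary residues.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import PDBFormatError, PDBParseError, TopologyError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "select",
]

# element symbols recognised when inferring from the atom-name columns
_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "CA", "SE", "NI", "CO",
}


@dataclass
class Atom:
    """One ATOM/HETATM record (coordinates in Å)."""

    serial: int
    name: str
    element: str
    coord: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """A residue addressed by (chain_id, res_seq, insertion_code)."""

    chain_id: str
    res_seq: int
    res_name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.res_name = self.res_name.upper()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


class Structure:
    """One model: an ordered collection of residues grouped by chain."""

    def __init__(self, residues: Iterable[Residue], model_id: int = 1,
                 source: str = ""):
        self.residues: list[Residue] = list(residues)
        self.model_id = model_id
        self.source = source
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in self.residues:
            if r.key in self._index:
                raise ValueError(f"duplicate residue identity {r.key}")
            self._index[r.key] = r

    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def get_residue(self, chain_id: str, res_seq: int,
                    insertion_code: str = "") -> Residue | None:
        return self._index.get((chain_id, res_seq, insertion_code))

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def topology_key(self) -> tuple[tuple[str, int, str, str, str], ...]:
        return tuple(
            (r.chain_id, r.res_seq, r.insertion_code, r.res_name, a.name)
            for r, a in self.atoms()
        )

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, a in self.atoms()], dtype=float)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def copy(self) -> "Structure":
        residues = [
            Residue(r.chain_id, r.res_seq, r.res_name, r.insertion_code,
                    [Atom(a.serial, a.name, a.element, a.coord.copy(),
                          a.alt_loc, a.occupancy, a.is_hetatm)
                     for a in r.atoms])
            for r in self.residues
        ]
        return Structure(residues, self.model_id, self.source)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-body-transformed copy (x -> R x + t)."""
        new = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for r in new.residues:
            for a in r.atoms:
                a.coord = R @ a.coord + t
        return new


class Trajectory:
    """An ordered sequence of Structures sharing one topology."""

    def __init__(self, frames: Sequence[Structure]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory requires at least one frame")
        key = frames[0].topology_key()
        for i, f in enumerate(frames[1:], start=2):
            if f.topology_key() != key:
                raise TopologyError(
                    f"frame {i} topology differs from frame 1 "
                    f"({f.n_atoms()} vs {len(key)} atoms or mismatched identities)"
                )
        self.frames: list[Structure] = frames
        self.topology_key = key

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Structure:
        return self.frames[i]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)


def _infer_element(name_field: str, element_field: str) -> str:
    element = element_field.strip().upper()
    if element and element not in ("D",):
        return element.capitalize() if len(element) == 2 else element
    # heuristics from the 4-char atom-name field: col 13 blank means the
    # symbol starts at col 14; digits in col 13 mark hydrogens like 1HB2
    raw = name_field
    stripped = raw.strip()
    if not stripped:
        return ""
    if raw[:1].strip() and raw[0].isdigit():
        return "H"
    two = stripped[:2].upper()
    if len(raw) >= 1 and raw[0] != " " and two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, line_number: int) -> tuple[tuple[str, int, str, str], Atom]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0  # some generators overflow serials; identity comes from name
    name = line[12:16].strip()
    alt_loc = line[16:17].strip()
    res_name = line[17:20].strip()
    chain_id = line[21:22].strip()
    try:
        res_seq = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"malformed residue number {line[22:26]!r}", line_number) from exc
    icode = line[26:27].strip()
    try:
        coord = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBParseError(f"malformed coordinate field {line[30:54]!r}", line_number) from exc
    try:
        occupancy = float(line[54:60])
    except (ValueError, IndexError):
        occupancy = 1.0
    element = _infer_element(line[12:16], line[76:78] if len(line) >= 78 else "")
    if not element:
        raise PDBParseError(f"cannot infer element for atom {name!r}", line_number)
    atom = Atom(serial, name, element, coord, alt_loc, occupancy,
                is_hetatm=line.startswith("HETATM"))
    return (chain_id, res_seq, icode, res_name), atom


def read_pdb(path_or_text: str | os.PathLike) -> Trajectory:
    """Parse a PDB document into a Trajectory (one frame per MODEL record).

    Accepts a filesystem path or the document text itself. A document
    without MODEL records yields exactly one frame. For alt-loc duplicates
    the highest-occupancy copy is kept (ties: first encountered).
    """
    text = None
    candidate = str(path_or_text)
    if "\n" not in candidate and os.path.exists(candidate):
        with open(candidate) as fh:
            text = fh.read()
        source = candidate
    else:
        text = candidate
        source = "<text>"

    frames: list[Structure] = []
    current: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    model_id = 1
    saw_model = False
    saw_atoms_in_model = False

    def flush() -> None:
        nonlocal current, index, saw_atoms_in_model
        if saw_atoms_in_model:
            frames.append(Structure(current, model_id=model_id, source=source))
        current, index = [], {}
        saw_atoms_in_model = False

    for line_number, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            if saw_atoms_in_model:
                flush()
            saw_model = True
            try:
                model_id = int(line[6:].strip() or len(frames) + 1)
            except ValueError:
                model_id = len(frames) + 1
        elif record.startswith("ENDMDL"):
            flush()
            model_id = len(frames) + 1
        elif record in ("ATOM  ", "HETATM"):
            (chain_id, res_seq, icode, res_name), atom = _parse_atom_line(line, line_number)
            key = (chain_id, res_seq, icode)
            residue = index.get(key)
            if residue is None:
                residue = Residue(chain_id, res_seq, res_name, icode)
                index[key] = residue
                current.append(residue)
            existing = residue.atom(atom.name)
            if existing is not None:
                # alt-loc duplicate: keep the highest occupancy, first on ties
                if atom.alt_loc and atom.occupancy > existing.occupancy:
                    residue.atoms[residue.atoms.index(existing)] = atom
                continue
            residue.atoms.append(atom)
            saw_atoms_in_model = True

    if saw_atoms_in_model:
        flush()
    if not frames:
        raise PDBParseError("document contains no ATOM/HETATM records")
    if not saw_model and len(frames) > 1:  # pragma: no cover - defensive
        raise PDBParseError("multiple frames without MODEL records")
    try:
        return Trajectory(frames)
    except TopologyError:
        raise


def _format_atom_name(name: str, element: str) -> str:
    # single-letter elements start in column 14 unless the name is 4 chars
    if len(name) >= 4 or (len(element) == 2 and name.upper().startswith(element.upper())):
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(traj: Trajectory | Structure) -> str:
    """Serialize a Trajectory (or single Structure) to PDB text.

    Coordinates are written at 3-decimal precision; identifiers round-trip
    exactly through :func:`read_pdb`.
    """
    if isinstance(traj, Structure):
        traj = Trajectory([traj])
    multi = len(traj) > 1
    lines: list[str] = []
    for frame_no, frame in enumerate(traj, start=1):
        if multi:
            lines.append(f"MODEL     {frame_no:>4d}")
        serial = 0
        last_chain = None
        for residue in frame.residues:
            if last_chain is not None and residue.chain_id != last_chain:
                lines.append("TER")
            last_chain = residue.chain_id
            for atom in residue.atoms:
                serial += 1
                x, y, z = atom.coord
                for v in (x, y, z):
                    if not (-999.999 <= v <= 9999.999):
                        raise PDBFormatError(
                            f"coordinate {v} exceeds the fixed-width PDB field")
                record = "HETATM" if atom.is_hetatm else "ATOM  "
                lines.append(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.alt_loc or ' ':1s}{residue.res_name:>3s} "
                    f"{residue.chain_id:1s}{residue.res_seq:>4d}{residue.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element.upper():>2s}"
                )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def select(structure: Structure,
           chain: str | None = None,
           res_range: tuple[int, int] | None = None,
           atom_names: Iterable[str] | None = None,
           include_hydrogens: bool = True) -> list[tuple[Residue, Atom]]:
    """Return (residue, atom) pairs matching all given criteria, in file order.

    ``None`` means "any". An empty selection is legal, not an error.
    """
    names = set(atom_names) if atom_names is not None else None
    out: list[tuple[Residue, Atom]] = []
    for residue in structure.residues:
        if chain is not None and residue.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= residue.res_seq <= res_range[1]):
            continue
        for atom in residue.atoms:
            if names is not None and atom.name not in names:
                continue
            if not include_hydrogens and atom.is_hydrogen:
                continue
            out.append((residue, atom))
    return out
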