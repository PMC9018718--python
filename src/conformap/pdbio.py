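"""Protein structure and ensemble I/O over the fixed-column PDB format.

A :class:`Structure` is one conformation: an ordered list of heavy atoms
with author residue numbering kept verbatim (residues are addressed the way
the literature addresses them, e.g. E17 or T308 of AKT1; no renumbering).
An :class:`Ensemble` is an ordered set of frames sharing one topology — a
multi-model PDB file stands in for a molecular-dynamics trajectory.

The reader enforces contracts that lenient general-purpose parsers do not:
malformed coordinate fields raise with the offending line number, alternate
locations are resolved to the highest-occupancy conformer (ties keep the
first), and multi-model files must be read through :func:`read_ensemble`,
which verifies that every model has the same atoms in the same order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "PDBFormatError",
    "read_pdb",
    "write_pdb",
    "read_ensemble",
    "write_ensemble",
    "THREE_TO_ONE",
    "STANDARD_RESIDUES",
]

#: 3-letter -> 1-letter codes for the 20 standard amino acids.  Anything
#: else is flagged non-standard and excluded from sequence-derived work.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBFormatError(ValueError):
    """Raised for malformed or contract-violating PDB content."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom.

    ``residue_index`` uses author numbering (1-based); ``icode`` is the
    insertion code, empty for the common case.  ``xyz`` is in Angstrom.
    """

    serial: int
    name: str
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    xyz: tuple[float, float, float]
    icode: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    hetero: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"atom {self.name}: non-finite coordinate {self.xyz}")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.icode)


class Structure:
    """An ordered collection of atoms for a single conformation.

    Atoms are stably sorted by (chain, residue_index, icode); the file's
    atom order within each residue is preserved.  Coordinate access is
    through ``coords`` (an (n, 3) float array, a copy); derived structures
    are built with :meth:`with_coords` rather than by mutation.
    """

    def __init__(self, atoms: Sequence[Atom], label: str = ""):
        if not atoms:
            raise PDBFormatError("empty structure: at least one atom is required")
        atoms = sorted(atoms, key=lambda a: (a.chain_id, a.residue_index, a.icode))
        seen: set[tuple] = set()
        for a in atoms:
            key = (a.chain_id, a.residue_index, a.icode, a.name)
            if key in seen:
                raise PDBFormatError(f"duplicate atom {a.name} in residue "
                                     f"{a.chain_id}/{a.residue_index}{a.icode}")
            seen.add(key)
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.label = label
        self._coords = np.array([a.xyz for a in atoms], dtype=float)
        # residue bookkeeping: ordinal slices in atom order
        keys: list[tuple[str, int, str]] = []
        starts: list[int] = []
        prev = None
        for i, a in enumerate(self.atoms):
            if a.residue_key != prev:
                keys.append(a.residue_key)
                starts.append(i)
                prev = a.residue_key
        starts.append(len(self.atoms))
        self._residue_keys = keys
        self._residue_slices = [slice(starts[i], starts[i + 1]) for i in range(len(keys))]
        self._key_to_ordinal = {k: i for i, k in enumerate(keys)}

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __repr__(self) -> str:
        return (f"<Structure {self.label!r}: {len(self.atoms)} atoms, "
                f"{self.n_residues} residues>")

    # -- coordinates ---------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self._coords.copy()

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Return a new Structure with the same topology and new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, xyz=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, label=self.label if label is None else label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply the rigid motion x -> R x + t to every atom."""
        return self.with_coords(self._coords @ np.asarray(rotation).T + translation)

    # -- residues ------------------------------------------------------
    @property
    def n_residues(self) -> int:
        return len(self._residue_keys)

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        return list(self._residue_keys)

    @property
    def residue_indices(self) -> list[int]:
        """Author residue numbers, in structure order."""
        return [k[1] for k in self._residue_keys]

    def residue_name(self, residue_index: int, chain_id: str | None = None) -> str:
        sl = self.residue_atoms(residue_index, chain_id)
        return self.atoms[sl.start].residue_name

    def residue_atoms(self, residue_index: int, chain_id: str | None = None,
                      icode: str = "") -> slice:
        """Atom slice of one residue, addressed by author number."""
        matches = [k for k in self._residue_keys
                   if k[1] == residue_index and k[2] == icode
                   and (chain_id is None or k[0] == chain_id)]
        if not matches:
            raise KeyError(f"residue {residue_index}{icode} not present"
                           + (f" in chain {chain_id}" if chain_id else ""))
        if len(matches) > 1:
            raise KeyError(f"residue {residue_index} is ambiguous across chains "
                           f"{[m[0] for m in matches]}; pass chain_id")
        return self._residue_slices[self._key_to_ordinal[matches[0]]]

    def has_residue(self, residue_index: int, chain_id: str | None = None) -> bool:
        try:
            self.residue_atoms(residue_index, chain_id)
            return True
        except KeyError:
            return False

    def atom_index(self, residue_index: int, atom_name: str,
                   chain_id: str | None = None) -> int:
        sl = self.residue_atoms(residue_index, chain_id)
        for i in range(sl.start, sl.stop):
            if self.atoms[i].name == atom_name:
                return i
        raise KeyError(f"residue {residue_index} has no atom {atom_name!r}")

    def ca_coords(self, residue_indices: Iterable[int] | None = None) -> np.ndarray:
        """C-alpha coordinates for the given residues (default: all that have one).

        Raises KeyError listing residues missing a CA when an explicit
        selection is given.
        """
        if residue_indices is None:
            idx = [i for i in range(len(self.atoms)) if self.atoms[i].name == "CA"]
            return self._coords[idx]
        missing, rows = [], []
        for r in residue_indices:
            try:
                rows.append(self.atom_index(r, "CA"))
            except KeyError:
                missing.append(r)
        if missing:
            raise KeyError(f"residues missing CA atom: {missing}")
        return self._coords[rows]

    def sequence(self, chain_id: str | None = None) -> str:
        """Derived 1-letter sequence; non-standard residues become 'X'."""
        out = []
        for k, sl in zip(self._residue_keys, self._residue_slices):
            if chain_id is not None and k[0] != chain_id:
                continue
            if self.atoms[sl.start].hetero:
                continue
            out.append(THREE_TO_ONE.get(self.atoms[sl.start].residue_name, "X"))
        return "".join(out)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in self._residue_keys:
            seen.setdefault(k[0])
        return list(seen)


@dataclass
class Ensemble:
    """Ordered frames over one topology; a trajectory surrogate.

    ``frames`` has shape (n_frames, n_atoms, 3).  ``topology`` carries the
    atom metadata and frame 0's coordinates.
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float | None = None  # optional, in whatever time unit

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incongruent with topology "
                f"({len(self.topology)} atoms)")
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# fixed-column parsing

def _parse_float(line_no: int, line: str, lo: int, hi: int, what: str) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise PDBFormatError(
            f"line {line_no}: non-numeric {what} field {text!r}") from None


def _parse_atom_line(line_no: int, line: str) -> tuple[Atom, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc)."""
    line = line.rstrip("\n").ljust(80)
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain = line[21].strip() or " "
    try:
        resseq = int(line[22:26])
    except ValueError:
        raise PDBFormatError(
            f"line {line_no}: non-integer residue number {line[22:26]!r}") from None
    icode = line[26].strip()
    x = _parse_float(line_no, line, 30, 38, "x coordinate")
    y = _parse_float(line_no, line, 38, 46, "y coordinate")
    z = _parse_float(line_no, line, 46, 54, "z coordinate")
    occ_text = line[54:60].strip()
    occ = float(occ_text) if occ_text else 1.0
    b_text = line[60:66].strip()
    bfac = float(b_text) if b_text else 0.0
    element = line[76:78].strip()
    if not element:
        # fall back to PDB atom-name convention: first alphabetic character
        letters = [c for c in name if c.isalpha()]
        if not letters:
            raise PDBFormatError(f"line {line_no}: cannot infer element from "
                                 f"atom name {name!r}")
        element = letters[0].upper()
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    atom = Atom(serial=serial, name=name, element=element, chain_id=chain,
                residue_index=resseq, residue_name=resname, xyz=(x, y, z),
                icode=icode, occupancy=occ, bfactor=bfac,
                hetero=line.startswith("HETATM"))
    return atom, altloc


def _resolve_altlocs(records: list[tuple[Atom, str]]) -> list[Atom]:
    """Keep the highest-occupancy alternate location per atom; ties keep the
    first occurrence (file order)."""
    best: dict[tuple, tuple[int, Atom]] = {}
    order: list[tuple] = []
    for pos, (atom, altloc) in enumerate(records):
        key = (atom.chain_id, atom.residue_index, atom.icode, atom.name)
        if key not in best:
            best[key] = (pos, atom)
            order.append(key)
        else:
            _, incumbent = best[key]
            if atom.occupancy > incumbent.occupancy:
                best[key] = (best[key][0], atom)
    return [best[k][1] for k in order]


def _read_models(lines: Iterable[str], include_hetero: bool
                 ) -> list[list[tuple[Atom, str]]]:
    models: list[list[tuple[Atom, str]]] = []
    current: list[tuple[Atom, str]] = []
    in_model = False
    saw_model_record = False
    for line_no, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            saw_model_record = True
            if current:
                models.append(current)
                current = []
            in_model = True
        elif rec.startswith("ENDMDL"):
            models.append(current)
            current = []
            in_model = False
        elif rec.startswith("ATOM") or (include_hetero and rec.startswith("HETATM")):
            current.append(_parse_atom_line(line_no, line))
    if current or not models:
        models.append(current)
    models = [m for m in models if m] or [[]]
    if not saw_model_record and len(models) == 1 and not models[0]:
        raise PDBFormatError("empty structure: no ATOM records found")
    if not any(models):
        raise PDBFormatError("empty structure: no ATOM records found")
    return models


def _source_lines(source: str | Path) -> list[str]:
    if isinstance(source, Path):
        return source.read_text().splitlines()
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        return Path(source).read_text().splitlines()
    return str(source).splitlines()


def read_pdb(source: str | Path, include_hetero: bool = False,
             label: str = "") -> Structure:
    """Read a single-conformation PDB file (or text) into a Structure.

    HETATM records are skipped unless ``include_hetero`` is set.  Files with
    more than one MODEL block are refused — use :func:`read_ensemble`.
    """
    models = _read_models(_source_lines(source), include_hetero)
    if len(models) > 1:
        raise PDBFormatError(
            f"source contains {len(models)} models; use read_ensemble for "
            "multi-model files")
    return Structure(_resolve_altlocs(models[0]), label=label)


def read_ensemble(source: str | Path, include_hetero: bool = False,
                  label: str = "") -> Ensemble:
    """Read a multi-model PDB into an Ensemble (topology = first model).

    Every model must contain the same atoms in the same order; a mismatch
    raises a congruence error naming the offending model index (0-based).
    """
    models = [_resolve_altlocs(m) for m in _read_models(_source_lines(source),
                                                        include_hetero)]
    topology = Structure(models[0], label=label)
    ref_keys = [(a.chain_id, a.residue_index, a.icode, a.name) for a in topology.atoms]
    frames = np.empty((len(models), len(topology), 3), dtype=float)
    frames[0] = topology.coords
    for mi, model in enumerate(models[1:], start=1):
        ordered = sorted(model, key=lambda a: (a.chain_id, a.residue_index, a.icode))
        keys = [(a.chain_id, a.residue_index, a.icode, a.name) for a in ordered]
        if keys != ref_keys:
            raise PDBFormatError(
                f"model {mi} is not congruent with model 0 "
                f"({len(keys)} atoms vs {len(ref_keys)})")
        frames[mi] = [a.xyz for a in ordered]
    return Ensemble(topology, frames)


# ---------------------------------------------------------------------------
# writing

_ATOM_FMT = ("{rec:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {element:>2s}")


def _format_atom_name(name: str, element: str) -> str:
    # one-letter elements start in column 14 by PDB convention
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: Atom, serial: int) -> str:
    for c in atom.xyz:
        if abs(c) >= 1e5:
            raise PDBFormatError(
                f"coordinate {c} exceeds the PDB field width (>= 1e5 A)")
    return _ATOM_FMT.format(
        rec="HETATM" if atom.hetero else "ATOM",
        serial=serial, name=_format_atom_name(atom.name, atom.element),
        altloc=" ", resname=atom.residue_name, chain=atom.chain_id,
        resseq=atom.residue_index, icode=atom.icode or " ",
        x=atom.xyz[0], y=atom.xyz[1], z=atom.xyz[2],
        occ=atom.occupancy, b=atom.bfactor, element=atom.element.upper())


def _structure_lines(structure: Structure, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    prev_chain = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append(f"TER   {serial:>5d}")
            serial += 1
        lines.append(_atom_line(atom, serial))
        serial += 1
        prev_chain = atom.chain_id
    lines.append(f"TER   {serial:>5d}")
    return lines


def write_pdb(structure: Structure, path: str | Path | None = None) -> str:
    """Serialize to fixed-column PDB text (serials renumbered from 1).

    Returns the text; also writes it to ``path`` when given.
    """
    text = "\n".join(_structure_lines(structure) + ["END"]) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_ensemble(ensemble: Ensemble, path: str | Path | None = None) -> str:
    """Serialize an Ensemble as a multi-model PDB."""
    lines: list[str] = []
    for i in range(ensemble.n_frames):
        lines.append(f"MODEL     {i + 1:>4d}")
        lines.extend(_structure_lines(ensemble.frame(i)))
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
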