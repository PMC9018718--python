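"""Ground-truthed synthetic two-domain proteins and ensembles.

The generator emulates the inputs of the autoinhibition analysis at desk
scale: a "closed" toy protein with two compact domains (a PH-like domain A
and a kinase-like domain B) packed face to face, a designed set of
hydrophobic interface contacts, one designated buried marker residue (the
T308 analogue: occluded by the partner domain in the closed form), one
designated cross-interface hydrogen bond (the analogue of an
interface-stabilising bond lost on opening), an "open" conformer made by a
rigid displacement of domain B, tandem-duplication variants, and
MD-trajectory-like ensembles (rigid jitter plus isotropic Gaussian
coordinate noise around a mean structure).

Everything is schematic — side chains are short carbon fans, there is no
force field — because the downstream operators are purely geometric.  What
matters is that every planted feature is known by construction
(:class:`GroundTruth`), so each pipeline stage can be checked against it.

Geometry of the closed form (Angstrom): residue centres sit on a 6 A grid,
5 x 5 per layer, domains face each other across a plane gap chosen so the
designed leucine-like contact fans meet at ``inter_domain_gap`` (default
3.5 A, giving nine carbon-carbon pairs within 3.8 A per designed pair,
while every non-designed cross-domain atom pair stays beyond 6 A).  The
marker residue sits at the centre of domain B's interface face inside a
carbon cage at 3.9 A: its own domain closes the rear and lateral
directions, a domain-A cap residue closes the face direction — so opening
the interface uncages it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .contacts import DomainSpec
from .mapping import ResidueMap, map_from_duplication
from .pdbio import Atom, Ensemble, Structure
from .sasa import _fibonacci_sphere

__all__ = [
    "ToySpec",
    "GroundTruth",
    "make_two_domain_toy",
    "make_open_conformer",
    "apply_duplication",
    "simulate_frames",
]

# layout constants (Angstrom)
_SPACING = 6.0          # residue-centre grid spacing
_GRID = 5               # lateral grid is _GRID x _GRID per layer
_PROTRUSION = 3.25      # contact side-chain reach beyond the residue centre
_CAGE_RADIUS = 3.9      # cage-carbon distance from the marker centre

# face-slot roles, by lateral (iy, iz) grid position
_MARKER_SLOT = (2, 2)
_CAGE_SLOTS = ((1, 2),)                        # domain-B lateral cage neighbour
_CAP_SLOTS = ((2, 2), (2, 1), (2, 3), (2, 0))  # domain-A cap residues
_HBOND_SLOT = (0, 1)
_CONTACT_SLOTS = tuple((iy, iz) for iy in (0, 2, 4) for iz in (0, 2, 4)
                       if (iy, iz) != _MARKER_SLOT)


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the closed two-domain toy.

    ``inter_domain_gap`` is the carbon-carbon contact distance of the
    designed interface pairs (default 3.5 A, comfortably inside the 4 A
    hydrophobic-contact criterion).  ``buried_marker_residue`` picks which
    domain-B residue is caged (default: the interface-face centre).
    """

    n_res_domain_a: int = 50
    n_res_domain_b: int = 50
    linker_length: int = 8
    inter_domain_gap: float = 3.5
    hydrophobic_fraction: float = 0.4
    designated_contact_pairs: int = 6
    buried_marker_residue: int | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_res_domain_a", "n_res_domain_b", "linker_length",
                     "designated_contact_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.hydrophobic_fraction <= 1.0):
            raise ValueError("hydrophobic_fraction must be in [0, 1]")
        if self.inter_domain_gap <= 0:
            raise ValueError("inter_domain_gap must be > 0")


@dataclass
class GroundTruth:
    """What was planted in a generated toy, for recovery checks."""

    domain_a: DomainSpec
    domain_b: DomainSpec
    linker_range: tuple[int, int]
    true_interface_pairs: list[tuple[int, int]]
    marker_residue: int
    designated_hbond: tuple[tuple[int, str], tuple[int, str]]  # (donor, acceptor)
    true_residue_map: ResidueMap
    true_displacements: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "domain_a": {"name": self.domain_a.name,
                         "ranges": [list(r) for r in self.domain_a.ranges]},
            "domain_b": {"name": self.domain_b.name,
                         "ranges": [list(r) for r in self.domain_b.ranges]},
            "linker_range": list(self.linker_range),
            "true_interface_pairs": [list(p) for p in self.true_interface_pairs],
            "marker_residue": self.marker_residue,
            "designated_hbond": [list(self.designated_hbond[0]),
                                 list(self.designated_hbond[1])],
            "residue_map_pairs": [list(p) for p in self.true_residue_map.pairs],
            "unmapped_mut": sorted(self.true_residue_map.unmapped_mut),
            "true_displacements": {str(k): v for k, v in self.true_displacements.items()},
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _slot_order(n: int) -> list[tuple[int, int, int]]:
    """(layer, iy, iz) slots, face layer (0) first, row-major laterally."""
    slots: list[tuple[int, int, int]] = []
    layer = 0
    while len(slots) < n:
        for iy in range(_GRID):
            for iz in range(_GRID):
                slots.append((layer, iy, iz))
                if len(slots) == n:
                    return slots
        layer += 1
    return slots


def _backbone(center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Schematic backbone in the residue's local yz-plane."""
    return [
        ("N", "N", center + (0.0, 1.2, 0.8)),
        ("CA", "C", center + (0.0, 0.0, 0.0)),
        ("C", "C", center + (0.0, -1.2, 0.8)),
        ("O", "O", center + (0.0, -1.9, 1.8)),
    ]


def _filler_sidechain(center: np.ndarray, away: float, hydrophobic: bool
                      ) -> tuple[str, list[tuple[str, str, np.ndarray]]]:
    """Side chain pointing along the x-direction ``away`` (+-1), so face
    residues keep their carbons off the interface."""
    d = np.array([away, 0.0, 0.0])
    if hydrophobic:  # valine-like: three side carbons
        return "VAL", [
            ("CB", "C", center + 1.3 * d + (0.0, 0.4, -0.9)),
            ("CG1", "C", center + 2.4 * d + (0.0, 1.1, -1.3)),
            ("CG2", "C", center + 2.4 * d + (0.0, -0.5, -1.7)),
        ]
    return "SER", [("CB", "C", center + 1.3 * d + (0.0, 0.4, -0.9))]


def _contact_sidechain(center: np.ndarray, toward: float
                       ) -> list[tuple[str, str, np.ndarray]]:
    """Leucine-like fan whose terminal carbon triangle protrudes
    ``_PROTRUSION`` beyond the residue centre toward the interface."""
    d = toward
    return [
        ("CB", "C", center + (1.6 * d, 0.0, 0.0)),
        ("CG", "C", center + (_PROTRUSION * d, 0.75, 0.0)),
        ("CD1", "C", center + (_PROTRUSION * d, -0.40, 0.65)),
        ("CD2", "C", center + (_PROTRUSION * d, -0.40, -0.65)),
    ]


def _cage_layout() -> dict[str, np.ndarray]:
    """24 near-uniform cage directions split among the caging residues.

    The interface-facing hemisphere (x < 0, toward domain A) is covered by
    three domain-A cap residues (4 carbons each), so that opening the
    interface uncages exactly that hemisphere; the rear hemisphere is
    covered by domain-B neighbours (rear residue plus two lateral belt
    residues) and travels with the marker.
    """
    dirs = _fibonacci_sphere(24)
    order = np.argsort(dirs[:, 0])
    front = dirs[order[:16]]   # toward/around the interface: domain-A side
    rear = dirs[order[16:]]    # strongly +x: domain-B side
    az = np.argsort(np.arctan2(front[:, 2], front[:, 1]))
    front = front[az]
    rear_order = np.argsort(-rear[:, 0])
    return {"cap0": front[0:4], "cap1": front[4:8],
            "cap2": front[8:12], "cap3": front[12:16],
            "back": rear[rear_order[:4]], "belt0": rear[rear_order[4:]]}


def make_two_domain_toy(spec: ToySpec = ToySpec()) -> tuple[Structure, GroundTruth]:
    """Build the closed (autoinhibited-like) toy and its ground truth.

    Residue numbering: domain A is 1..n_a, the linker follows, then domain
    B.  Deterministic given the seed (filler residue identities are the
    only randomised feature).
    """
    n_a, n_b, n_l = spec.n_res_domain_a, spec.n_res_domain_b, spec.linker_length
    if spec.designated_contact_pairs > len(_CONTACT_SLOTS):
        raise ValueError(
            f"cannot place {spec.designated_contact_pairs} contact pairs: only "
            f"{len(_CONTACT_SLOTS)} interface slots with safe lateral spacing")
    rng = np.random.default_rng(spec.seed)
    half = (spec.inter_domain_gap + 2.0 * _PROTRUSION) / 2.0

    slots_a = _slot_order(n_a)
    slots_b = _slot_order(n_b)
    contact_slots = _CONTACT_SLOTS[:spec.designated_contact_pairs]

    def slot_ordinal(slots, lateral):
        for i, (layer, iy, iz) in enumerate(slots):
            if layer == 0 and (iy, iz) == lateral:
                return i
        return None

    role_laterals = set(contact_slots) | {_HBOND_SLOT, _MARKER_SLOT}
    for dom, slots, n in (("A", slots_a, n_a), ("B", slots_b, n_b)):
        needed = role_laterals | (set(_CAGE_SLOTS) if dom == "B" else set(_CAP_SLOTS))
        for lateral in needed:
            if slot_ordinal(slots, lateral) is None:
                raise ValueError(f"domain {dom} too small ({n} residues) to "
                                 "place all designated interface roles")
    rear_cage_ordinal = _GRID * _GRID + _MARKER_SLOT[0] * _GRID + _MARKER_SLOT[1]
    if n_b <= rear_cage_ordinal:
        raise ValueError(f"domain B too small ({n_b} residues): the marker "
                         "cage needs its second-layer rear neighbour "
                         f"(>= {rear_cage_ordinal + 1} residues)")

    b_start = n_a + n_l + 1
    marker_ordinal = slot_ordinal(slots_b, _MARKER_SLOT)
    if spec.buried_marker_residue is not None:
        marker_res = spec.buried_marker_residue
        if not (b_start <= marker_res < b_start + n_b):
            raise ValueError("buried_marker_residue must lie in domain B")
        free = {s for s in ((iy, iz) for iy in range(_GRID) for iz in range(_GRID))
                if s not in role_laterals and s not in _CAGE_SLOTS}
        i = marker_res - b_start
        layer_i, iy_i, iz_i = slots_b[i]
        if not (layer_i == 0 and (iy_i, iz_i) in free or i == marker_ordinal):
            raise ValueError("buried_marker_residue must occupy a free "
                             "domain-B face slot")
        slots_b = list(slots_b)
        slots_b[i], slots_b[marker_ordinal] = slots_b[marker_ordinal], slots_b[i]
    else:
        marker_res = b_start + marker_ordinal

    marker_center = np.array([half, _SPACING * _MARKER_SLOT[0],
                              _SPACING * _MARKER_SLOT[1]])
    cage = _cage_layout()
    belt_by_slot = dict(zip(_CAGE_SLOTS, ("belt0",)))
    cap_by_slot = dict(zip(_CAP_SLOTS, ("cap0", "cap1", "cap2", "cap3")))

    atoms: list[Atom] = []
    serial = 0

    def add_residue(res_index: int, res_name: str,
                    parts: list[tuple[str, str, np.ndarray]]):
        nonlocal serial
        for name, element, xyz in parts:
            serial += 1
            atoms.append(Atom(serial=serial, name=name, element=element,
                              chain_id="A", residue_index=res_index,
                              residue_name=res_name, xyz=tuple(np.asarray(xyz))))

    def cage_carbons(kind: str) -> list[tuple[str, str, np.ndarray]]:
        names = ("CB", "CG1", "CG2", "CG3")
        return [(names[k], "C", marker_center + _CAGE_RADIUS * cage[kind][k])
                for k in range(4)]

    def build_domain(side: float, slots, start_index: int, is_b: bool):
        """side = -1 for domain A (face at -half), +1 for domain B."""
        for i, (layer, iy, iz) in enumerate(slots):
            res = start_index + i
            center = np.array([side * (half + layer * _SPACING),
                               _SPACING * iy, _SPACING * iz])
            lateral = (iy, iz)
            on_face = layer == 0
            parts = _backbone(center)
            if on_face and lateral in contact_slots:
                name = "LEU"
                parts += _contact_sidechain(center, toward=-side)
            elif on_face and lateral == _HBOND_SLOT:
                if not is_b:  # donor: asparagine-like, amide N in the gap
                    name = "ASN"
                    parts += [("CB", "C", center + (1.2, 0.0, 0.0)),
                              ("CG", "C", center + (2.4, 0.0, 0.0)),
                              ("ND2", "N", center + (3.6, 0.0, 0.0))]
                else:  # acceptor: glutamine-like, carbonyl O in the gap
                    name = "GLN"
                    parts += [("CB", "C", center + (-1.2, 0.0, 0.0)),
                              ("CG", "C", center + (-2.4, 0.0, 0.0)),
                              ("OE1", "O", center + (-3.5, 0.0, 0.0))]
            elif is_b and res == marker_res:
                # the T308 analogue: side chain points at the interface, so
                # the closed-form cage occludes it and opening frees it
                name = "THR"
                parts += [("CB", "C", center + (-0.9, 0.4, -0.5)),
                          ("CG2", "C", center + (-1.9, 0.8, -1.0))]
            elif is_b and on_face and lateral in belt_by_slot:
                name = "ASN"  # lateral cage neighbour
                parts += cage_carbons(belt_by_slot[lateral])
            elif is_b and layer == 1 and lateral == _MARKER_SLOT:
                name = "ASN"  # rear neighbour closes the +x cone
                parts += cage_carbons("back")
            elif not is_b and on_face and lateral in cap_by_slot:
                # domain-A cap residue: backbone floats in the gap, its
                # carbons close part of the marker's front hemisphere
                name = "SER"
                parts = _backbone(np.array([-1.5, center[1], center[2]]))
                parts += cage_carbons(cap_by_slot[lateral])
            else:
                hydro = bool(rng.random() < spec.hydrophobic_fraction)
                away = side if on_face else (1.0 if rng.random() < 0.5 else -1.0)
                name, side_parts = _filler_sidechain(center, away, hydro)
                parts += side_parts
            add_residue(res, name, parts)

    # domain A (residues 1..n_a), face at x = -half
    build_domain(-1.0, slots_a, 1, is_b=False)

    # linker: a V-shaped detour outside the interface zone
    y_off = _SPACING * _GRID + 4.0
    z_mid = _SPACING * (_GRID - 1) / 2.0
    leg = max((n_l + 1) * 4.5 / 2.0, half + 2.0)
    h = float(np.sqrt(max(leg ** 2 - half ** 2, 4.0)))
    p0 = np.array([-half, y_off, z_mid])
    apex = np.array([0.0, y_off + h, z_mid])
    p1 = np.array([half, y_off, z_mid])
    for i in range(n_l):
        t = (i + 1) / (n_l + 1)
        pos = p0 + 2 * t * (apex - p0) if t <= 0.5 else apex + (2 * t - 1) * (p1 - apex)
        add_residue(n_a + 1 + i, "SER",
                    _backbone(pos) + [("CB", "C", pos + (0.0, 1.0, -1.0))])

    # domain B (residues b_start..), face at x = +half
    build_domain(+1.0, slots_b, b_start, is_b=True)

    structure = Structure(atoms, label="toy-closed")
    donor_res = 1 + slot_ordinal(slots_a, _HBOND_SLOT)
    acceptor_res = b_start + slot_ordinal(slots_b, _HBOND_SLOT)
    pairs = sorted(
        (1 + slot_ordinal(slots_a, lateral), b_start + slot_ordinal(slots_b, lateral))
        for lateral in contact_slots)
    truth = GroundTruth(
        domain_a=DomainSpec("A", [(1, n_a)]),
        domain_b=DomainSpec("B", [(b_start, b_start + n_b - 1)]),
        linker_range=(n_a + 1, n_a + n_l),
        true_interface_pairs=pairs,
        marker_residue=marker_res,
        designated_hbond=((donor_res, "ND2"), (acceptor_res, "OE1")),
        true_residue_map=ResidueMap.identity(structure.residue_indices),
        seed=spec.seed,
    )
    return structure, truth


def make_open_conformer(closed: Structure, domain_b: DomainSpec,
                        translation: Sequence[float],
                        rotation: np.ndarray | None = None,
                        linker_range: tuple[int, int] | None = None) -> Structure:
    """Rigidly displace domain B (and the distal half of the linker).

    With ``rotation`` None, every domain-B residue's true displacement is
    exactly |translation|.  Overlaps closer than 1 A between moved and
    fixed atoms raise a warning (the move is deterministic; choose a
    different translation to resolve).
    """
    t = np.asarray(translation, dtype=float)
    if np.linalg.norm(t) == 0:
        raise ValueError("translation magnitude must be > 0")
    move = {r for r in closed.residue_indices if r in domain_b}
    if linker_range is not None:
        lo, hi = linker_range
        mid = (lo + hi) // 2
        move.update(r for r in range(mid + 1, hi + 1) if closed.has_residue(r))
    coords = closed.coords
    mask = np.array([a.residue_index in move for a in closed.atoms])
    if not mask.any():
        raise ValueError("domain_b selects no residues of the structure")
    if rotation is not None:
        R = np.asarray(rotation, dtype=float)
        cen = coords[mask].mean(axis=0)
        coords[mask] = (coords[mask] - cen) @ R.T + cen + t
    else:
        coords[mask] = coords[mask] + t
    if (~mask).any():
        d, _ = cKDTree(coords[~mask]).query(coords[mask], k=1)
        if (d < 1.0).any():
            warnings.warn("open conformer has moved atoms within 1 A of the "
                          "fixed region; consider a different translation",
                          stacklevel=2)
    return closed.with_coords(coords, label="toy-open")


def apply_duplication(structure: Structure, dup_start: int, dup_end: int
                      ) -> tuple[Structure, ResidueMap]:
    """Tandem-duplicate residues ``dup_start..dup_end`` of a contiguous
    single-chain structure.

    The duplicate copy occupies mutant positions dup_end+1 ..
    dup_end+length, offset from the original block by ~2.3 A along the
    local chain direction; residues after the block are renumbered by the
    block length (the first copy keeps wild-type identity).  Returns the
    mutant structure and the wild-type -> mutant ResidueMap, identical to
    :func:`map_from_duplication`.
    """
    indices = structure.residue_indices
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise ValueError("duplication requires contiguous residue numbering "
                         "(range spans a chain break or gap)")
    if not (indices[0] <= dup_start <= dup_end <= indices[-1]):
        raise ValueError(f"duplication range {dup_start}..{dup_end} outside "
                         f"structure ({indices[0]}..{indices[-1]})")
    length = dup_end - dup_start + 1
    # local chain direction at the end of the duplicated block
    ref = dup_start if dup_start == dup_end else dup_end - 1
    ca0 = np.asarray(structure.atoms[structure.atom_index(ref, "CA")].xyz)
    ca1 = np.asarray(structure.atoms[structure.atom_index(dup_end, "CA")].xyz)
    step = ca1 - ca0
    norm = float(np.linalg.norm(step))
    direction = step / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    offset = 2.0 * direction + np.array([0.0, 0.0, 1.2])

    new_atoms: list[Atom] = []
    serial = 0

    def push(atom: Atom, res_index: int, xyz: np.ndarray | None = None):
        nonlocal serial
        serial += 1
        new_atoms.append(Atom(
            serial=serial, name=atom.name, element=atom.element,
            chain_id=atom.chain_id, residue_index=res_index,
            residue_name=atom.residue_name,
            xyz=tuple(xyz) if xyz is not None else atom.xyz,
            icode=atom.icode, hetero=atom.hetero))

    for atom in structure.atoms:
        r = atom.residue_index
        push(atom, r if r <= dup_end else r + length)
    for atom in structure.atoms:
        r = atom.residue_index
        if dup_start <= r <= dup_end:
            push(atom, r + length, xyz=np.asarray(atom.xyz) + offset)

    mutant = Structure(new_atoms,
                       label=f"{structure.label}+dup{dup_start}-{dup_end}")
    rmap = map_from_duplication(len(indices), dup_start, dup_end)
    return mutant, rmap


def simulate_frames(mean: Structure, n_frames: int, noise_sd: float,
                    rigid_jitter_deg: float = 0.0,
                    rigid_jitter_trans: float = 0.0,
                    seed: int = 0) -> Ensemble:
    """MD-like ensemble: per-frame small random rigid motion of the mean
    plus i.i.d. Gaussian per-coordinate noise.  Deterministic given seed.

    The noise model is deliberately simple (no correlated breathing
    modes); it provides exactly what time-averaging assumes it must
    remove: rigid tumbling and uncorrelated thermal scatter.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0 or rigid_jitter_deg < 0 or rigid_jitter_trans < 0:
        raise ValueError("noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    base = mean.coords
    cen = base.mean(axis=0)
    frames = np.empty((n_frames, len(mean), 3))
    for i in range(n_frames):
        coords = base
        if rigid_jitter_deg > 0:
            rotvec = rng.normal(scale=np.radians(rigid_jitter_deg), size=3)
            R = Rotation.from_rotvec(rotvec).as_matrix()
            coords = (coords - cen) @ R.T + cen
        if rigid_jitter_trans > 0:
            coords = coords + rng.normal(scale=rigid_jitter_trans, size=3)
        if noise_sd > 0:
            coords = coords + rng.normal(scale=noise_sd, size=coords.shape)
        frames[i] = coords
    return Ensemble(mean, frames)
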