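"""Inter-domain contacts, hydrogen bonds, and residue-residue distance maps.

This is the observable layer of the analysis: which pleckstrin-homology /
kinase residue pairs hold the autoinhibited (closed) conformation together,
and how those couplings change in a mutant or open conformer.

A hydrophobic interface pair follows a carbon-count criterion: two
hydrophobic residues, one per domain, with at least ``min_carbon_pairs``
carbon-carbon contacts within ``max_carbon_distance`` (defaults 6 and
4.0 A).  Distance-difference maps compare pure internal distances between
mapped residues of two structures and are therefore invariant to any rigid
motion of either input — deformation shows up, tumbling does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import representative_coords
from .mapping import ResidueMap
from .pdbio import Structure

__all__ = [
    "DomainSpec",
    "ContactCriteria",
    "InterfacePair",
    "HBondCriteria",
    "HBond",
    "DistanceMatrix",
    "DistanceDiffMap",
    "find_interface_pairs",
    "find_hbonds",
    "residue_distance_matrix",
    "distance_diff_map",
    "pair_distance_report",
    "diff_block_summary",
]

#: Residues counted as hydrophobic for the interface criterion.  The set is
#: side-chain based (aliphatic + aromatic + P/C) and configurable.
DEFAULT_HYDROPHOBIC = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "CYS"})

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

Metric = Literal["ca", "min_heavy"]


@dataclass(frozen=True)
class DomainSpec:
    """A named set of inclusive residue-index intervals, e.g.
    DomainSpec("PH", [(5, 108)])."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __init__(self, name: str, ranges: Sequence[Sequence[int]]):
        norm = tuple(tuple(int(v) for v in r) for r in ranges)
        for lo, hi in norm:
            if lo > hi:
                raise ValueError(f"domain {name}: empty interval {lo}..{hi}")
        for (a, b), (c, d) in zip(norm, norm[1:]):
            if c <= b:
                raise ValueError(f"domain {name}: intervals must be sorted "
                                 "and non-overlapping")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "ranges", norm)

    def __contains__(self, residue_index: int) -> bool:
        return any(lo <= residue_index <= hi for lo, hi in self.ranges)

    def residues_in(self, structure: Structure) -> list[int]:
        return [r for r in structure.residue_indices if r in self]

    def shifted(self, residue_map: ResidueMap) -> list[int]:
        """Mutant-side residue indices corresponding to this (wild-type)
        domain under a residue map."""
        fwd = residue_map.forward
        return [fwd[r] for lo, hi in self.ranges for r in range(lo, hi + 1)
                if r in fwd]


@dataclass(frozen=True)
class ContactCriteria:
    max_carbon_distance: float = 4.0
    min_carbon_pairs: int = 6
    hydrophobic_residues: frozenset[str] = DEFAULT_HYDROPHOBIC
    sidechain_only: bool = False  # default counts backbone carbons too

    def __post_init__(self):
        if self.max_carbon_distance <= 0:
            raise ValueError("max_carbon_distance must be > 0")
        if self.min_carbon_pairs < 1:
            raise ValueError("min_carbon_pairs must be >= 1")


@dataclass(frozen=True)
class InterfacePair:
    """A hydrophobic residue pair bridging the two domains."""

    residue_a: int
    residue_b: int
    name_a: str
    name_b: str
    n_carbon_pairs: int
    min_distance: float


def _residue_carbons(structure: Structure, residues: Sequence[int],
                     sidechain_only: bool) -> tuple[np.ndarray, np.ndarray]:
    """(coords, residue-index array) of carbon atoms of the given residues."""
    rows, owners = [], []
    wanted = set(residues)
    for i, atom in enumerate(structure.atoms):
        if atom.element != "C" or atom.residue_index not in wanted:
            continue
        if sidechain_only and atom.name in _BACKBONE:
            continue
        rows.append(i)
        owners.append(atom.residue_index)
    coords = structure.coords[rows] if rows else np.empty((0, 3))
    return coords, np.asarray(owners, dtype=int)


def find_interface_pairs(structure: Structure, domain_a: DomainSpec,
                         domain_b: DomainSpec,
                         criteria: ContactCriteria = ContactCriteria()
                         ) -> list[InterfacePair]:
    """Hydrophobic contact pairs between two domains.

    A pair (a in domain_a, b in domain_b) qualifies iff both residue types
    are in ``criteria.hydrophobic_residues`` and at least
    ``criteria.min_carbon_pairs`` carbon-carbon pairs between them lie
    within ``criteria.max_carbon_distance``.  Output is sorted by
    (residue_a, residue_b).
    """
    res_a = [r for r in domain_a.residues_in(structure)
             if structure.residue_name(r) in criteria.hydrophobic_residues]
    res_b = [r for r in domain_b.residues_in(structure)
             if structure.residue_name(r) in criteria.hydrophobic_residues]
    if not domain_a.residues_in(structure) or not domain_b.residues_in(structure):
        raise ValueError("empty domain selection: "
                         f"{domain_a.name} or {domain_b.name} selects no residues")
    if set(res_a) & set(res_b):
        raise ValueError("domains overlap in residue indices")
    if not res_a or not res_b:
        return []
    ca_coords, ca_owner = _residue_carbons(structure, res_a, criteria.sidechain_only)
    cb_coords, cb_owner = _residue_carbons(structure, res_b, criteria.sidechain_only)
    if len(ca_coords) == 0 or len(cb_coords) == 0:
        return []
    tree = cKDTree(cb_coords)
    counts: dict[tuple[int, int], int] = {}
    mins: dict[tuple[int, int], float] = {}
    neighbor_lists = tree.query_ball_point(ca_coords, r=criteria.max_carbon_distance)
    for ia, neighbors in enumerate(neighbor_lists):
        for ib in neighbors:
            key = (int(ca_owner[ia]), int(cb_owner[ib]))
            d = float(np.linalg.norm(ca_coords[ia] - cb_coords[ib]))
            counts[key] = counts.get(key, 0) + 1
            mins[key] = min(mins.get(key, np.inf), d)
    out = []
    for (ra, rb), n in sorted(counts.items()):
        if n >= criteria.min_carbon_pairs:
            out.append(InterfacePair(
                residue_a=ra, residue_b=rb,
                name_a=structure.residue_name(ra),
                name_b=structure.residue_name(rb),
                n_carbon_pairs=n, min_distance=mins[(ra, rb)]))
    return out


def interface_pair_table(pairs: list[InterfacePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.residue_a, p.name_a, p.residue_b, p.name_b,
          p.n_carbon_pairs, p.min_distance) for p in pairs],
        columns=["residue_a", "name_a", "residue_b", "name_b",
                 "n_carbon_pairs", "min_distance_A"])


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion on heavy atoms.

    N/O atoms of different residues within ``max_donor_acceptor_distance``
    count as bonded; the D-H...A angle test applies only when explicit
    hydrogens are present in the structure.
    """

    max_donor_acceptor_distance: float = 3.5
    min_dha_angle: float = 120.0  # degrees
    donor_acceptor_elements: frozenset[str] = frozenset({"N", "O"})

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("min_dha_angle must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor_residue: int
    donor_atom: str
    acceptor_residue: int
    acceptor_atom: str
    distance: float
    angle: float | None  # degrees, None when no hydrogens exist

    @property
    def key(self) -> tuple[int, str, int, str]:
        return (self.donor_residue, self.donor_atom,
                self.acceptor_residue, self.acceptor_atom)

    @property
    def residue_pair(self) -> tuple[int, int]:
        return (self.donor_residue, self.acceptor_residue)


def find_hbonds(structure: Structure,
                criteria: HBondCriteria = HBondCriteria()) -> list[HBond]:
    """Geometric hydrogen-bond detection.

    Heavy-atom mode (the default for hydrogen-free structures): every N/O -
    N/O pair from different residues within the distance cutoff is
    reported, donor/acceptor assigned by atom order, angle None.  When the
    structure carries explicit hydrogens, a bond additionally requires some
    hydrogen within covalent range (1.2 A) of the donor subtending a
    D-H...A angle of at least ``min_dha_angle``.
    """
    rows = [i for i, a in enumerate(structure.atoms)
            if a.element in criteria.donor_acceptor_elements]
    if not rows:
        return []
    coords = structure.coords
    no_coords = coords[rows]
    h_rows = [i for i, a in enumerate(structure.atoms) if a.element == "H"]
    h_tree = cKDTree(coords[h_rows]) if h_rows else None
    tree = cKDTree(no_coords)
    bonds = []
    for ia, ib in sorted(tree.query_pairs(criteria.max_donor_acceptor_distance)):
        i, j = rows[ia], rows[ib]
        a, b = structure.atoms[i], structure.atoms[j]
        if a.residue_key == b.residue_key:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        angle = None
        if h_tree is not None:
            # treat each side as the candidate donor; keep the best angle
            angle = -1.0
            for donor, acceptor in ((i, j), (j, i)):
                for hh in h_tree.query_ball_point(coords[donor], r=1.2):
                    h = coords[h_rows[hh]]
                    v1 = coords[donor] - h
                    v2 = coords[acceptor] - h
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    angle = max(angle, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
            if angle < criteria.min_dha_angle:
                continue
        bonds.append(HBond(
            donor_residue=a.residue_index, donor_atom=a.name,
            acceptor_residue=b.residue_index, acceptor_atom=b.name,
            distance=d, angle=angle))
    return bonds


def hbond_table(bonds: list[HBond]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.donor_residue, b.donor_atom, b.acceptor_residue, b.acceptor_atom,
          b.distance, b.angle) for b in bonds],
        columns=["donor_residue", "donor_atom", "acceptor_residue",
                 "acceptor_atom", "distance_A", "angle_deg"])


# ---------------------------------------------------------------------------
# distance maps

@dataclass
class DistanceMatrix:
    """Symmetric inter-residue distance matrix over a residue selection."""

    residue_indices: list[int]
    matrix: np.ndarray
    metric: Metric

    def to_csv(self, path: str | Path | None = None) -> str:
        df = pd.DataFrame(self.matrix, index=self.residue_indices,
                          columns=self.residue_indices)
        text = f"# metric: {self.metric}\n" + df.to_csv()
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class DistanceDiffMap:
    """Per-pair internal-distance change between two alleles.

    entry (i, j) = d_b(map(i), map(j)) - d_a(i, j), defined on residues
    mapped in both structures.  Rigid-motion invariant by construction.
    """

    wt_indices: list[int]
    mut_indices: list[int]
    matrix: np.ndarray
    metric: Metric

    def to_csv(self, path: str | Path | None = None) -> str:
        df = pd.DataFrame(self.matrix, index=self.wt_indices,
                          columns=self.wt_indices)
        text = f"# metric: {self.metric} (rows/cols are wild-type residue numbers)\n" \
            + df.to_csv()
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.wt_indices)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.wt_indices[i], self.wt_indices[j],
                             self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["residue_i", "residue_j", "delta_A"])


def _metric_coords(structure: Structure, residues: Sequence[int], metric: Metric):
    """Either per-residue CA coords (ca) or (atom coords, owner ordinal)
    arrays (min_heavy)."""
    if metric == "ca":
        return structure.ca_coords(residues)
    rows, owners = [], []
    for ordi, r in enumerate(residues):
        sl = structure.residue_atoms(r)
        for i in range(sl.start, sl.stop):
            if structure.atoms[i].element != "H":
                rows.append(i)
                owners.append(ordi)
    return structure.coords[rows], np.asarray(owners)


def residue_distance_matrix(structure: Structure,
                            selection: Sequence[int] | None = None,
                            metric: Metric = "ca") -> DistanceMatrix:
    """Pairwise inter-residue distances under the chosen metric.

    ``ca``: distance between alpha carbons (raises listing residues that
    lack one).  ``min_heavy``: minimum over all heavy-atom pairs.
    """
    residues = list(selection) if selection is not None else structure.residue_indices
    if metric == "ca":
        coords = structure.ca_coords(residues)  # KeyError lists missing residues
        mat = cdist(coords, coords)
    elif metric == "min_heavy":
        coords, owners = _metric_coords(structure, residues, "min_heavy")
        n = len(residues)
        mat = np.full((n, n), np.inf)
        d = cdist(coords, coords)
        for oi in range(n):
            rows_i = owners == oi
            for oj in range(oi, n):
                rows_j = owners == oj
                mat[oi, oj] = mat[oj, oi] = d[np.ix_(rows_i, rows_j)].min()
        np.fill_diagonal(mat, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(residues, mat, metric)


def distance_diff_map(struct_a: Structure, struct_b: Structure,
                      residue_map: ResidueMap,
                      metric: Metric = "ca",
                      selection: Sequence[int] | None = None) -> DistanceDiffMap:
    """Distance-difference map between two alleles over mapped residues.

    ``selection`` restricts to a set of wild-type residue indices; asking
    for an unmapped residue is an error.
    """
    fwd = residue_map.forward
    if selection is None:
        wt = [w for w, m in residue_map.pairs
              if struct_a.has_residue(w) and struct_b.has_residue(m)]
    else:
        missing = [r for r in selection if r not in fwd]
        if missing:
            raise KeyError(f"residues not mapped between alleles: {missing}")
        wt = list(selection)
    mut = [fwd[w] for w in wt]
    da = residue_distance_matrix(struct_a, wt, metric).matrix
    db = residue_distance_matrix(struct_b, mut, metric).matrix
    return DistanceDiffMap(wt, mut, db - da, metric)


def diff_block_summary(diff: DistanceDiffMap, domain_a: DomainSpec,
                       domain_b: DomainSpec) -> dict[str, float]:
    """Mean distance change within and across two domains (off-diagonal
    upper-triangle entries only)."""
    idx = np.asarray(diff.wt_indices)
    in_a = np.array([r in domain_a for r in idx])
    in_b = np.array([r in domain_b for r in idx])
    iu = np.triu_indices(len(idx), k=1)
    out = {}
    masks = {
        f"intra_{domain_a.name}": np.outer(in_a, in_a),
        f"intra_{domain_b.name}": np.outer(in_b, in_b),
        f"cross_{domain_a.name}_{domain_b.name}": np.outer(in_a, in_b) | np.outer(in_b, in_a),
    }
    for name, mask in masks.items():
        sel = mask[iu]
        out[name] = float(diff.matrix[iu][sel].mean()) if sel.any() else float("nan")
    return out


def pair_distance_report(avg_a: Structure, avg_b: Structure,
                         pairs: list[InterfacePair],
                         residue_map: ResidueMap,
                         representative: Literal["CA", "sidechain_centroid"]
                         = "sidechain_centroid") -> pd.DataFrame:
    """Per-interface-pair separation in two (time-averaged) structures.

    For each pair found on allele A, the distance between the residues'
    representative points in A and in B (via the residue map), plus the
    change (positive delta = separation, i.e. interface disruption).  Pairs
    touching unmapped residues are flagged, not dropped.  The returned
    frame carries RMS aggregates over unflagged pairs in ``df.attrs``.
    """
    fwd = residue_map.forward
    rows = []
    for p in pairs:
        da = float(np.linalg.norm(
            representative_coords(avg_a, p.residue_a, representative)
            - representative_coords(avg_a, p.residue_b, representative)))
        mapped = p.residue_a in fwd and p.residue_b in fwd
        if mapped:
            db = float(np.linalg.norm(
                representative_coords(avg_b, fwd[p.residue_a], representative)
                - representative_coords(avg_b, fwd[p.residue_b], representative)))
            delta = db - da
        else:
            db = delta = float("nan")
        rows.append((p.residue_a, p.name_a, p.residue_b, p.name_b,
                     da, db, delta, not mapped))
    df = pd.DataFrame(rows, columns=["residue_a", "name_a", "residue_b",
                                     "name_b", "distance_a_A", "distance_b_A",
                                     "delta_A", "flagged"])
    ok = df[~df.flagged]
    df.attrs["rms_distance_a"] = float(np.sqrt((ok.distance_a_A ** 2).mean())) if len(ok) else float("nan")
    df.attrs["rms_distance_b"] = float(np.sqrt((ok.distance_b_A ** 2).mean())) if len(ok) else float("nan")
    df.attrs["representative"] = representative
    return df
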