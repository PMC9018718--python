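"""Solvent-accessible surface area and relative-solvent-accessibility bins.

Shrake-Rupley quadrature: each atom's accessible area is estimated from a
deterministic Fibonacci lattice of test points on its solvent-expanded
sphere (radius = van der Waals radius + probe radius, probe 1.4 A for
water); a point is accessible iff it lies outside every neighbour's
expanded sphere.  Relative solvent accessibility (RSA) divides a residue's
summed atom SASA by the tabulated theoretical maximum for its residue type
and is reported in decile bins — the convention in which a buried
activation-loop threonine sits at "10-20%" and a surface-exposed one at
"50-60%".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mapping import ResidueMap
from .pdbio import STANDARD_RESIDUES, Structure

__all__ = [
    "SASAParams",
    "RSARecord",
    "MAX_ASA",
    "VDW_RADII",
    "atom_sasa",
    "residue_sasa",
    "residue_rsa",
    "rsa_delta",
    "exposure_bin",
]

#: van der Waals radii (A) for the elements of heavy-atom protein models.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
                               "H": 1.20, "P": 1.80}

#: Theoretical maximum accessible surface area per residue type (A^2),
#: Tien-style Gly-X-Gly values, used to normalize SASA into RSA.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radius_table: Mapping[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_sasa(structure: Structure,
              params: SASAParams = SASAParams()) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    area_i = 4 pi (r_i + probe)^2 * (fraction of lattice points outside
    every neighbour's expanded sphere).  An isolated atom therefore gets
    its exact analytic sphere area for any lattice size.
    """
    coords = structure.coords
    try:
        radii = np.array([params.radius_table[a.element] for a in structure.atoms])
    except KeyError as exc:
        raise KeyError(f"element {exc.args[0]!r} missing from the SASA "
                       "radius table") from None
    expanded = radii + params.probe_radius
    sphere = _fibonacci_sphere(params.n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        neighbors = [j for j in tree.query_ball_point(coords[i], r=max_reach)
                     if j != i]
        points = coords[i] + expanded[i] * sphere
        if neighbors:
            nb = np.asarray(neighbors)
            # accessible iff outside every neighbour's expanded sphere
            d2 = ((points[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            accessible = (d2 >= (expanded[nb] ** 2)[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * frac
    return areas


def residue_sasa(structure: Structure,
                 params: SASAParams = SASAParams()) -> dict[int, float]:
    """Summed atom SASA per residue (keyed by author residue number)."""
    per_atom = atom_sasa(structure, params)
    out: dict[int, float] = {}
    for atom, area in zip(structure.atoms, per_atom):
        out[atom.residue_index] = out.get(atom.residue_index, 0.0) + float(area)
    return out


def exposure_bin(rsa: float) -> str:
    """Decile exposure label; RSA >= 1 (possible for extended conformations)
    reports the top bin rather than clamping."""
    if rsa >= 1.0:
        return "90-100%+"
    k = int(rsa * 10)
    return f"{10 * k}-{10 * (k + 1)}%"


@dataclass(frozen=True)
class RSARecord:
    residue_index: int
    residue_name: str
    sasa: float
    max_asa: float | None
    rsa: float | None
    exposure_bin: str | None

    @property
    def flagged(self) -> bool:
        """True for residue types without a reference maximum area."""
        return self.rsa is None


def residue_rsa(structure: Structure,
                params: SASAParams = SASAParams(),
                max_asa_table: Mapping[str, float] | None = None
                ) -> list[RSARecord]:
    """Relative solvent accessibility per residue, with decile bins.

    Residue types absent from the reference table (non-standard residues)
    are reported with raw SASA but null RSA/bin (flagged).
    """
    table = MAX_ASA if max_asa_table is None else max_asa_table
    per_res = residue_sasa(structure, params)
    records = []
    for r in structure.residue_indices:
        name = structure.residue_name(r)
        sasa = per_res[r]
        if name in table and name in STANDARD_RESIDUES:
            rsa = sasa / table[name]
            records.append(RSARecord(r, name, sasa, table[name], rsa,
                                     exposure_bin(rsa)))
        else:
            records.append(RSARecord(r, name, sasa, None, None, None))
    return records


def rsa_table(records: Sequence[RSARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.residue_index, r.residue_name, r.sasa, r.max_asa, r.rsa,
          r.exposure_bin) for r in records],
        columns=["residue_index", "residue_name", "sasa_A2", "max_asa_A2",
                 "rsa", "bin"])


def rsa_delta(records_wt: Sequence[RSARecord],
              records_mut: Sequence[RSARecord],
              residue_map: ResidueMap) -> pd.DataFrame:
    """Join wild-type and mutant RSA records over mapped residues.

    Returns a frame keyed by wild-type residue number with (rsa_wt,
    rsa_mut, delta, bin_wt, bin_mut).  Unmapped residues of either side
    are listed in ``df.attrs['unmapped_wt']`` / ``['unmapped_mut']``.
    """
    fwd = residue_map.forward
    by_wt = {r.residue_index: r for r in records_wt}
    by_mut = {r.residue_index: r for r in records_mut}
    rows = []
    for w, rec in by_wt.items():
        m = fwd.get(w)
        if m is None or m not in by_mut:
            continue
        mrec = by_mut[m]
        delta = (mrec.rsa - rec.rsa
                 if rec.rsa is not None and mrec.rsa is not None else float("nan"))
        rows.append((w, m, rec.residue_name, rec.rsa, mrec.rsa, delta,
                     rec.exposure_bin, mrec.exposure_bin))
    df = pd.DataFrame(rows, columns=["wt_residue", "mut_residue", "residue_name",
                                     "rsa_wt", "rsa_mut", "delta_rsa",
                                     "bin_wt", "bin_mut"])
    mapped_mut = set(fwd.values())
    df.attrs["unmapped_wt"] = sorted(w for w in by_wt if w not in fwd)
    df.attrs["unmapped_mut"] = sorted(m for m in by_mut if m not in mapped_mut)
    return df


def bin_shift(rsa_wt: float, rsa_mut: float) -> int:
    """Number of decile bins gained (positive = more exposed)."""
    return min(int(rsa_mut * 10), 9) - min(int(rsa_wt * 10), 9)
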