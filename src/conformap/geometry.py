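"""Rigid-body superposition, ensemble time-averaging, and per-residue
displacement between alleles.

The displacement analysis answers "relative to what frame did residue X
move?": two time-averaged structures are superposed on the C-alpha atoms of
a chosen reference region (by default the domain the perturbation does not
touch), and each mapped residue's displacement is the distance between its
representative atoms in that common frame.  Time-averaging optionally
removes overall rigid motion by superposing every frame onto a reference
frame before taking the per-atom Cartesian mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .mapping import ResidueMap
from .pdbio import Ensemble, Structure

__all__ = [
    "SuperpositionResult",
    "DisplacementRecord",
    "superpose",
    "apply_superposition",
    "time_average",
    "per_residue_displacement",
    "representative_coords",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid transform mapping `moving` onto `reference`:
    x -> rotation @ x + translation."""

    rotation: np.ndarray    # (3, 3), proper: det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_points: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def superpose(moving: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal rigid (proper-rotation) superposition by the Kabsch method.

    Returns the transform that minimizes the (weighted) RMSD of ``moving``
    onto ``reference``.  Requires at least 3 non-collinear points.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    p_cen = (w[:, None] * P).sum(0) / wsum
    q_cen = (w[:, None] * Q).sum(0) / wsum
    P0, Q0 = P - p_cen, Q - q_cen
    # collinearity / rank check on the centered moving set
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise ValueError("degenerate point set: all points are collinear")
    # scipy's align_vectors implements Kabsch with proper-rotation
    # (reflection-corrected) guarantees; the residual is recomputed from
    # the fitted transform for full float64 accuracy near zero.
    rot, _ = Rotation.align_vectors(Q0, P0, weights=w)
    R = rot.as_matrix()
    t = q_cen - R @ p_cen
    resid = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((w * np.sum(resid ** 2, axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_points=n)


def apply_superposition(structure: Structure, result: SuperpositionResult) -> Structure:
    return structure.transformed(result.rotation, result.translation)


def _ca_atom_indices(structure: Structure,
                     residue_indices: Iterable[int] | None = None) -> list[int]:
    if residue_indices is None:
        return [i for i, a in enumerate(structure.atoms) if a.name == "CA"]
    wanted = set(residue_indices)
    return [i for i, a in enumerate(structure.atoms)
            if a.name == "CA" and a.residue_index in wanted]


def time_average(ensemble: Ensemble, align: bool = True,
                 align_selection: Sequence[int] | None = None,
                 reference_frame: int = 0,
                 label: str | None = None) -> Structure:
    """Per-atom Cartesian mean structure of an ensemble.

    With ``align`` on (the default) every frame is first superposed onto
    ``reference_frame`` using the C-alpha atoms of ``align_selection``
    (residue indices; default all residues), so overall tumbling and drift
    do not smear the average.  Averaging is done on Cartesian coordinates
    after superposition; no internal-coordinate averaging is attempted.
    """
    topo = ensemble.topology
    frames = ensemble.frames
    if align:
        sel = _ca_atom_indices(topo, align_selection)
        if len(sel) < 3:
            raise ValueError(
                "alignment selection must contain >= 3 C-alpha atoms "
                f"(got {len(sel)})")
        ref = frames[reference_frame][sel]
        aligned = np.empty_like(frames)
        for i in range(frames.shape[0]):
            sup = superpose(frames[i][sel], ref)
            aligned[i] = sup.transform(frames[i])
        mean = aligned.mean(axis=0)
    else:
        mean = frames.mean(axis=0)
    name = label if label is not None else topo.label
    return topo.with_coords(mean, label=name)


@dataclass(frozen=True)
class DisplacementRecord:
    """Distance between a residue's representative atoms in two alleles,
    after superposition on the reference region."""

    wt_residue: int
    mut_residue: int
    residue_name: str
    displacement: float  # Angstrom, >= 0


def representative_coords(structure: Structure, residue_index: int,
                          representative: Literal["CA", "sidechain_centroid"] = "CA"
                          ) -> np.ndarray:
    """Representative point of one residue.

    ``CA`` uses the alpha carbon; ``sidechain_centroid`` averages all heavy
    side-chain atoms (falling back to CA for glycine-like residues with no
    side chain).
    """
    sl = structure.residue_atoms(residue_index)
    if representative == "CA":
        return np.asarray(structure.atoms[structure.atom_index(residue_index, "CA")].xyz)
    backbone = {"N", "CA", "C", "O", "OXT"}
    rows = [i for i in range(sl.start, sl.stop)
            if structure.atoms[i].name not in backbone]
    if not rows:
        return np.asarray(structure.atoms[structure.atom_index(residue_index, "CA")].xyz)
    return structure.coords[rows].mean(axis=0)


def per_residue_displacement(avg_wt: Structure, avg_mut: Structure,
                             residue_map: ResidueMap,
                             frame_selection: Sequence[int] | None = None,
                             representative: Literal["CA", "sidechain_centroid"] = "CA",
                             ) -> list[DisplacementRecord]:
    """Displacement of every mapped residue between two (time-averaged)
    structures.

    ``frame_selection`` (wild-type residue indices) defines the rigid
    reference: the mutant is superposed onto the wild type using the
    C-alpha atoms of the mapped residues in that region, then each mapped
    residue's displacement is the distance between representative atoms.
    Default selection: all mapped residues.
    """
    mapped = [(w, m) for w, m in residue_map.pairs
              if avg_wt.has_residue(w) and avg_mut.has_residue(m)]
    if frame_selection is None:
        frame = mapped
    else:
        wanted = set(frame_selection)
        frame = [(w, m) for w, m in mapped if w in wanted]
    frame_pairs = []
    for w, m in frame:
        try:
            frame_pairs.append((avg_wt.atom_index(w, "CA"), avg_mut.atom_index(m, "CA")))
        except KeyError:
            continue
    if len(frame_pairs) < 3:
        raise ValueError("no usable mapped C-alpha atoms in frame_selection "
                         f"(found {len(frame_pairs)}, need >= 3)")
    wt_ca = avg_wt.coords[[i for i, _ in frame_pairs]]
    mut_ca = avg_mut.coords[[j for _, j in frame_pairs]]
    sup = superpose(mut_ca, wt_ca)
    mut_fit = apply_superposition(avg_mut, sup)
    records = []
    for w, m in mapped:
        p = representative_coords(avg_wt, w, representative)
        q = representative_coords(mut_fit, m, representative)
        records.append(DisplacementRecord(
            wt_residue=w, mut_residue=m,
            residue_name=avg_wt.residue_name(w),
            displacement=float(np.linalg.norm(p - q))))
    return records


def per_frame_displacement(avg_wt: Structure, mut_ensemble: Ensemble,
                           residue_map: ResidueMap,
                           frame_selection: Sequence[int] | None = None,
                           representative: Literal["CA", "sidechain_centroid"] = "CA",
                           ) -> list[DisplacementRecord]:
    """Alternative displacement mode: compute per ensemble frame, then
    average.

    Each mutant frame is compared against the wild-type time-averaged
    structure (same superposition rule as
    :func:`per_residue_displacement`) and the per-residue displacements
    are averaged over frames.  With a noise-free single-frame ensemble
    this reduces exactly to the time-averaged mode; with noise it is
    upward-biased by the per-frame scatter, which is why the
    time-averaged mode is the default.
    """
    sums: dict[tuple[int, int], float] = {}
    names: dict[tuple[int, int], str] = {}
    for i in range(mut_ensemble.n_frames):
        frame = mut_ensemble.frame(i)
        for rec in per_residue_displacement(avg_wt, frame, residue_map,
                                            frame_selection, representative):
            key = (rec.wt_residue, rec.mut_residue)
            sums[key] = sums.get(key, 0.0) + rec.displacement
            names[key] = rec.residue_name
    n = mut_ensemble.n_frames
    return [DisplacementRecord(w, m, names[(w, m)], sums[(w, m)] / n)
            for (w, m) in sorted(sums)]


def displacement_table(records: list[DisplacementRecord]):
    """Displacement report as a pandas DataFrame
    (wt_residue, mut_residue, residue_name, displacement_A)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.wt_residue, r.mut_residue, r.residue_name, r.displacement)
         for r in records],
        columns=["wt_residue", "mut_residue", "residue_name", "displacement_A"])
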