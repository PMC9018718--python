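"""Model-similarity gating and 3D mutation clustering.

Two concerns live here.  First, a quality gate for comparing structural
models of the same protein: the TM-score of the mapped C-alpha trace,
converted to a p-value against the null of unrelated structures and
corrected across model pairs (Benjamini-Hochberg, i.e. Q values) — models
whose domains are "significantly more similar than expected by chance"
pass the gate.  Second, spatial clustering of mutated residues: mutations
that are far apart in sequence but lie within a few Angstrom of one
another in the folded protein (the classic 5 A criterion) form a 3D
cluster, e.g. at an autoinhibitory domain interface.

Only the superposition is optimized for the TM-score; the residue
correspondence comes from the mapping layer, because model pairs here are
alleles of one protein whose alignment is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .contacts import residue_distance_matrix
from .geometry import superpose
from .mapping import ResidueMap
from .pdbio import Structure

__all__ = [
    "TMResult",
    "ClusterCriteria",
    "ClusterResult",
    "tm_d0",
    "tm_score",
    "tm_pvalue",
    "bh_adjust",
    "proximity_clusters",
]


@dataclass(frozen=True)
class TMResult:
    tm_score: float
    aligned_length: int
    d0: float
    normalization_length: int


def tm_d0(normalization_length: int) -> float:
    """TM-score distance scale d0 = 1.24 (L - 15)^(1/3) - 1.8, floored at
    0.5 A (the floor covers short chains, L <= ~21)."""
    if normalization_length <= 15:
        return 0.5
    return max(0.5, 1.24 * (normalization_length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_distances(d: np.ndarray, d0: float, l_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_score(struct_a: Structure, struct_b: Structure,
             residue_map: ResidueMap,
             normalization_length: int | None = None,
             fixed_superposition: bool = False) -> TMResult:
    """TM-score over the mapped C-alpha pairs of two structures.

    TM = (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2) with d0 from
    :func:`tm_d0`.  With ``fixed_superposition`` the structures are scored
    in their given frames; otherwise the score-maximizing superposition is
    sought by iterated Kabsch fits on shrinking inlier subsets (the
    TM-align-style heuristic, run from several seed fragments), which never
    scores lower than the plain full-set fit.
    """
    pairs = [(w, m) for w, m in residue_map.pairs
             if struct_a.has_residue(w) and struct_b.has_residue(m)]
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 mapped residues with C-alpha, got {len(pairs)}")
    A = struct_a.ca_coords([w for w, _ in pairs])
    B = struct_b.ca_coords([m for _, m in pairs])
    n = len(pairs)
    l_norm = n if normalization_length is None else int(normalization_length)
    d0 = tm_d0(l_norm)

    if fixed_superposition:
        d = np.linalg.norm(A - B, axis=1)
        return TMResult(_tm_from_distances(d, d0, l_norm), n, d0, l_norm)

    cutoff = max(d0 + 1.0, 3.5)
    best = -1.0
    seeds = [np.arange(n), np.arange(n // 2 + 2), np.arange(n // 2 - 2, n)]
    for seed in seeds:
        inliers = np.unique(np.clip(seed, 0, n - 1))
        if len(inliers) < 3:
            continue
        prev: set[int] | None = None
        for _ in range(30):
            sup = superpose(B[inliers], A[inliers])
            d_all = np.linalg.norm(A - sup.transform(B), axis=1)
            score = _tm_from_distances(d_all, d0, l_norm)
            best = max(best, score)
            new = np.where(d_all < cutoff)[0]
            if len(new) < 3:
                new = np.argsort(d_all)[:3]
            new_set = set(int(v) for v in new)
            if new_set == prev:
                break
            prev = new_set
            inliers = np.asarray(sorted(new_set))
    return TMResult(best, n, d0, l_norm)


# extreme-value null for TM-scores of unrelated structure pairs; this
# parametrization puts p(0.5) ~ 5e-7, matching the conventional reading
# that TM >= 0.5 is far beyond chance similarity.
_EVD_MU = 0.1512
_EVD_SIGMA = 0.0242


def tm_pvalue(tm: float, length: int) -> float:
    """Right-tail probability of observing >= tm between unrelated
    structures of the given length, under an extreme-value null.

    Strictly decreasing in tm at fixed length; defined for chains long
    enough that d0 is off its floor (length >= 22).
    """
    if not (0.0 < tm <= 1.0):
        raise ValueError(f"tm must be in (0, 1], got {tm}")
    if length < 22:
        raise ValueError(f"length must be >= 22, got {length}")
    z = (tm - _EVD_MU) / _EVD_SIGMA
    # P(TM >= tm) = 1 - exp(-exp(-z)); use expm1 for the small-p regime
    return float(-np.expm1(-np.exp(-z)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# 3D proximity clustering

@dataclass(frozen=True)
class ClusterCriteria:
    cutoff: float = 5.0
    metric: Literal["min_heavy", "ca"] = "min_heavy"
    linkage: Literal["component", "clique"] = "component"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ClusterResult:
    """Partition of the input residues into spatial clusters (singletons
    included), in deterministic order: larger clusters first, ties by the
    smallest member."""

    clusters: list[frozenset[int]]
    criteria: ClusterCriteria

    @property
    def non_singleton(self) -> list[frozenset[int]]:
        return [c for c in self.clusters if len(c) > 1]

    def table(self, structure: Structure | None = None) -> pd.DataFrame:
        rows = []
        for ci, cluster in enumerate(self.clusters):
            for r in sorted(cluster):
                name = structure.residue_name(r) if structure is not None else ""
                rows.append((ci, r, name))
        return pd.DataFrame(rows, columns=["cluster_id", "residue_index",
                                           "residue_name"])


def proximity_clusters(structure: Structure, residues: Sequence[int],
                       criteria: ClusterCriteria = ClusterCriteria()
                       ) -> ClusterResult:
    """Cluster mutated residues by spatial adjacency in the folded protein.

    Builds the graph of residue pairs whose inter-residue distance (default
    minimum heavy-atom distance) is within ``criteria.cutoff`` (default
    5 A).  ``component`` linkage returns connected components — residues
    chained through intermediates cluster together.  ``clique`` linkage
    reads "within 5 A of one another" literally: maximal sets with ALL
    pairwise distances inside the cutoff, resolved into a partition by
    greedily peeling the largest maximal clique (ties to the
    lexicographically smallest member set).
    """
    residues = list(dict.fromkeys(residues))
    missing = [r for r in residues if not structure.has_residue(r)]
    if missing:
        raise KeyError(f"residues absent from structure: {missing}")
    dm = residue_distance_matrix(structure, residues, criteria.metric)
    g = nx.Graph()
    g.add_nodes_from(residues)
    n = len(residues)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.matrix[i, j] <= criteria.cutoff:
                g.add_edge(residues[i], residues[j])

    if criteria.linkage == "component":
        clusters = [frozenset(c) for c in nx.connected_components(g)]
    elif criteria.linkage == "clique":
        clusters = []
        remaining = g.copy()
        while remaining.number_of_nodes():
            cliques = [sorted(c) for c in nx.find_cliques(remaining)]
            cliques.sort(key=lambda c: (-len(c), c))
            take = cliques[0]
            clusters.append(frozenset(take))
            remaining.remove_nodes_from(take)
    else:
        raise ValueError(f"unknown linkage {criteria.linkage!r}")
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterResult(clusters, criteria)


def tm_gate_report(results: Sequence[tuple[str, TMResult]],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Multiple-testing-corrected significance gate over model pairs.

    Each (label, TMResult) becomes a row with its p-value, BH q-value, and
    pass/fail at ``alpha`` — the gate for keeping a modeled allele whose
    mapped domain is significantly more similar to the wild-type model
    than chance.
    """
    ps = [tm_pvalue(r.tm_score, r.normalization_length) for _, r in results]
    qs = bh_adjust(ps)
    rows = [(label, r.tm_score, r.d0, p, q, bool(q < alpha))
            for (label, r), p, q in zip(results, ps, qs)]
    return pd.DataFrame(rows, columns=["pair", "tm", "d0_A", "p", "q", "pass"])
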