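"""TM-score machinery, p-value contract, BH correction, and 3D proximity
clustering (with union-find and subset-enumeration oracles)."""

import itertools

import numpy as np
import pytest

from conformap.mapping import ResidueMap
from conformap.pdbio import Atom, Structure
from conformap.similarity import (ClusterCriteria, bh_adjust,
                                  proximity_clusters, tm_d0, tm_pvalue,
                                  tm_score, tm_gate_report)

from conftest import random_structure


def ca_structure(coords, start=1):
    return Structure([Atom(i + 1, "CA", "C", "A", start + i, "ALA", tuple(c))
                      for i, c in enumerate(coords)])


def test_tm_score_identity_is_exactly_one(toy_closed):
    m = ResidueMap.identity(toy_closed.residue_indices)
    for fixed in (True, False):
        r = tm_score(toy_closed, toy_closed, m, fixed_superposition=fixed)
        assert r.tm_score == 1.0


def test_d0_closed_form():
    assert tm_d0(128) == pytest.approx(1.24 * 113 ** (1 / 3) - 1.8, abs=1e-12)
    assert tm_d0(128) == pytest.approx(4.19, abs=0.005)
    # short chains ride the floor
    assert tm_d0(15) == 0.5
    assert tm_d0(21) == 0.5


def test_all_pairs_at_d0_score_half():
    """Every mapped pair exactly d0 apart in the given frame: each term is
    1/2, so the fixed-frame TM-score is exactly 0.5."""
    rng = np.random.default_rng(0)
    n = 30
    d0 = tm_d0(n)
    A = rng.normal(size=(n, 3)) * 10
    B = A + np.array([0.0, 0.0, d0])
    sa, sb = ca_structure(A), ca_structure(B)
    r = tm_score(sa, sb, ResidueMap.identity(range(1, n + 1)),
                 fixed_superposition=True)
    assert r.tm_score == pytest.approx(0.5, abs=1e-12)


def test_optimized_superposition_never_scores_below_fixed():
    rng = np.random.default_rng(4)
    n = 40
    A = rng.normal(size=(n, 3)) * 8
    B = A + rng.normal(scale=1.5, size=(n, 3))
    sa, sb = ca_structure(A), ca_structure(B)
    m = ResidueMap.identity(range(1, n + 1))
    fixed = tm_score(sa, sb, m, fixed_superposition=True).tm_score
    opt = tm_score(sa, sb, m).tm_score
    assert opt >= fixed - 1e-12
    assert 0 < opt <= 1


def test_tm_score_decreases_with_noise(toy_closed):
    m = ResidueMap.identity(toy_closed.residue_indices)
    rng = np.random.default_rng(9)
    noise = rng.normal(size=(len(toy_closed), 3))
    scores = []
    for sd in (0.0, 0.5, 2.0, 6.0):
        noisy = toy_closed.with_coords(toy_closed.coords + sd * noise)
        scores.append(tm_score(toy_closed, noisy, m).tm_score)
    assert scores == sorted(scores, reverse=True)
    assert scores[0] == 1.0


def test_tm_score_needs_four_mapped_pairs():
    s = ca_structure(np.eye(3) * 3.0)
    with pytest.raises(ValueError, match=">= 4"):
        tm_score(s, s, ResidueMap.identity([1, 2, 3]))


def test_tm_pvalue_contract():
    # strictly decreasing in tm at fixed length
    grid = np.linspace(0.05, 1.0, 40)
    for L in (25, 100, 400):
        ps = [tm_pvalue(t, L) for t in grid]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert all(a > b for a, b in zip(ps, ps[1:]))
    assert tm_pvalue(1.0, 100) < tm_pvalue(0.5, 100)
    # a TM-score of 0.5 is far beyond chance; 0.17 is typical of chance
    assert tm_pvalue(0.5, 100) < 1e-5
    assert tm_pvalue(0.17, 100) > 0.1
    with pytest.raises(ValueError):
        tm_pvalue(0.0, 100)
    with pytest.raises(ValueError):
        tm_pvalue(1.5, 100)
    with pytest.raises(ValueError):
        tm_pvalue(0.5, 10)


def test_gate_report_passes_similar_models(toy_closed):
    m = ResidueMap.identity(toy_closed.residue_indices)
    r = tm_score(toy_closed, toy_closed, m)
    noisy = toy_closed.with_coords(
        toy_closed.coords
        + np.random.default_rng(1).normal(scale=0.5, size=(len(toy_closed), 3)))
    r2 = tm_score(toy_closed, noisy, m)
    rep = tm_gate_report([("self", r), ("noisy", r2)], alpha=0.05)
    assert rep["pass"].all()
    assert (rep.q < 0.05).all()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def brute_force_bh(ps):
    """Step-up definition: q_(i) = min over j >= i of p_(j) * m / j."""
    ps = np.asarray(ps, float)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


def test_bh_simple_cases():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


@pytest.mark.parametrize("seed", range(10))
def test_bh_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    ps = rng.uniform(size=rng.integers(1, 40))
    np.testing.assert_allclose(bh_adjust(ps), brute_force_bh(ps), atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# proximity clustering

def three_residue_structure(d_ab, d_bc, d_ac):
    """Residues A=1, B=2, C=3 with the given pairwise CA distances
    (must satisfy the triangle inequality)."""
    ax, ay = 0.0, 0.0
    bx, by = d_ab, 0.0
    cx = (d_ac ** 2 - d_bc ** 2 + d_ab ** 2) / (2 * d_ab)
    cy = np.sqrt(max(d_ac ** 2 - cx ** 2, 0.0))
    return ca_structure([(ax, ay, 0.0), (bx, by, 0.0), (cx, cy, 0.0)])


def test_single_residue_is_singleton(toy_closed):
    r = proximity_clusters(toy_closed, [1])
    assert r.clusters == [frozenset({1})]


def test_chain_of_three_component_vs_clique():
    s = three_residue_structure(3.0, 3.0, 5.9)
    comp = proximity_clusters(s, [1, 2, 3],
                              ClusterCriteria(cutoff=5.0, metric="ca",
                                              linkage="component"))
    assert comp.clusters == [frozenset({1, 2, 3})]
    cliq = proximity_clusters(s, [1, 2, 3],
                              ClusterCriteria(cutoff=5.0, metric="ca",
                                              linkage="clique"))
    # maximal cliques {1,2} and {2,3}; largest-first peeling with
    # lexicographic ties takes {1,2}, leaving {3}
    assert cliq.clusters == [frozenset({1, 2}), frozenset({3})]
    # partition invariant
    assert set().union(*cliq.clusters) == {1, 2, 3}
    assert sum(len(c) for c in cliq.clusters) == 3


def test_far_residues_are_singletons():
    s = ca_structure([(0.0, 0, 0), (50.0, 0, 0)])
    for linkage in ("component", "clique"):
        r = proximity_clusters(s, [1, 2],
                               ClusterCriteria(metric="ca", linkage=linkage))
        assert r.clusters == [frozenset({1}), frozenset({2})]


def test_missing_residue_named():
    s = ca_structure([(0.0, 0, 0)])
    with pytest.raises(KeyError, match="42"):
        proximity_clusters(s, [1, 42])


def union_find_components(structure, residues, cutoff, metric):
    from conformap.contacts import residue_distance_matrix
    parent = {r: r for r in residues}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    dm = residue_distance_matrix(structure, residues, metric)
    for i, j in itertools.combinations(range(len(residues)), 2):
        if dm.matrix[i, j] <= cutoff:
            parent[find(residues[i])] = find(residues[j])
    groups = {}
    for r in residues:
        groups.setdefault(find(r), set()).add(r)
    return sorted((frozenset(g) for g in groups.values()),
                  key=lambda c: (-len(c), min(c)))


@pytest.mark.parametrize("seed", range(15))
def test_component_linkage_matches_union_find(seed):
    s = random_structure(seed, n_residues=12, box=16.0)
    residues = s.residue_indices
    crit = ClusterCriteria(cutoff=5.0, metric="min_heavy")
    ours = proximity_clusters(s, residues, crit)
    assert ours.clusters == union_find_components(s, residues, 5.0, "min_heavy")


@pytest.mark.parametrize("seed", range(8))
def test_clique_linkage_properties(seed):
    """Every emitted clique is internally within the cutoff and maximal
    among the residues still unassigned when it was taken."""
    from conformap.contacts import residue_distance_matrix
    s = random_structure(seed, n_residues=10, box=14.0)
    residues = s.residue_indices
    crit = ClusterCriteria(cutoff=6.0, metric="min_heavy", linkage="clique")
    result = proximity_clusters(s, residues, crit)
    dm = residue_distance_matrix(s, residues, "min_heavy")
    idx = {r: i for i, r in enumerate(residues)}
    assert sorted(r for c in result.clusters for r in c) == sorted(residues)
    for c in result.clusters:
        for a, b in itertools.combinations(sorted(c), 2):
            assert dm.matrix[idx[a], idx[b]] <= 6.0 + 1e-9


def test_increasing_cutoff_never_splits_clusters(toy_closed):
    residues = toy_closed.residue_indices[:30]
    prev = None
    for cutoff in (4.0, 6.0, 9.0, 14.0):
        r = proximity_clusters(toy_closed, residues,
                               ClusterCriteria(cutoff=cutoff, metric="ca"))
        if prev is not None:
            # each earlier cluster is contained in some later cluster
            for c in prev:
                assert any(c <= d for d in r.clusters)
        prev = r.clusters


def test_toy_interface_mutations_cluster_at_interface(toy, ground_truth):
    """Residues of the designed interface pairs plus the marker form one
    spatial cluster across the closed interface, the way physically
    adjacent mutations cluster in 3D despite distant sequence positions."""
    closed, truth = toy
    muts = sorted({r for p in truth.true_interface_pairs for r in p})
    result = proximity_clusters(closed, muts, ClusterCriteria(cutoff=5.0))
    big = result.clusters[0]
    # every designed pair is joined across the interface
    for a, b in truth.true_interface_pairs:
        assert any(a in c and b in c for c in result.clusters)
    assert len(big) >= 2
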