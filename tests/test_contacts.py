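"""Interface-pair detection, hydrogen bonds, and distance maps, each
checked against brute-force all-pair oracles."""

import numpy as np
import pytest

from conformap.contacts import (ContactCriteria, DomainSpec, HBondCriteria,
                                distance_diff_map, find_hbonds,
                                find_interface_pairs, pair_distance_report,
                                residue_distance_matrix)
from conformap.mapping import ResidueMap
from conformap.pdbio import Atom, Structure

from conftest import random_structure


def _mk(atoms):
    return Structure(atoms)


def _leu(res, base, xs):
    """A leucine-like residue: CA plus carbons at given x-offsets (y=z=0
    relative to base)."""
    out = [Atom(0, "CA", "C", "A", res, "LEU", tuple(base))]
    for i, dx in enumerate(xs):
        out.append(Atom(0, f"C{i + 1}", "C", "A", res, "LEU",
                        (base[0] + dx, base[1], base[2])))
    return out


DOM_A = DomainSpec("A", [(1, 10)])
DOM_B = DomainSpec("B", [(11, 20)])


def test_far_apart_domains_give_no_pairs():
    s = _mk(_leu(1, (0, 0, 0), [1, 2]) + _leu(11, (30, 0, 0), [-1, -2]))
    assert find_interface_pairs(s, DOM_A, DOM_B) == []


def test_exactly_six_carbon_pairs_at_threshold():
    """Six cross-residue carbon pairs at 3.8 A qualify; five do not."""
    # residue 1: three carbons in the x=0 plane; residue 11: three at x=3.8
    a = [Atom(0, "CA", "C", "A", 1, "LEU", (-5.0, 0, 0)),
         Atom(0, "C1", "C", "A", 1, "LEU", (0.0, 0.0, 0.0)),
         Atom(0, "C2", "C", "A", 1, "LEU", (0.0, 0.9, 0.0))]
    b = [Atom(0, "CA", "C", "A", 11, "LEU", (8.8, 0, 0)),
         Atom(0, "C1", "C", "A", 11, "LEU", (3.8, 0.0, 0.0)),
         Atom(0, "C2", "C", "A", 11, "LEU", (3.8, 0.9, 0.0)),
         Atom(0, "C3", "C", "A", 11, "LEU", (3.8, 0.45, 0.8))]
    s = _mk(a + b)
    # cross distances: C1/C2 of res 1 to C1/C2/C3 of res 11 -> 6 pairs <= 3.97
    crit = ContactCriteria(max_carbon_distance=4.0, min_carbon_pairs=6)
    pairs = find_interface_pairs(s, DOM_A, DOM_B, crit)
    assert len(pairs) == 1
    assert pairs[0].n_carbon_pairs == 6
    assert pairs[0].min_distance == pytest.approx(3.8)
    # with min 7 required (only 6 exist), nothing qualifies
    crit7 = ContactCriteria(max_carbon_distance=4.0, min_carbon_pairs=7)
    assert find_interface_pairs(s, DOM_A, DOM_B, crit7) == []


def test_non_hydrophobic_partner_excluded():
    a = _leu(1, (0, 0, 0), [1.0])
    b = [Atom(0, "CA", "C", "A", 11, "SER", (3.0, 0, 0)),
         Atom(0, "CB", "C", "A", 11, "SER", (2.0, 0, 0))]
    s = _mk(a + b)
    crit = ContactCriteria(min_carbon_pairs=1)
    assert find_interface_pairs(s, DOM_A, DOM_B, crit) == []


def test_empty_domain_selection_errors(toy_closed):
    with pytest.raises(ValueError, match="empty domain"):
        find_interface_pairs(toy_closed, DomainSpec("X", [(900, 950)]),
                             DomainSpec("Y", [(960, 990)]))


def brute_force_pairs(structure, dom_a, dom_b, crit):
    """O(n^2) oracle for the hydrophobic-contact criterion."""
    found = []
    res_a = [r for r in structure.residue_indices
             if r in dom_a and structure.residue_name(r) in crit.hydrophobic_residues]
    res_b = [r for r in structure.residue_indices
             if r in dom_b and structure.residue_name(r) in crit.hydrophobic_residues]
    coords = structure.coords
    for ra in res_a:
        for rb in res_b:
            n = 0
            dmin = np.inf
            for i in range(*structure.residue_atoms(ra).indices(len(structure))):
                if structure.atoms[i].element != "C":
                    continue
                for j in range(*structure.residue_atoms(rb).indices(len(structure))):
                    if structure.atoms[j].element != "C":
                        continue
                    d = np.linalg.norm(coords[i] - coords[j])
                    if d <= crit.max_carbon_distance:
                        n += 1
                        dmin = min(dmin, d)
            if n >= crit.min_carbon_pairs:
                found.append((ra, rb, n, dmin))
    return found


@pytest.mark.parametrize("seed", range(20))
def test_interface_pairs_match_brute_force(seed):
    s = random_structure(seed, n_residues=12, box=14.0)
    dom_a = DomainSpec("A", [(1, 6)])
    dom_b = DomainSpec("B", [(7, 12)])
    crit = ContactCriteria(min_carbon_pairs=2)
    ours = [(p.residue_a, p.residue_b, p.n_carbon_pairs,
             pytest.approx(p.min_distance)) for p in
            find_interface_pairs(s, dom_a, dom_b, crit)]
    oracle = [(ra, rb, n, pytest.approx(d))
              for ra, rb, n, d in sorted(brute_force_pairs(s, dom_a, dom_b, crit))]
    assert ours == oracle


def test_toy_interface_pairs_are_the_designed_ones(toy, toy_open):
    closed, truth = toy
    pairs = find_interface_pairs(closed, truth.domain_a, truth.domain_b)
    assert [(p.residue_a, p.residue_b) for p in pairs] == truth.true_interface_pairs
    assert all(p.n_carbon_pairs >= 6 for p in pairs)
    open_pairs = find_interface_pairs(toy_open, truth.domain_a, truth.domain_b)
    assert {(p.residue_a, p.residue_b) for p in open_pairs} <= \
        set(truth.true_interface_pairs)
    assert len(open_pairs) < len(pairs)


# ---------------------------------------------------------------------------
# hydrogen bonds

def test_hbond_basic_geometry():
    s = _mk([Atom(0, "N", "N", "A", 1, "ALA", (0.0, 0, 0)),
             Atom(0, "CA", "C", "A", 1, "ALA", (1.0, 1, 0)),
             Atom(0, "O", "O", "A", 2, "ALA", (2.9, 0, 0)),
             Atom(0, "CA", "C", "A", 2, "ALA", (4.0, 1, 0))])
    bonds = find_hbonds(s)
    assert len(bonds) == 1
    assert bonds[0].distance == pytest.approx(2.9)
    assert bonds[0].angle is None


def test_hbond_beyond_cutoff_and_carbon_only():
    far = _mk([Atom(0, "N", "N", "A", 1, "ALA", (0.0, 0, 0)),
               Atom(0, "O", "O", "A", 2, "ALA", (4.2, 0, 0))])
    assert find_hbonds(far) == []
    carbons = _mk([Atom(0, "CA", "C", "A", 1, "ALA", (0.0, 0, 0)),
                   Atom(0, "CB", "C", "A", 2, "ALA", (2.0, 0, 0))])
    assert find_hbonds(carbons) == []


def test_hbond_angle_applied_when_hydrogens_present():
    # linear N-H...O passes; bent (H off-axis ~60 deg) fails
    good = _mk([Atom(0, "N", "N", "A", 1, "ALA", (0.0, 0, 0)),
                Atom(0, "H", "H", "A", 1, "ALA", (1.0, 0, 0)),
                Atom(0, "O", "O", "A", 2, "ALA", (2.9, 0, 0))])
    bonds = find_hbonds(good)
    assert len(bonds) == 1 and bonds[0].angle == pytest.approx(180.0, abs=1e-6)
    bad = _mk([Atom(0, "N", "N", "A", 1, "ALA", (0.0, 0, 0)),
               Atom(0, "H", "H", "A", 1, "ALA", (0.0, 1.0, 0)),
               Atom(0, "O", "O", "A", 2, "ALA", (0.0, -2.9, 0))])
    assert find_hbonds(bad) == []


def test_designated_toy_hbond_lost_on_opening(toy, toy_open):
    closed, truth = toy
    (dres, datom), (ares, aatom) = truth.designated_hbond
    def keys(bonds):
        return {(b.donor_residue, b.donor_atom, b.acceptor_residue,
                 b.acceptor_atom) for b in bonds}
    assert (dres, datom, ares, aatom) in keys(find_hbonds(closed))
    assert (dres, datom, ares, aatom) not in keys(find_hbonds(toy_open))


# ---------------------------------------------------------------------------
# distance matrices and difference maps

def test_distance_matrix_3_4_5_triangle():
    s = _mk([Atom(0, "CA", "C", "A", 1, "ALA", (0.0, 0, 0)),
             Atom(0, "CA", "C", "A", 2, "ALA", (3.0, 4.0, 0))])
    dm = residue_distance_matrix(s, metric="ca")
    assert dm.matrix[0, 1] == pytest.approx(5.0)
    assert dm.matrix[1, 0] == pytest.approx(5.0)
    assert dm.matrix[0, 0] == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_min_heavy_matrix_matches_brute_force(seed):
    s = random_structure(seed, n_residues=8)
    dm = residue_distance_matrix(s, metric="min_heavy")
    ca = residue_distance_matrix(s, metric="ca")
    coords = s.coords
    n = len(s.residue_indices)
    for i, ri in enumerate(s.residue_indices):
        for j, rj in enumerate(s.residue_indices):
            if i == j:
                continue
            sli = s.residue_atoms(ri)
            slj = s.residue_atoms(rj)
            brute = min(np.linalg.norm(coords[x] - coords[y])
                        for x in range(sli.start, sli.stop)
                        for y in range(slj.start, slj.stop))
            assert dm.matrix[i, j] == pytest.approx(brute)
    # min over heavy atoms can never exceed the CA-CA distance
    assert (dm.matrix <= ca.matrix + 1e-9).all()
    np.testing.assert_allclose(dm.matrix, dm.matrix.T)


def test_distance_matrix_missing_ca_lists_residues():
    s = _mk([Atom(0, "CA", "C", "A", 1, "ALA", (0.0, 0, 0)),
             Atom(0, "CB", "C", "A", 2, "ALA", (3.0, 0, 0))])
    with pytest.raises(KeyError, match="2"):
        residue_distance_matrix(s, metric="ca")


def test_diff_map_identity_and_rigid_motion(toy_closed):
    m = ResidueMap.identity(toy_closed.residue_indices)
    d0 = distance_diff_map(toy_closed, toy_closed, m)
    assert np.abs(d0.matrix).max() == 0.0
    rng = np.random.default_rng(2)
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    moved = toy_closed.transformed(R, np.array([3.0, -1.0, 8.0]))
    d1 = distance_diff_map(toy_closed, moved, m)
    assert np.abs(d1.matrix).max() < 1e-9


def test_diff_map_antisymmetric_under_swap(toy_closed, toy_open, ground_truth):
    m = ground_truth.true_residue_map
    fwd = distance_diff_map(toy_closed, toy_open, m)
    back = distance_diff_map(toy_open, toy_closed, m.inverse())
    np.testing.assert_allclose(fwd.matrix, -back.matrix, atol=1e-9)


def test_diff_map_axis_aligned_translation():
    """Collinear construction: translating one residue along the line to
    another increases exactly that internal distance by |t|."""
    s = _mk([Atom(0, "CA", "C", "A", 1, "ALA", (0.0, 0, 0)),
             Atom(0, "CA", "C", "A", 2, "ALA", (8.0, 0, 0)),
             Atom(0, "CA", "C", "A", 3, "ALA", (0.0, 6.0, 0))])
    coords = s.coords
    coords[1] += (5.0, 0.0, 0.0)  # move residue 2 along the 1->2 axis
    moved = s.with_coords(coords)
    m = ResidueMap.identity([1, 2, 3])
    d = distance_diff_map(s, moved, m)
    assert d.matrix[0, 1] == pytest.approx(5.0)
    assert d.matrix[0, 2] == pytest.approx(0.0)


def test_diff_map_unmapped_selection_errors(toy_closed, toy_mutant):
    mutant, rmap = toy_mutant
    with pytest.raises(KeyError, match="not mapped"):
        distance_diff_map(toy_closed, mutant, rmap,
                          selection=[1, 2, 10**6])


def test_toy_diff_map_block_signature(toy_closed, toy_open, ground_truth):
    from conformap.contacts import diff_block_summary
    d = distance_diff_map(toy_closed, toy_open, ground_truth.true_residue_map)
    blocks = diff_block_summary(d, ground_truth.domain_a, ground_truth.domain_b)
    assert blocks["cross_A_B"] > 0
    assert abs(blocks["intra_A"]) < 1e-9
    assert abs(blocks["intra_B"]) < 1e-9


# ---------------------------------------------------------------------------
# pair distance report

def test_pair_report_identity_and_translation(toy, toy_open):
    closed, truth = toy
    m = truth.true_residue_map
    pairs = find_interface_pairs(closed, truth.domain_a, truth.domain_b)
    same = pair_distance_report(closed, closed, pairs, m)
    assert np.abs(same.delta_A).max() == pytest.approx(0.0)
    moved = pair_distance_report(closed, toy_open, pairs, m)
    # axis-aligned pairs separate by exactly the translation magnitude
    assert (moved.delta_A > 0).all()
    assert (moved.delta_A <= 12.0 + 1e-6).all()
    assert moved.attrs["rms_distance_b"] > moved.attrs["rms_distance_a"]


def test_pair_report_flags_unmapped_rows(toy_closed, ground_truth):
    pairs = find_interface_pairs(toy_closed, ground_truth.domain_a,
                                 ground_truth.domain_b)
    # build a map that drops one interface residue entirely
    drop = pairs[0].residue_a
    m = ResidueMap([(r, r) for r in toy_closed.residue_indices if r != drop])
    rep = pair_distance_report(toy_closed, toy_closed, pairs, m)
    flagged = rep[rep.flagged]
    assert len(flagged) == 1
    assert flagged.iloc[0].residue_a == drop
    assert np.isnan(flagged.iloc[0].distance_b_A)
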