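"""Shared fixtures: the synthetic toy protein family used across tests."""

import numpy as np
import pytest
from hypothesis import settings

from conformap import (ToySpec, apply_duplication, make_open_conformer,
                       make_two_domain_toy)
from conformap.pdbio import Atom, Structure

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: translation used to open the toy interface in fixture structures
OPEN_TRANSLATION = (12.0, 0.0, 0.0)
#: wild-type residue range duplicated in the mutant fixture (domain A interior)
DUP_RANGE = (30, 39)


@pytest.fixture(scope="session")
def toy():
    """(closed structure, ground truth) with default parameters."""
    return make_two_domain_toy(ToySpec())


@pytest.fixture(scope="session")
def toy_closed(toy):
    return toy[0]


@pytest.fixture(scope="session")
def ground_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_open(toy):
    closed, truth = toy
    return make_open_conformer(closed, truth.domain_b, OPEN_TRANSLATION,
                               linker_range=truth.linker_range)


@pytest.fixture(scope="session")
def toy_mutant(toy_open):
    """Open conformer with the duplication applied; (structure, map)."""
    return apply_duplication(toy_open, *DUP_RANGE)


def random_structure(seed: int, n_residues: int = 10,
                     box: float = 18.0) -> Structure:
    """Small random structure for oracle tests: each residue gets a CA
    plus 1-4 extra carbon/nitrogen/oxygen atoms scattered nearby."""
    rng = np.random.default_rng(seed)
    names = ["ALA", "VAL", "LEU", "ILE", "SER", "THR", "ASN", "PHE", "GLY"]
    atoms = []
    serial = 0
    for r in range(1, n_residues + 1):
        center = rng.uniform(0, box, size=3)
        resname = names[rng.integers(len(names))]
        serial += 1
        atoms.append(Atom(serial, "CA", "C", "A", r, resname, tuple(center)))
        n_extra = rng.integers(1, 5)
        for k in range(n_extra):
            pos = center + rng.normal(scale=1.5, size=3)
            element = ["C", "N", "O"][rng.integers(3)]
            serial += 1
            atoms.append(Atom(serial, f"X{k + 1}", element, "A", r, resname,
                              tuple(pos)))
    return Structure(atoms, label=f"random-{seed}")
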