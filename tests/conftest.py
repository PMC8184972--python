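"""Shared fixtures: toy complexes, slab fixtures, and the decoy feature dataset.

The decoy dataset fixture is session-scoped because feature extraction over
hundreds of rigid-body decoys is the single most expensive step; every test
that needs labelled interface features shares it.
"""

import numpy as np
import pytest

from piscore.structure_io import Atom, Chain, Residue, Structure
from piscore.synthetic_decoys import ToyComplexSpec, build_training_set, make_toy_complex

C_VDW = 1.87  # carbon radius of the bundled radii set


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_interface(toy_complex):
    from piscore.interface_core import assign_interface
    iface = assign_interface(toy_complex, "A", "B")
    assert iface is not None
    return iface


def make_slab_pair(gap: float, nx: int = 12, ny: int = 12, spacing: float = 1.0,
                   layers: int = 2) -> Structure:
    """Two flat carbon-atom slabs facing each other across `gap` (surface gap, A)."""

    def slab(cid, z0, direction):
        residues = []
        k = 0
        for lz in range(layers):
            for i in range(nx):
                atoms = [Atom(name="C", element="C",
                              coord=[i * spacing, j * spacing,
                                     z0 + direction * lz * 2.0])
                         for j in range(ny)]
                k += 1
                residues.append(Residue(name="ALA", seq_id=k, chain_id=cid,
                                        atoms=atoms))
        return Chain(cid, residues)

    upper = slab("A", 0.0, +1)
    lower = slab("B", -(2 * C_VDW + gap), -1)
    return Structure(id=f"slabs-gap{gap}", chains=[upper, lower])


def make_c3_trimer(n_residues: int = 24, radius: float = 4.8) -> Structure:
    """Three identical helices related by a 3-fold rotation about z."""
    base = make_toy_complex(ToyComplexSpec(seed=3, n_residues=n_residues)).chain("A")
    chains = []
    for k, cid in enumerate(("A", "B", "C")):
        ang = 2 * np.pi * k / 3
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0],
                      [0, 0, 1.0]])
        offset = R @ np.array([radius, 0.0, 0.0])
        residues = []
        for res in base.residues:
            atoms = [Atom(name=a.name, element=a.element,
                          coord=R @ a.coord + offset, occupancy=a.occupancy)
                     for a in res.atoms]
            residues.append(Residue(name=res.name, seq_id=res.seq_id,
                                    chain_id=cid, atoms=atoms))
        chains.append(Chain(cid, residues))
    return Structure(id="c3-trimer", chains=chains)


@pytest.fixture(scope="session")
def decoy_dataset():
    """Labelled features for >= 200 decoys per class over five toy complexes."""
    complexes = [make_toy_complex(ToyComplexSpec(seed=i)) for i in range(5)]
    return build_training_set(complexes, n_pos=200, n_neg=200, seed=2)
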