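import math
import random

import networkx as nx
import pytest

from molsketch import Atom, Bond, Molecule
from molsketch.fixtures import regular_ring


@pytest.fixture
def benzene():
    mol = regular_ring(6)
    for i, b in enumerate(mol.bonds):
        b.order = 2 if i % 2 == 0 else 1
    return mol


@pytest.fixture
def ethane():
    return Molecule([Atom("C", x=0.0, y=0.0), Atom("C", x=1.5, y=0.0)], [Bond(0, 1)])


def random_molecule(seed: int, n_max: int = 12) -> Molecule:
    """A random small sketch: a bonded tree plus occasional extra ring bond.

    Atoms are spread out (no pair closer than 0.5 A) so the structure is a
    valid, non-overlapping sketch.
    """
    rng = random.Random(seed)
    n = rng.randint(1, n_max)
    elements = ["C", "C", "C", "N", "O", "S", "Fe", "Cl"]
    atoms: list[Atom] = []
    while len(atoms) < n:
        x, y = rng.uniform(-6, 6), rng.uniform(-6, 6)
        if all(math.hypot(a.x - x, a.y - y) > 0.5 for a in atoms):
            atoms.append(
                Atom(
                    rng.choice(elements),
                    x=x,
                    y=y,
                    charge=rng.choice([0, 0, 0, 1, -1]),
                    unpaired=rng.choice([0, 0, 0, 1]),
                    isotope=rng.choice([0, 0, 0, 13]),
                    hydrogens=rng.choice([None, None, None, 0, 2]),
                )
            )
    mol = Molecule(atoms)
    for i in range(1, n):
        j = rng.randrange(i)
        mol.add_bond(
            Bond(
                j,
                i,
                order=rng.choice([1, 1, 1, 2, 3]),
                stereo=rng.choice(["none", "none", "none", "inclined", "declined"]),
            )
        )
    if n > 3 and rng.random() < 0.5:
        a, b = rng.sample(range(n), 2)
        if mol.find_bond(a, b) is None:
            mol.add_bond(Bond(a, b))
    return mol


def molecule_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(mol.atoms):
        g.add_node(i, element=a.element, charge=a.charge)
    for b in mol.bonds:
        g.add_edge(b.frm, b.to, order=b.order, stereo=b.stereo)
    return g


def graphs_isomorphic(a: Molecule, b: Molecule) -> bool:
    """Element/charge/order/stereo-labelled graph isomorphism."""
    return nx.is_isomorphic(
        molecule_graph(a),
        molecule_graph(b),
        node_match=lambda x, y: x == y,
        edge_match=lambda x, y: x == y,
    )
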