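"""Built-in template fragments and reference structures.

Ships a minimal template set (plain rings C3-C8, benzene, cyclopentadiene,
naphthalene, acetyl, carboxyl) plus hand-encoded reference connection tables
for the worked drawing examples. All geometry uses the default 1.5 A bond
length with idealized ring coordinates.
"""

from __future__ import annotations

import math

from .grafting import Template
from .structures import DEFAULT_BOND_LENGTH, Atom, Bond, Molecule

__all__ = ["regular_ring", "builtin_templates", "get_template", "generate_fixture"]


def regular_ring(n: int, bond: float = DEFAULT_BOND_LENGTH, element: str = "C") -> Molecule:
    """A regular n-gon of single-bonded atoms with the given bond length.

    The first atom sits at the top of the ring (angle 90 degrees) and the
    ring is traversed clockwise, so the first bond is roughly horizontal.
    """
    if n < 3:
        raise ValueError("a ring needs at least 3 atoms")
    radius = bond / (2.0 * math.sin(math.pi / n))
    atoms = []
    for i in range(n):
        theta = math.radians(90.0 - 360.0 * i / n)
        atoms.append(Atom(element=element, x=radius * math.cos(theta), y=radius * math.sin(theta)))
    bonds = [Bond(i, (i + 1) % n) for i in range(n)]
    return Molecule(atoms, bonds)


def _benzene() -> Molecule:
    mol = regular_ring(6)
    for i, b in enumerate(mol.bonds):
        b.order = 2 if i % 2 == 0 else 1
    return mol


def _cyclopentadiene() -> Molecule:
    mol = regular_ring(5)
    mol.bonds[1].order = 2
    mol.bonds[3].order = 2
    return mol


def _naphthalene() -> Molecule:
    """Two fused hexagons sharing one bond, with a consistent Kekule pattern."""
    left = _benzene()
    # fuse a second ring on the bond between atoms 0 and 1
    a0, a1 = left.atoms[0], left.atoms[1]
    midx, midy = (a0.x + a1.x) / 2.0, (a0.y + a1.y) / 2.0
    cx, cy = left.centroid()
    # reflect the left ring's far atoms through the shared bond's midline
    mol = left.copy()
    new_idx = {}
    for i in (2, 3, 4, 5):
        src = left.atoms[i]
        nx, ny = 2 * midx - src.x, 2 * midy - src.y
        # mirror about the shared bond midpoint gives the fused-ring positions
        new_idx[i] = mol.add_atom(Atom("C", x=nx, y=ny))
    # Kekule form with the shared (ring-fusion) bond double: the pattern a
    # bond-aligned fusion of two alternating benzene rings produces
    ring2 = [0, new_idx[2], new_idx[3], new_idx[4], new_idx[5], 1]
    orders = [1, 2, 1, 2, 1]
    for k in range(5):
        mol.add_bond(Bond(ring2[k], ring2[k + 1], order=orders[k]))
    del cx, cy
    return mol


def _acetyl() -> Molecule:
    """CH3-C(=O)- fragment: carbonyl carbon at the origin."""
    L = DEFAULT_BOND_LENGTH
    atoms = [
        Atom("C", x=0.0, y=0.0),  # carbonyl carbon (attachment point)
        Atom("O", x=L * math.cos(math.radians(90)), y=L * math.sin(math.radians(90))),
        Atom("C", x=L * math.cos(math.radians(210)), y=L * math.sin(math.radians(210))),
    ]
    bonds = [Bond(0, 1, order=2), Bond(0, 2, order=1)]
    return Molecule(atoms, bonds)


def _carboxyl() -> Molecule:
    """-C(=O)OH fragment: acid carbon at the origin."""
    L = DEFAULT_BOND_LENGTH
    atoms = [
        Atom("C", x=0.0, y=0.0),
        Atom("O", x=L * math.cos(math.radians(90)), y=L * math.sin(math.radians(90))),
        Atom("O", x=L * math.cos(math.radians(330)), y=L * math.sin(math.radians(330))),
    ]
    bonds = [Bond(0, 1, order=2), Bond(0, 2, order=1)]
    return Molecule(atoms, bonds)


def builtin_templates() -> dict[str, Template]:
    """The minimal built-in template library, keyed by name."""
    lib = {
        "cyclopropane": Template(regular_ring(3), "cyclopropane"),
        "cyclobutane": Template(regular_ring(4), "cyclobutane"),
        "cyclopentane": Template(regular_ring(5), "cyclopentane"),
        "cyclohexane": Template(regular_ring(6), "cyclohexane"),
        "cycloheptane": Template(regular_ring(7), "cycloheptane"),
        "cyclooctane": Template(regular_ring(8), "cyclooctane"),
        "benzene": Template(_benzene(), "benzene"),
        "cyclopentadiene": Template(_cyclopentadiene(), "cyclopentadiene"),
        "naphthalene": Template(_naphthalene(), "naphthalene"),
        "acetyl": Template(_acetyl(), "acetyl"),
        "carboxyl": Template(_carboxyl(), "carboxyl"),
    }
    return lib


def get_template(name: str) -> Template:
    lib = builtin_templates()
    if name not in lib:
        raise KeyError(f"unknown template {name!r}; available: {sorted(lib)}")
    return lib[name]


# ---------------------------------------------------------------------------
# Reference fixtures (idealized connection tables for the worked examples)


def _graph_fixture(elements: list[str], bonds: list[tuple[int, int, int]],
                   stereo: dict[tuple[int, int], str] | None = None) -> Molecule:
    """Build a reference connection table with placeholder ring coordinates.

    Reference fixtures are compared by graph (elements, bond orders, stereo
    styles), not by coordinates; atoms are laid out on a circle purely so the
    molecule is a valid sketch.
    """
    n = len(elements)
    atoms = []
    for i in range(n):
        theta = 2 * math.pi * i / max(n, 1)
        atoms.append(Atom(elements[i], x=3.0 * math.cos(theta), y=3.0 * math.sin(theta)))
    blist = []
    stereo = stereo or {}
    for a, b, order in bonds:
        blist.append(Bond(a, b, order=order, stereo=stereo.get((a, b), "none")))
    return Molecule(atoms, blist)


def _aspirin() -> Molecule:
    # acetylsalicylic acid: 13 heavy atoms, 13 bonds
    elements = ["C"] * 6 + ["C", "O", "O", "O", "C", "O", "C"]
    bonds = [
        (0, 1, 2), (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 0, 1),  # ring
        (0, 6, 1),   # ring -> carboxyl C
        (6, 7, 2),   # C=O
        (6, 8, 1),   # C-OH
        (1, 9, 1),   # ring -> ester O
        (9, 10, 1),  # O -> acetyl C
        (10, 11, 2),  # C=O
        (10, 12, 1),  # C-CH3
    ]
    return _graph_fixture(elements, bonds)


def _benzene_fixture() -> Molecule:
    return _benzene()


def _ingenol() -> Molecule:
    # Ingenol skeleton as sketched: bicyclo[4.4.1]undecane core (two
    # seven-membered rings sharing the 0-1-2 bridge path), a fused
    # cyclopentene, a fused gem-dimethyl cyclopropane, the bridge ketone,
    # the hydroxymethyl arm, wedged hydroxyl and an explicit hydrogen label
    # at a bridgehead.
    elements = (
        ["C"] * 11        # 0-10: bicyclo[4.4.1] core (1 = one-carbon bridge)
        + ["C", "C", "C"]  # 11-13: cyclopentene extension on bond 4-5
        + ["C"]           # 14: cyclopropane apex on bond 8-9
        + ["O"]           # 15: bridge ketone oxygen
        + ["C"]           # 16: hydroxymethyl carbon on the alkene
        + ["O"]           # 17: inclined hydroxyl
        + ["H"]           # 18: declined explicit hydrogen (bridgehead)
        + ["C", "C"]      # 19-20: gem-dimethyl on the cyclopropane apex
        + ["O"]           # 21: hydroxymethyl oxygen
    )
    bonds = [
        # ring P: 0-1-2-3-4-5-6
        (0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1), (6, 0, 1),
        # ring Q: 0-7-8-9-10-2 (shares the 0-1-2 path with ring P)
        (7, 0, 1), (7, 8, 1), (8, 9, 1), (9, 10, 1), (10, 2, 1),
        # cyclopentene fused on bond 4-5
        (4, 11, 1), (11, 12, 1), (12, 13, 2), (13, 5, 1),
        # cyclopropane fused on bond 8-9
        (8, 14, 1), (14, 9, 1),
        # substituents
        (1, 15, 2),    # bridge ketone
        (12, 16, 1),   # CH2 of the hydroxymethyl
        (3, 17, 1),    # hydroxyl, inclined wedge
        (2, 18, 1),    # explicit H, declined wedge
        (14, 19, 1), (14, 20, 1),  # gem-dimethyl
        (16, 21, 1),   # hydroxymethyl oxygen
    ]
    stereo = {(7, 0): "inclined", (3, 17): "inclined", (2, 18): "declined"}
    return _graph_fixture(elements, bonds, stereo)


def _gold_intermediate() -> Molecule:
    # Carbene-gold carboxylation intermediate as sketched: a three-membered
    # N,N-ring carbene double-bonded to gold, two symmetric N-aryl wings
    # carrying wedge-drawn CH(CH3)2 substituents, and a trans carboxylate
    # arm Au-O-C(=O) capped by a five-membered ring bearing N and O.
    elements = (
        ["Au"]             # 0
        + ["C", "N", "N"]  # 1-3: carbene ring (C bound to Au)
        + ["C"] * 6        # 4-9: first aryl ring (4 = ipso)
        + ["C", "C", "C", "C", "C", "C"]  # 10-15: wing-1 CH x2 + methyls x4
        + ["C"] * 6        # 16-21: second aryl ring (16 = ipso)
        + ["C", "C", "C", "C", "C", "C"]  # 22-27: wing-2 CH x2 + methyls x4
        + ["O"]            # 28: Au-O
        + ["C", "O"]       # 29-30: carboxylate C and =O
        + ["O", "C", "N", "C", "C"]  # 31-35: azole ring (32 = attachment C)
    )
    bonds = [
        (1, 2, 1), (2, 3, 1), (3, 1, 1),  # three-membered ring
        (0, 1, 2),                        # Au=C carbene (scaled long)
        (2, 4, 1),                        # N -> aryl (wing 1)
        # aryl ring 1 (alternating Kekule)
        (4, 5, 2), (5, 6, 1), (6, 7, 2), (7, 8, 1), (8, 9, 2), (9, 4, 1),
        # wing 1: wedge-drawn CH groups and their methyls
        (6, 10, 1), (8, 11, 1),
        (10, 12, 1), (11, 13, 1), (10, 14, 1), (11, 15, 1),
        # aryl ring 2
        (16, 17, 2), (17, 18, 1), (18, 19, 2), (19, 20, 1), (20, 21, 2), (21, 16, 1),
        # wing 2
        (18, 22, 1), (20, 23, 1),
        (22, 24, 1), (23, 25, 1), (22, 26, 1), (23, 27, 1),
        (3, 16, 1),                       # N -> aryl (wing 2)
        # carboxylate arm
        (0, 28, 1), (28, 29, 1), (29, 30, 2),
        # azole ring bridged onto the carboxylate carbon
        (31, 32, 1), (32, 33, 2), (33, 34, 1), (34, 35, 2), (35, 31, 1),
        (29, 32, 1),
    ]
    stereo = {(6, 10): "declined", (8, 11): "inclined",
              (18, 22): "declined", (20, 23): "inclined"}
    return _graph_fixture(elements, bonds, stereo)


_FIXTURES = {
    "aspirin": _aspirin,
    "benzene": _benzene_fixture,
    "ingenol": _ingenol,
    "gold_intermediate": _gold_intermediate,
    "naphthalene": _naphthalene,
    "cyclopentadiene": _cyclopentadiene,
}


def generate_fixture(name: str) -> Molecule:
    """A hand-encoded reference connection table, by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return _FIXTURES[name]()
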