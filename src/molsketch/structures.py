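"""Connection-table data model for 2D molecular sketches.

A sketch is a molecular connection table -- atoms carrying 2D coordinates in
Angstroms plus bonds with an order and an optional wedge/stereo annotation.
Editing primitives act on a :class:`SketchState`, which pairs a molecule with
a *subject*: either a selection set, a current atom, or a current bond.

This module also implements the bookkeeping shared by the grafting and
merging machinery: atom/bond *exoticness* (which of two coincident atoms
survives a merge), overlap merging, and the coordinate-based sketch
equivalence test used to deduplicate graft candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_BOND_LENGTH",
    "OVERLAP_THRESHOLD",
    "Atom",
    "Bond",
    "Molecule",
    "SketchState",
    "subject_atoms",
    "atom_exoticness",
    "bond_exoticness",
    "merge_overlapping",
    "structures_equivalent",
]

#: Default distance between two bonded atoms, in Angstroms. Applies
#: regardless of atom and bond type.
DEFAULT_BOND_LENGTH = 1.5

#: Two atoms closer than this (Angstroms) are considered overlapping.
OVERLAP_THRESHOLD = 0.2

#: Sentinel isotope value meaning natural-abundance mass.
NATURAL_ABUNDANCE = 0

#: Sentinel hydrogen-count value meaning "computed automatically".
AUTO_HYDROGENS = None

BOND_ORDERS = (0, 1, 2, 3, 4)
STEREO_STYLES = ("none", "inclined", "declined", "unknown")


@dataclass
class Atom:
    """One atom of a sketch.

    ``element`` may be a periodic element symbol, an abbreviation, or the
    ``"*"`` guide-atom placeholder used by templates. ``isotope`` is 0 for
    natural abundance, otherwise a positive mass number. ``hydrogens`` is
    ``None`` for the automatic implicit-hydrogen mode, otherwise an explicit
    count >= 0.
    """

    element: str = "C"
    x: float = 0.0
    y: float = 0.0
    charge: int = 0
    unpaired: int = 0
    isotope: int = NATURAL_ABUNDANCE
    hydrogens: int | None = AUTO_HYDROGENS

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element symbol must be a non-empty string")
        if self.unpaired < 0:
            raise ValueError("unpaired electron count must be >= 0")
        if self.hydrogens is not None and self.hydrogens < 0:
            raise ValueError("explicit hydrogen count must be >= 0")

    @property
    def pos(self) -> tuple[float, float]:
        return (self.x, self.y)

    def copy(self) -> "Atom":
        return replace(self)


@dataclass
class Bond:
    """A bond between two atoms, referenced by 0-based atom index.

    The (from, to) direction is significant for wedge bonds: the narrow end
    of an inclined (solid wedge) or declined (hashed wedge) bond emanates
    from ``frm``.
    """

    frm: int
    to: int
    order: int = 1
    stereo: str = "none"

    def __post_init__(self) -> None:
        if self.frm == self.to:
            raise ValueError("self-bonds are not allowed")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unsupported bond order {self.order!r}")
        if self.stereo not in STEREO_STYLES:
            raise ValueError(f"unsupported stereo style {self.stereo!r}")

    def key(self) -> frozenset[int]:
        return frozenset((self.frm, self.to))

    def other(self, idx: int) -> int:
        if idx == self.frm:
            return self.to
        if idx == self.to:
            return self.frm
        raise ValueError(f"atom {idx} is not an endpoint of this bond")

    def copy(self) -> "Bond":
        return replace(self)


class Molecule:
    """An ordered list of atoms plus an ordered list of bonds.

    Atom identifiers are stable integer list indices (0-based). Removing
    atoms renumbers subsequent indices; helpers that delete atoms return or
    apply the corresponding index mapping.
    """

    def __init__(self, atoms: list[Atom] | None = None, bonds: list[Bond] | None = None):
        self.atoms: list[Atom] = list(atoms or [])
        self.bonds: list[Bond] = list(bonds or [])
        self._validate()

    def _validate(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if not (0 <= b.frm < n and 0 <= b.to < n):
                raise ValueError(f"bond ({b.frm},{b.to}) references a missing atom")
            k = b.key()
            if k in seen:
                raise ValueError(f"duplicate bond between atoms {sorted(k)}")
            seen.add(k)

    # -- construction -----------------------------------------------------

    def copy(self) -> "Molecule":
        m = Molecule.__new__(Molecule)
        m.atoms = [a.copy() for a in self.atoms]
        m.bonds = [b.copy() for b in self.bonds]
        return m

    def add_atom(self, atom: Atom) -> int:
        self.atoms.append(atom)
        return len(self.atoms) - 1

    def add_bond(self, bond: Bond) -> int:
        n = len(self.atoms)
        if not (0 <= bond.frm < n and 0 <= bond.to < n):
            raise ValueError("bond endpoint references a missing atom")
        if self.find_bond(bond.frm, bond.to) is not None:
            raise ValueError(f"bond ({bond.frm},{bond.to}) already exists")
        self.bonds.append(bond)
        return len(self.bonds) - 1

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def find_bond(self, a: int, b: int) -> int | None:
        """Index of the bond between atoms ``a`` and ``b``, or None."""
        want = frozenset((a, b))
        for i, bond in enumerate(self.bonds):
            if bond.key() == want:
                return i
        return None

    def neighbours(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.frm == idx:
                out.append(b.to)
            elif b.to == idx:
                out.append(b.frm)
        return out

    def degree(self, idx: int) -> int:
        return len(self.neighbours(idx))

    def bonds_at(self, idx: int) -> list[int]:
        return [i for i, b in enumerate(self.bonds) if idx in (b.frm, b.to)]

    def total_bond_order(self, idx: int) -> int:
        return sum(b.order for b in self.bonds if idx in (b.frm, b.to))

    def distance(self, a: int, b: int) -> float:
        pa, pb = self.atoms[a], self.atoms[b]
        return math.hypot(pa.x - pb.x, pa.y - pb.y)

    def centroid(self) -> tuple[float, float]:
        if not self.atoms:
            return (0.0, 0.0)
        n = len(self.atoms)
        return (sum(a.x for a in self.atoms) / n, sum(a.y for a in self.atoms) / n)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y); zeros for an empty molecule."""
        if not self.atoms:
            return (0.0, 0.0, 0.0, 0.0)
        xs = [a.x for a in self.atoms]
        ys = [a.y for a in self.atoms]
        return (min(xs), min(ys), max(xs), max(ys))

    def connected_component(self, idx: int, skip_bond: int | None = None) -> set[int]:
        """Atom indices reachable from ``idx``; ``skip_bond`` is ignored."""
        adj: dict[int, list[int]] = {}
        for i, b in enumerate(self.bonds):
            if i == skip_bond:
                continue
            adj.setdefault(b.frm, []).append(b.to)
            adj.setdefault(b.to, []).append(b.frm)
        seen = {idx}
        stack = [idx]
        while stack:
            cur = stack.pop()
            for nxt in adj.get(cur, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def ring_bonds(self) -> set[int]:
        """Indices of bonds that are part of a ring (i.e. not bridges)."""
        out = set()
        for i, b in enumerate(self.bonds):
            if b.frm in self.connected_component(b.to, skip_bond=i):
                out.add(i)
        return out

    def is_ring_bond(self, bond_idx: int) -> bool:
        b = self.bonds[bond_idx]
        return b.frm in self.connected_component(b.to, skip_bond=bond_idx)

    # -- mutation ---------------------------------------------------------

    def remove_atoms(self, indices: set[int]) -> dict[int, int]:
        """Delete the given atoms (and incident bonds); return old->new map."""
        keep = [i for i in range(len(self.atoms)) if i not in indices]
        mapping = {old: new for new, old in enumerate(keep)}
        self.atoms = [self.atoms[i] for i in keep]
        self.bonds = [
            replace(b, frm=mapping[b.frm], to=mapping[b.to])
            for b in self.bonds
            if b.frm in mapping and b.to in mapping
        ]
        return mapping

    def remove_bonds(self, indices: set[int]) -> None:
        self.bonds = [b for i, b in enumerate(self.bonds) if i not in indices]

    def translate(self, dx: float, dy: float, atoms: set[int] | None = None) -> None:
        targets = range(len(self.atoms)) if atoms is None else atoms
        for i in targets:
            self.atoms[i].x += dx
            self.atoms[i].y += dy

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Molecule({len(self.atoms)} atoms, {len(self.bonds)} bonds)"


@dataclass
class SketchState:
    """A molecule plus the subject annotation primitives act on.

    At any time there may be a current atom or a current bond, but not both.
    ``current_bond`` is a bond index into ``molecule.bonds``.
    """

    molecule: Molecule = field(default_factory=Molecule)
    current_atom: int | None = None
    current_bond: int | None = None
    selection: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.current_atom is not None and self.current_bond is not None:
            raise ValueError("cannot have both a current atom and a current bond")
        n = len(self.molecule.atoms)
        if self.current_atom is not None and not 0 <= self.current_atom < n:
            raise ValueError("current atom out of range")
        if self.current_bond is not None and not 0 <= self.current_bond < len(self.molecule.bonds):
            raise ValueError("current bond out of range")
        if any(not 0 <= i < n for i in self.selection):
            raise ValueError("selection contains an atom outside the molecule")

    def copy(self) -> "SketchState":
        return SketchState(
            molecule=self.molecule.copy(),
            current_atom=self.current_atom,
            current_bond=self.current_bond,
            selection=set(self.selection),
        )


def subject_atoms(state: SketchState) -> list[int]:
    """Resolve the subject of a primitive to an ordered atom-index list.

    All selected atoms if there are any (ascending index); else the current
    atom; else the two atoms of the current bond in [from, to] order; else
    an empty list.
    """
    if state.selection:
        return sorted(state.selection)
    if state.current_atom is not None:
        return [state.current_atom]
    if state.current_bond is not None:
        b = state.molecule.bonds[state.current_bond]
        return [b.frm, b.to]
    return []


# ---------------------------------------------------------------------------
# Exoticness and merging


def atom_exoticness(atom: Atom) -> int:
    """How non-default an atom is: one point per satisfied condition.

    Conditions: non-carbon element label; non-zero charge; any unpaired
    electrons; non-default isotope; a specific (non-automatic) hydrogen
    count. Range 0..5.
    """
    score = 0
    if atom.element != "C":
        score += 1
    if atom.charge != 0:
        score += 1
    if atom.unpaired > 0:
        score += 1
    if atom.isotope != NATURAL_ABUNDANCE:
        score += 1
    if atom.hydrogens is not None:
        score += 1
    return score


def bond_exoticness(bond: Bond) -> int:
    """One point each for a non-single order and any stereo assignment."""
    score = 0
    if bond.order != 1:
        score += 1
    if bond.stereo != "none":
        score += 1
    return score


def _collapse_duplicate_bonds(mol: Molecule) -> None:
    """Keep the more exotic of duplicate bonds (the first on a draw)."""
    best: dict[frozenset[int], int] = {}
    drop: set[int] = set()
    for i, b in enumerate(mol.bonds):
        k = b.key()
        if k not in best:
            best[k] = i
        elif bond_exoticness(b) > bond_exoticness(mol.bonds[best[k]]):
            drop.add(best[k])
            best[k] = i
        else:
            drop.add(i)
    if drop:
        mol.remove_bonds(drop)


def _merge_atom_pair(mol: Molecule, keep: int, drop: int) -> None:
    """Reassign ``drop``'s bonds to ``keep`` and delete ``drop`` in place.

    Indices of atoms after ``drop`` shift down by one; callers must remap.
    """
    for b in mol.bonds:
        if b.frm == drop:
            b.frm = keep
        if b.to == drop:
            b.to = keep
    # a bond that joined keep and drop becomes a self-bond: remove it
    mol.bonds = [b for b in mol.bonds if b.frm != b.to]
    _collapse_duplicate_bonds(mol)
    mapping = mol.remove_atoms({drop})
    del mapping  # callers use merge_overlapping_tracked for index maps


def merge_overlapping_tracked(
    mol: Molecule,
    group_a: set[int] | None = None,
    group_b: set[int] | None = None,
    threshold: float = OVERLAP_THRESHOLD,
) -> tuple[Molecule, int, dict[int, int]]:
    """Merge overlapping atoms; return (molecule, merge count, index map).

    With both groups given, only cross-partition pairs are examined (the
    template-grafting case: group_a from the input structure, group_b from
    the fragment). With both empty/None, all pairs are examined. Of each
    overlapping pair the more exotic atom is retained -- or the first one
    (the group_a / lower-index atom) on a draw -- and the other atom's bonds
    are reassigned to it, collapsing any duplicate bonds that result.

    The returned map sends input atom indices to output indices; a merged-
    away atom maps to the index of the atom that absorbed it.
    """
    work = mol.copy()
    n0 = len(work.atoms)
    # current position of each original atom (None once absorbed -> alias)
    where: list[int] = list(range(n0))
    partition_a = set(group_a) if group_a else set()
    partition_b = set(group_b) if group_b else set()
    partitioned = bool(partition_a or partition_b)
    if partitioned and partition_a & partition_b:
        raise ValueError("merge partitions must be disjoint")

    merged = 0
    while True:
        pair = None
        live = {}
        for orig, cur in enumerate(where):
            live.setdefault(cur, orig)
        for i in sorted(live.values()):
            for j in sorted(live.values()):
                if j <= i:
                    continue
                if partitioned:
                    cross = (i in partition_a and j in partition_b) or (
                        i in partition_b and j in partition_a
                    )
                    if not cross:
                        continue
                pi, pj = where[i], where[j]
                if math.hypot(
                    work.atoms[pi].x - work.atoms[pj].x,
                    work.atoms[pi].y - work.atoms[pj].y,
                ) < threshold:
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            break
        i, j = pair
        # "first" on a draw: in partitioned mode the input-structure atom,
        # otherwise the lower original index -- both are i by construction
        # (group_a indices precede appended fragment atoms).
        first, second = (i, j)
        if partitioned and i in partition_b:
            first, second = j, i
        ka = work.atoms[where[first]]
        kb = work.atoms[where[second]]
        if atom_exoticness(kb) > atom_exoticness(ka):
            keep_orig, drop_orig = second, first
        else:
            keep_orig, drop_orig = first, second
        keep, drop = where[keep_orig], where[drop_orig]
        _merge_atom_pair(work, keep, drop)
        merged += 1
        for orig in range(n0):
            cur = where[orig]
            if cur == drop:
                where[orig] = keep if keep < drop else keep - 1
            elif cur > drop:
                where[orig] = cur - 1
    return work, merged, {orig: cur for orig, cur in enumerate(where)}


def merge_overlapping(
    mol: Molecule,
    group_a: set[int] | None = None,
    group_b: set[int] | None = None,
    threshold: float = OVERLAP_THRESHOLD,
) -> Molecule:
    """Merge overlapping atoms between two partitions (see Appendix rules).

    Pairwise combinations of cross-partition atoms are examined; of each
    overlapping pair the more exotic atom is retained and the other's bonds
    reassigned to it. With no partitions given, all pairs are examined.
    """
    out, _, _ = merge_overlapping_tracked(mol, group_a, group_b, threshold)
    return out


# ---------------------------------------------------------------------------
# Sketch equivalence


def _atoms_fields_equal(a: Atom, b: Atom) -> bool:
    return (
        a.element == b.element
        and a.charge == b.charge
        and a.unpaired == b.unpaired
        and a.isotope == b.isotope
        and a.hydrogens == b.hydrogens
    )


def structures_equivalent(a: Molecule, b: Molecule, threshold: float = OVERLAP_THRESHOLD) -> bool:
    """Coordinate-level sketch equivalence (not graph isomorphism).

    The two structures are centre-translated onto each other; each atom of
    ``a`` must map uniquely to an atom of ``b`` within ``threshold``
    Angstroms with identical fields, and every bond must have a counterpart
    of equal order and stereo. Wedge bonds match direction-sensitively; for
    other bonds the inverse endpoint mapping is also permitted. Kekule
    resonance forms therefore compare as different species.
    """
    if len(a.atoms) != len(b.atoms) or len(a.bonds) != len(b.bonds):
        return False
    if not a.atoms:
        return True
    ca, cb = a.centroid(), b.centroid()
    pa = [(at.x - ca[0], at.y - ca[1]) for at in a.atoms]
    pb = [(at.x - cb[0], at.y - cb[1]) for at in b.atoms]
    # greedy nearest-neighbour assignment in ascending distance order
    pairs = sorted(
        (math.hypot(pa[i][0] - pb[j][0], pa[i][1] - pb[j][1]), i, j)
        for i in range(len(pa))
        for j in range(len(pb))
    )
    mapping: dict[int, int] = {}
    used_b: set[int] = set()
    for d, i, j in pairs:
        if d >= threshold:
            break
        if i in mapping or j in used_b:
            continue
        mapping[i] = j
        used_b.add(j)
    if len(mapping) != len(a.atoms):
        return False
    for i, j in mapping.items():
        if not _atoms_fields_equal(a.atoms[i], b.atoms[j]):
            return False
    b_bonds: dict[tuple[int, int], Bond] = {(bond.frm, bond.to): bond for bond in b.bonds}
    for bond in a.bonds:
        m1, m2 = mapping[bond.frm], mapping[bond.to]
        cand = b_bonds.get((m1, m2))
        if cand is None and bond.stereo not in ("inclined", "declined"):
            cand = b_bonds.get((m2, m1))
        elif cand is None and bond.stereo in ("inclined", "declined"):
            # a reversed counterpart exists only if it is also non-wedge;
            # wedge bonds are direction sensitive on both sides
            rev = b_bonds.get((m2, m1))
            if rev is not None and rev.stereo not in ("inclined", "declined"):
                cand = rev
        if cand is None or cand.order != bond.order or cand.stereo != bond.stereo:
            return False
    return True
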