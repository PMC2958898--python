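"""Subject-driven editing primitives: atom/bond properties, connection,
deletion, merging and movement.

Every primitive takes a :class:`~molsketch.structures.SketchState` and
returns a new one; the input state is never mutated. The *subject* of each
operation is resolved by :func:`~molsketch.structures.subject_atoms`: the
selection set if non-empty, else the current atom, else the two atoms of the
current bond.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

from .structures import (
    DEFAULT_BOND_LENGTH,
    Atom,
    Bond,
    Molecule,
    SketchState,
    atom_exoticness,
    subject_atoms,
)

__all__ = [
    "add_atom",
    "set_atom_property",
    "set_bond_order",
    "set_stereo_style",
    "connect_atoms",
    "disconnect_atoms",
    "delete",
    "merge_atoms",
    "move_atoms",
    "scale_atoms",
    "scale_bond",
    "flip_atoms",
    "rotate_atoms",
    "MERGE_TOLERANCE",
    "CONNECT_SLACK",
    "NUDGE_SMALL",
    "NUDGE_LARGE",
    "SCALE_GROW",
    "SCALE_SHRINK",
]

log = logging.getLogger(__name__)

#: Merge Atoms proximity tolerance -- significantly shorter than a bond.
MERGE_TOLERANCE = 0.5

#: Connect Atoms joins pairs with |d - 1.5| <= this slack (20% of a bond).
CONNECT_SLACK = 0.3

NUDGE_SMALL = 0.1
NUDGE_LARGE = 0.5
SCALE_GROW = 1.25
SCALE_SHRINK = 0.8

_ATOM_PROPERTIES = ("element", "charge", "unpaired", "hydrogens", "isotope")


def add_atom(state: SketchState, element: str) -> SketchState:
    """Create a new unbonded atom with default properties.

    It is placed along the top and to the right of any existing atoms (one
    default bond length past the right edge, level with the top edge) and
    becomes the current atom.
    """
    out = state.copy()
    mol = out.molecule
    if mol.atoms:
        _, _, max_x, max_y = mol.bounding_box()
        pos = (max_x + DEFAULT_BOND_LENGTH, max_y)
    else:
        pos = (0.0, 0.0)
    idx = mol.add_atom(Atom(element=element, x=pos[0], y=pos[1]))
    out.current_atom = idx
    out.current_bond = None
    return out


def set_atom_property(state: SketchState, prop: str, value) -> SketchState:
    """Set one atom-centred property on every subject atom.

    An element change with an empty subject maps to :func:`add_atom`.
    """
    if prop not in _ATOM_PROPERTIES:
        raise ValueError(f"unknown atom property {prop!r}")
    subject = subject_atoms(state)
    if not subject:
        if prop == "element":
            return add_atom(state, value)
        log.warning("set_atom_property(%s): empty subject, no-op", prop)
        return state.copy()
    if prop in ("unpaired",) and value < 0:
        raise ValueError("unpaired electron count must be >= 0")
    if prop == "hydrogens" and value is not None and value < 0:
        raise ValueError("explicit hydrogen count must be >= 0")
    out = state.copy()
    for idx in subject:
        out.molecule.atoms[idx] = replace(out.molecule.atoms[idx], **{prop: value})
    return out


def set_bond_order(state: SketchState, order: int) -> SketchState:
    """Set the order of every bond between two subject atoms.

    A single-atom subject delegates to New Bond with Order; two unbonded
    subject atoms gain a new bond of the requested order. Bonds whose order
    is changed here lose any stereo style.
    """
    subject = subject_atoms(state)
    if len(subject) == 1:
        from .sketch import new_bond_with_order

        return new_bond_with_order(state, order)
    out = state.copy()
    mol = out.molecule
    if len(subject) == 2 and mol.find_bond(subject[0], subject[1]) is None:
        bidx = mol.add_bond(Bond(subject[0], subject[1], order=order))
        out.current_bond = bidx
        out.current_atom = None
        return out
    sset = set(subject)
    for b in mol.bonds:
        if b.frm in sset and b.to in sset:
            b.order = order
            b.stereo = "none"
    return out


def set_stereo_style(state: SketchState, style: str) -> SketchState:
    """Set the wedge/stereo style of every bond between two subject atoms.

    A single-atom subject delegates to New Bond with Style; two unbonded
    subject atoms gain a new order-1 bond with the style, directed from the
    first subject atom. A bond that already carries the requested wedge style
    has its endpoints swapped instead, inverting the wedge's meaning.
    """
    if style not in ("inclined", "declined", "unknown"):
        raise ValueError(f"unknown stereo style {style!r}")
    subject = subject_atoms(state)
    if len(subject) == 1:
        from .sketch import new_bond_with_style

        return new_bond_with_style(state, style)
    out = state.copy()
    mol = out.molecule
    if len(subject) == 2 and mol.find_bond(subject[0], subject[1]) is None:
        bidx = mol.add_bond(Bond(subject[0], subject[1], order=1, stereo=style))
        out.current_bond = bidx
        out.current_atom = None
        return out
    sset = set(subject)
    for b in mol.bonds:
        if b.frm in sset and b.to in sset:
            if b.stereo == style and style in ("inclined", "declined"):
                b.frm, b.to = b.to, b.frm
            else:
                b.stereo = style
    return out


def connect_atoms(state: SketchState) -> SketchState:
    """Join unbonded subject-atom pairs that sit about a bond length apart.

    Every unbonded pair within ``DEFAULT_BOND_LENGTH +/- CONNECT_SLACK`` gets
    a single bond; if no pair qualifies, only the closest unbonded pair is
    connected.
    """
    subject = subject_atoms(state)
    if len(subject) < 2:
        log.warning("connect_atoms: fewer than two subject atoms, no-op")
        return state.copy()
    out = state.copy()
    mol = out.molecule
    unbonded = [
        (mol.distance(a, b), a, b)
        for i, a in enumerate(subject)
        for b in subject[i + 1 :]
        if mol.find_bond(a, b) is None
    ]
    if not unbonded:
        log.warning("connect_atoms: no unbonded subject pair, no-op")
        return out
    close = [t for t in unbonded if abs(t[0] - DEFAULT_BOND_LENGTH) <= CONNECT_SLACK]
    targets = close if close else [min(unbonded)]
    for _, a, b in targets:
        mol.add_bond(Bond(a, b, order=1))
    return out


def disconnect_atoms(state: SketchState) -> SketchState:
    """Delete every bond whose two atoms are both in the subject."""
    sset = set(subject_atoms(state))
    out = state.copy()
    drop = {
        i
        for i, b in enumerate(out.molecule.bonds)
        if b.frm in sset and b.to in sset
    }
    _drop_bonds(out, drop)
    return out


def delete(state: SketchState, mode: str = "atoms") -> SketchState:
    """Delete subject atoms (with incident bonds), intra-subject bonds, or everything."""
    out = state.copy()
    mol = out.molecule
    if mode == "all":
        return SketchState(molecule=Molecule())
    sset = set(subject_atoms(state))
    if mode == "bonds":
        drop = {i for i, b in enumerate(mol.bonds) if b.frm in sset and b.to in sset}
        _drop_bonds(out, drop)
        return out
    if mode != "atoms":
        raise ValueError(f"unknown delete mode {mode!r}")
    mapping = mol.remove_atoms(sset)
    out.selection = {mapping[i] for i in out.selection if i in mapping}
    if out.current_atom is not None:
        out.current_atom = mapping.get(out.current_atom)
    out.current_bond = None
    return out


def _drop_bonds(state: SketchState, drop: set[int]) -> None:
    if state.current_bond in drop:
        state.current_bond = None
    elif state.current_bond is not None:
        state.current_bond -= sum(1 for i in drop if i < state.current_bond)
    state.molecule.remove_bonds(drop)


def merge_atoms(state: SketchState) -> SketchState:
    """Fuse each subject atom with any atoms within the merge tolerance.

    For each subject atom, all other atoms within ``MERGE_TOLERANCE`` are
    collected; the most exotic atom of the group is retained (the subject
    atom on a draw), the others' bonds are reassigned to it, and it moves to
    the average position of the group.
    """
    subject = subject_atoms(state)
    if not subject:
        log.warning("merge_atoms: empty subject, no-op")
        return state.copy()
    out = state.copy()
    mol = out.molecule
    for s in subject:
        # indices shift as atoms are removed; refuse stale subjects quietly
        if s >= len(mol.atoms):
            continue
        group = [s] + [
            i
            for i in range(len(mol.atoms))
            if i != s and mol.distance(s, i) < MERGE_TOLERANCE
        ]
        if len(group) == 1:
            continue
        keep = max(group, key=lambda i: (atom_exoticness(mol.atoms[i]), i == s))
        ax = sum(mol.atoms[i].x for i in group) / len(group)
        ay = sum(mol.atoms[i].y for i in group) / len(group)
        for other in sorted((i for i in group if i != keep), reverse=True):
            for b in mol.bonds:
                if b.frm == other:
                    b.frm = keep
                if b.to == other:
                    b.to = keep
            mol.bonds = [b for b in mol.bonds if b.frm != b.to]
            _collapse_dups(mol)
            mapping = mol.remove_atoms({other})
            keep = mapping[keep]
        mol.atoms[keep].x = ax
        mol.atoms[keep].y = ay
        out.selection = {i for i in out.selection if i < len(mol.atoms)}
        if out.current_atom is not None and out.current_atom >= len(mol.atoms):
            out.current_atom = None
        out.current_bond = None
    return out


def _collapse_dups(mol: Molecule) -> None:
    from .structures import _collapse_duplicate_bonds

    _collapse_duplicate_bonds(mol)


_DIRECTIONS = {"left": (-1, 0), "right": (1, 0), "up": (0, 1), "down": (0, -1)}


def move_atoms(state: SketchState, direction: str, extent: str) -> SketchState:
    """Translate the subject atoms in one of four directions.

    ``extent``: ``small_nudge`` (0.1 A), ``large_nudge`` (0.5 A), or
    ``furthest`` -- the offset that puts the subject 1 A beyond every
    non-subject atom in that direction.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    subject = subject_atoms(state)
    if not subject:
        raise ValueError("move_atoms requires a non-empty subject")
    dx, dy = _DIRECTIONS[direction]
    out = state.copy()
    mol = out.molecule
    if extent == "small_nudge":
        dist = NUDGE_SMALL
    elif extent == "large_nudge":
        dist = NUDGE_LARGE
    elif extent == "furthest":
        others = [i for i in range(len(mol.atoms)) if i not in set(subject)]
        if not others:
            dist = 0.0
        else:
            axis = (lambda a: a.x) if dx else (lambda a: a.y)
            sign = dx + dy  # +1 for right/up, -1 for left/down
            if sign > 0:
                edge_others = max(axis(mol.atoms[i]) for i in others)
                edge_subject = min(axis(mol.atoms[i]) for i in subject)
                dist = edge_others + 1.0 - edge_subject
            else:
                edge_others = min(axis(mol.atoms[i]) for i in others)
                edge_subject = max(axis(mol.atoms[i]) for i in subject)
                dist = edge_subject - (edge_others - 1.0)
            dist = max(dist, 0.0)
    else:
        raise ValueError(f"unknown move extent {extent!r}")
    mol.translate(dx * dist, dy * dist, set(subject))
    return out


def _subject_centre(state: SketchState) -> tuple[float, float]:
    """Centre for scale/flip/rotate: the current atom/bond centre when there
    is one, else the centroid of the selected atoms."""
    mol = state.molecule
    if state.current_atom is not None:
        a = mol.atoms[state.current_atom]
        return (a.x, a.y)
    if state.current_bond is not None:
        b = mol.bonds[state.current_bond]
        p, q = mol.atoms[b.frm], mol.atoms[b.to]
        return ((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)
    sel = sorted(state.selection)
    if not sel:
        raise ValueError("no subject to derive a centre from")
    return (
        sum(mol.atoms[i].x for i in sel) / len(sel),
        sum(mol.atoms[i].y for i in sel) / len(sel),
    )


def scale_atoms(state: SketchState, mode: str) -> SketchState:
    """Scale the selected atoms about their centre (grow x1.25 / shrink x0.8).

    The centre is the current atom or bond's central position when one
    exists, else the selection centroid. With no selection but a current
    bond, the operation maps to :func:`scale_bond`.
    """
    factor = _scale_factor(mode)
    if not state.selection:
        if state.current_bond is not None:
            return scale_bond(state, mode)
        if state.current_atom is None:
            raise ValueError("scale_atoms requires a subject")
        return state.copy()  # a lone current atom scales about itself
    cx, cy = _subject_centre(state)
    out = state.copy()
    for i in sorted(state.selection):
        a = out.molecule.atoms[i]
        a.x = cx + (a.x - cx) * factor
        a.y = cy + (a.y - cy) * factor
    return out


def _scale_factor(mode: str) -> float:
    if mode == "grow":
        return SCALE_GROW
    if mode == "shrink":
        return SCALE_SHRINK
    raise ValueError(f"unknown scale mode {mode!r}")


def scale_bond(state: SketchState, mode: str) -> SketchState:
    """Lengthen or shorten one bond (grow x1.25 / shrink x0.8).

    For an acyclic bond the side with fewer atoms moves (all of it, rigidly,
    along the bond axis); equal sides split the motion half-and-half. For a
    ring bond only the two bond atoms themselves are extended, half each.
    """
    factor = _scale_factor(mode)
    subject = subject_atoms(state)
    if len(subject) != 2:
        raise ValueError("scale_bond requires a subject of two bonded atoms")
    out = state.copy()
    mol = out.molecule
    bidx = mol.find_bond(subject[0], subject[1])
    if bidx is None:
        raise ValueError("scale_bond subject atoms are not bonded")
    a, b = mol.bonds[bidx].frm, mol.bonds[bidx].to
    pa, pb = mol.atoms[a], mol.atoms[b]
    length = mol.distance(a, b)
    if length < 1e-12:
        return out
    ux, uy = (pb.x - pa.x) / length, (pb.y - pa.y) / length
    delta = length * (factor - 1.0)
    if mol.is_ring_bond(bidx):
        half = delta / 2.0
        pa.x -= ux * half
        pa.y -= uy * half
        pb.x += ux * half
        pb.y += uy * half
        return out
    side_a = mol.connected_component(a, skip_bond=bidx)
    side_b = mol.connected_component(b, skip_bond=bidx)
    if len(side_a) == len(side_b):
        wa, wb = 0.5, 0.5
    elif len(side_a) < len(side_b):
        wa, wb = 1.0, 0.0
    else:
        wa, wb = 0.0, 1.0
    if wa:
        mol.translate(-ux * delta * wa, -uy * delta * wa, side_a)
    if wb:
        mol.translate(ux * delta * wb, uy * delta * wb, side_b)
    return out


def flip_atoms(state: SketchState, axis: str) -> SketchState:
    """Reflect the subject about a horizontal or vertical mirror line.

    A vertical flip negates y about the centre line; a horizontal flip
    negates x. With only a current atom or bond as subject, the whole
    connected component flips; with an empty subject, all atoms flip. Wedge
    styles are left untouched.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"unknown flip axis {axis!r}")
    out = state.copy()
    mol = out.molecule
    if state.selection:
        targets = sorted(state.selection)
        cx, cy = _subject_centre(state)
    elif state.current_atom is not None or state.current_bond is not None:
        cx, cy = _subject_centre(state)
        seed = (
            state.current_atom
            if state.current_atom is not None
            else mol.bonds[state.current_bond].frm
        )
        targets = sorted(mol.connected_component(seed))
    else:
        targets = list(range(len(mol.atoms)))
        if not targets:
            return out
        cx = sum(mol.atoms[i].x for i in targets) / len(targets)
        cy = sum(mol.atoms[i].y for i in targets) / len(targets)
    for i in targets:
        a = mol.atoms[i]
        if axis == "vertical":
            a.y = 2.0 * cy - a.y
        else:
            a.x = 2.0 * cx - a.x
    return out


def rotate_atoms(state: SketchState, increment: float) -> SketchState:
    """Rotate the subject by a discrete increment (degrees, CCW positive).

    The centre is the current atom/bond centre when present, else the
    selection centroid. Special case: with no selection and a current bond
    with exactly one terminal end, the terminal atom orbits the other end.
    """
    out = state.copy()
    mol = out.molecule
    if not state.selection and state.current_bond is not None:
        b = mol.bonds[state.current_bond]
        deg_f, deg_t = mol.degree(b.frm), mol.degree(b.to)
        if (deg_f == 1) != (deg_t == 1):
            terminal, pivot = (b.frm, b.to) if deg_f == 1 else (b.to, b.frm)
            p = mol.atoms[pivot]
            _rotate(mol, [terminal], p.x, p.y, increment)
            return out
    subject = sorted(state.selection) if state.selection else subject_atoms(state)
    if not subject:
        raise ValueError("rotate_atoms requires a subject")
    cx, cy = _subject_centre(state)
    _rotate(mol, subject, cx, cy, increment)
    return out


def _rotate(mol: Molecule, atoms, cx: float, cy: float, degrees: float) -> None:
    rad = math.radians(degrees)
    c, s = math.cos(rad), math.sin(rad)
    for i in atoms:
        a = mol.atoms[i]
        dx, dy = a.x - cx, a.y - cy
        a.x = cx + dx * c - dy * s
        a.y = cy + dx * s + dy * c
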