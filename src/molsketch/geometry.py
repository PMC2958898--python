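"""Geometry perception for sketch primitives.

Seven idealized geometry templates cover the bond-direction patterns that
dominate 2D structure depiction: linear, trigonal, two tetrahedral drawing
variants, square planar and two octahedral drawing variants. Given an atom's
element, its existing bond bearings and the order of a bond about to be
created, this module enumerates which templates are plausible, matches the
existing bearings onto template slots (allowing rotation and mirroring,
within a 2 degree tolerance), and returns the vacant directions as candidate
new-bond angles. When no template fits, the fallback is the set of circular
midpoints between consecutive existing bearings ("median-cut" angles).

The congestion functions quantify crowding as a sum of reciprocal squared
distances with a 0.001 A^2 softening constant; primitives place new content
at the least congested candidate position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .structures import Molecule

__all__ = [
    "ANGLE_TOLERANCE",
    "CONGESTION_EPSILON",
    "GeometryTemplate",
    "GEOMETRY_TEMPLATES",
    "bond_angles_at",
    "point_congestion",
    "total_congestion",
    "enumerate_plausible_geometries",
    "match_template",
    "template_matches",
    "propose_new_bond_angles",
    "median_cut_angles",
    "refit_to_geometry",
    "RefitError",
]

#: Angular tolerance (degrees) for template matching and degeneracy collapse.
ANGLE_TOLERANCE = 2.0

#: Additive softening constant in the congestion denominator (Angstrom^2).
CONGESTION_EPSILON = 0.001


@dataclass(frozen=True)
class GeometryTemplate:
    """A named, ordered set of idealized bond directions (degrees, CCW from +x)."""

    name: str
    angles: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.angles) <= 6:
            raise ValueError("geometry templates have between 2 and 6 slots")
        if list(self.angles) != sorted(self.angles) or any(
            not 0 <= a < 360 for a in self.angles
        ):
            raise ValueError("template angles must be strictly increasing in [0, 360)")

    def mirrored(self) -> tuple[float, ...]:
        return tuple(sorted((360.0 - a) % 360.0 for a in self.angles))


GEOMETRY_TEMPLATES: dict[str, GeometryTemplate] = {
    t.name: t
    for t in (
        GeometryTemplate("linear", (0.0, 180.0)),
        GeometryTemplate("trigonal", (0.0, 120.0, 240.0)),
        GeometryTemplate("tetra1", (0.0, 120.0, 180.0, 240.0)),
        GeometryTemplate("tetra2", (0.0, 60.0, 180.0, 240.0)),
        GeometryTemplate("square_planar", (0.0, 90.0, 180.0, 270.0)),
        GeometryTemplate("octa1", (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)),
        GeometryTemplate("octa2", (0.0, 45.0, 90.0, 180.0, 225.0, 270.0)),
    )
}


def _norm(angle: float) -> float:
    a = angle % 360.0
    return a if a >= 0 else a + 360.0


def _circ_diff(a: float, b: float) -> float:
    """Absolute circular difference between two bearings, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _signed_diff(a: float, b: float) -> float:
    """Signed smallest rotation taking ``b`` to ``a``, in (-180, 180]."""
    d = (a - b) % 360.0
    return d if d <= 180.0 else d - 360.0


# ---------------------------------------------------------------------------
# Bearings and congestion


def bond_angles_at(mol: Molecule, atom: int) -> list[float]:
    """Bearings (degrees, ascending) from ``atom`` to each of its neighbours."""
    a = mol.atoms[atom]
    out = []
    for n in mol.neighbours(atom):
        b = mol.atoms[n]
        out.append(_norm(math.degrees(math.atan2(b.y - a.y, b.x - a.x))))
    return sorted(out)


def point_congestion(mol: Molecule, x: float, y: float) -> float:
    """Crowding at a point: sum over atoms of 1/(d^2 + 0.001)."""
    total = 0.0
    for a in mol.atoms:
        total += 1.0 / ((a.x - x) ** 2 + (a.y - y) ** 2 + CONGESTION_EPSILON)
    return total


def total_congestion(mol: Molecule) -> float:
    """Crowding of a whole sketch: sum over unique atom pairs of 1/(d^2 + 0.001)."""
    total = 0.0
    atoms = mol.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d2 = (atoms[i].x - atoms[j].x) ** 2 + (atoms[i].y - atoms[j].y) ** 2
            total += 1.0 / (d2 + CONGESTION_EPSILON)
    return total


# ---------------------------------------------------------------------------
# Periodic-table block classification

_S_BLOCK = {"H", "He", "Li", "Be", "Na", "Mg", "K", "Ca", "Rb", "Sr", "Cs", "Ba", "Fr", "Ra"}
_P_BLOCK_EARLY = {  # p-block periods 2-4
    "B", "C", "N", "O", "F", "Ne",
    "Al", "Si", "P", "S", "Cl", "Ar",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
}
_P_BLOCK_LATE = {
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
}
_P_BLOCK = _P_BLOCK_EARLY | _P_BLOCK_LATE
_D_BLOCK = {
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "La", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Ac", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds", "Rg", "Cn",
}
_F_BLOCK = {
    "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
    "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm", "Md", "No", "Lr",
}
_ELEMENTS = _S_BLOCK | _P_BLOCK | _D_BLOCK | _F_BLOCK


def _is_element(symbol: str) -> bool:
    return symbol in _ELEMENTS


def _in_sp_block(symbol: str) -> bool:
    return symbol in _S_BLOCK or symbol in _P_BLOCK


def enumerate_plausible_geometries(
    mol: Molecule, atom: int, new_order: int
) -> list[GeometryTemplate]:
    """Plausible geometry templates for adding a bond of ``new_order`` at ``atom``.

    The decision list considers the element, the existing bond orders and the
    new bond's order. Terminal carbon/nitrogen heading for an alkyne- or
    allene-like pattern is linear; terminal d/f-block metals get the
    octahedral drawing variants; ordinary terminal organics are trigonal.
    Divalent atoms whose two bonds are already collinear extend to square
    planar (s/p-block) or octahedral (otherwise). Everything else falls to a
    periodic-block table. The rules are exhaustive: the list is never empty.
    """
    g = GEOMETRY_TEMPLATES
    element = mol.atoms[atom].element
    orders = [mol.bonds[i].order for i in mol.bonds_at(atom)]
    degree = len(orders)

    if degree == 1:
        future = sorted((orders[0], new_order))
        if element in ("C", "N") and future in ([1, 3], [2, 2]):
            return [g["linear"]]
        if _is_element(element) and not _in_sp_block(element):
            return [g["octa1"], g["octa2"]]
        if element in ("C", "N", "O"):
            return [g["trigonal"]]
        return [g["trigonal"], g["linear"]]

    if degree == 2:
        bearings = bond_angles_at(mol, atom)
        if abs(_circ_diff(bearings[0], bearings[1]) - 180.0) <= ANGLE_TOLERANCE:
            if _in_sp_block(element):
                return [g["square_planar"]]
            if _is_element(element):
                return [g["octa1"], g["octa2"]]

    if not _is_element(element):
        return [g["trigonal"], g["square_planar"]]
    if element in _S_BLOCK:
        return [g["trigonal"], g["square_planar"], g["octa1"], g["octa2"]]
    if element == "C":
        if all(o == 1 for o in orders) and new_order == 1:
            return [g["trigonal"], g["square_planar"], g["tetra1"], g["tetra2"]]
        return [g["trigonal"]]
    if element in _P_BLOCK_EARLY:
        return [g["trigonal"], g["tetra1"], g["tetra2"], g["square_planar"]]
    if element in _P_BLOCK_LATE:
        return [
            g["linear"], g["trigonal"], g["tetra1"], g["tetra2"],
            g["square_planar"], g["octa1"], g["octa2"],
        ]
    return [g["octa1"], g["octa2"]]


# ---------------------------------------------------------------------------
# Template matching


@dataclass(frozen=True)
class TemplateMatch:
    """One way of superimposing existing bearings onto template slots."""

    rotation: float
    mirrored: bool
    assignment: tuple[int, ...]  # slot index for each existing bearing
    vacancies: tuple[float, ...]  # bearings of unoccupied slots, ascending


def template_matches(
    existing: Sequence[float],
    template: GeometryTemplate,
    tolerance: float = ANGLE_TOLERANCE,
    mirror: bool = True,
) -> Iterator[TemplateMatch]:
    """Yield every distinct superposition of ``existing`` onto the template.

    Rotations are seeded at each (existing bearing, slot) pair and refined to
    the mean angular offset of the greedy assignment; a superposition is a
    match when every existing bearing lands on a distinct slot within
    ``tolerance`` degrees. The mirror image of the template is also tried.
    """
    existing = [_norm(a) for a in existing]
    variants = [(False, template.angles)]
    if mirror:
        mirrored = template.mirrored()
        if mirrored != template.angles:
            variants.append((True, mirrored))
    seen: set[tuple[bool, tuple[int, ...]]] = set()
    for mirrored_flag, slots in variants:
        if len(existing) > len(slots):
            continue
        if not existing:
            yield TemplateMatch(0.0, mirrored_flag, (), tuple(slots))
            continue
        for e_seed in existing:
            for s_seed in slots:
                rotation = e_seed - s_seed
                result = _assign(existing, slots, rotation, tolerance)
                if result is None:
                    continue
                assignment, refined = result
                key = (mirrored_flag, assignment)
                if key in seen:
                    continue
                seen.add(key)
                vac = tuple(
                    sorted(
                        _norm(slots[i] + refined)
                        for i in range(len(slots))
                        if i not in assignment
                    )
                )
                yield TemplateMatch(_norm(refined), mirrored_flag, assignment, vac)


def _assign(
    existing: list[float], slots: tuple[float, ...], rotation: float, tolerance: float
) -> tuple[tuple[int, ...], float] | None:
    """Greedy distinct-slot assignment; returns (assignment, refined rotation)."""

    def attempt(rot: float, tol: float) -> tuple[int, ...] | None:
        rotated = [_norm(s + rot) for s in slots]
        cand = sorted(
            (_circ_diff(e, r), ei, si)
            for ei, e in enumerate(existing)
            for si, r in enumerate(rotated)
        )
        out: dict[int, int] = {}
        used: set[int] = set()
        for dev, ei, si in cand:
            if dev > tol:
                break
            if ei in out or si in used:
                continue
            out[ei] = si
            used.add(si)
        if len(out) != len(existing):
            return None
        return tuple(out[i] for i in range(len(existing)))

    rough = attempt(rotation, 2.0 * tolerance + 1e-9)
    if rough is None:
        return None
    # refine the rotation to the mean signed offset of the rough assignment
    offsets = [
        _signed_diff(existing[i], _norm(slots[rough[i]] + rotation))
        for i in range(len(existing))
    ]
    refined = rotation + sum(offsets) / len(offsets)
    final = attempt(refined, tolerance)
    if final is None:
        return None
    return final, refined


def match_template(
    existing: Sequence[float],
    template: GeometryTemplate,
    tolerance: float = ANGLE_TOLERANCE,
    mirror: bool = True,
) -> list[float]:
    """Vacant bond directions implied by matching ``existing`` onto ``template``.

    All nondegenerate vacancies across all distinct superpositions (rotations
    and the mirror image) are pooled; vacancies within ``tolerance`` of each
    other or of an existing bearing are collapsed. An empty list means no
    match (or a full-occupancy match with nothing vacant).
    """
    vacancies: list[float] = []
    for m in template_matches(existing, template, tolerance, mirror):
        for v in m.vacancies:
            if any(_circ_diff(v, e) <= tolerance for e in existing):
                continue
            if any(_circ_diff(v, w) <= tolerance for w in vacancies):
                continue
            vacancies.append(v)
    return sorted(vacancies)


def median_cut_angles(existing: Sequence[float]) -> list[float]:
    """Circular midpoints between consecutive sorted bearings (with wrap)."""
    bearings = sorted(_norm(a) for a in existing)
    if not bearings:
        return []
    if len(bearings) == 1:
        return [_norm(bearings[0] + 180.0)]
    out = []
    for i, a in enumerate(bearings):
        b = bearings[(i + 1) % len(bearings)]
        gap = (b - a) % 360.0
        if gap == 0.0 and len(bearings) > 1:
            gap = 360.0
        out.append(_norm(a + gap / 2.0))
    return sorted(out)


def propose_new_bond_angles(mol: Molecule, atom: int, new_order: int = 1) -> list[float]:
    """Candidate bearings for a new bond of ``new_order`` at ``atom``.

    An isolated atom offers the four axis directions. Otherwise the first
    plausible geometry template that matches the existing bearings supplies
    its vacant directions; if none match (irregular geometry or full
    valence), the median-cut angles are returned.
    """
    bearings = bond_angles_at(mol, atom)
    if not bearings:
        return [0.0, 90.0, 180.0, 270.0]
    for template in enumerate_plausible_geometries(mol, atom, new_order):
        vac = match_template(bearings, template)
        if vac:
            return vac
    return median_cut_angles(bearings)


# ---------------------------------------------------------------------------
# Geometry refitting


class RefitError(ValueError):
    """Raised when an atom cannot be refitted to the requested geometry."""


def refit_to_geometry(
    mol: Molecule, atom: int, template: GeometryTemplate
) -> Molecule:
    """Rotate the bonds at ``atom`` so they comply with ``template``.

    If the existing bearings already match the template (with any number of
    vacancies) the input is returned unchanged. Otherwise every pairwise
    (existing bond, template slot) seed rotation -- and the mirror image of
    the template -- is tried: remaining bonds snap to the nearest distinct
    slots, assignments that would move a ring bond are disallowed, and the
    assignment with the smallest overall angular displacement wins (ties
    prefer the unmirrored template, then the lowest seed slot index). Moved
    neighbours carry their whole acyclic substituent branch rigidly.

    Raises :class:`RefitError` when every assignment requires moving a ring
    bond or the atom has more neighbours than the template has slots.
    """
    neighbours = mol.neighbours(atom)
    if not neighbours:
        raise RefitError("cannot refit an isolated atom")
    if len(neighbours) > len(template.angles):
        raise RefitError("atom has more bonds than the requested geometry has slots")
    centre = mol.atoms[atom]
    bearings = [
        _norm(math.degrees(math.atan2(mol.atoms[n].y - centre.y, mol.atoms[n].x - centre.x)))
        for n in neighbours
    ]
    if any(True for _ in template_matches(bearings, template)):
        return mol  # already compliant

    ring = {
        n
        for n in neighbours
        if mol.is_ring_bond(mol.find_bond(atom, n))
    }

    best: tuple[float, int, int, int] | None = None  # (displacement, mirrored, seed_slot, seed_e)
    best_targets: list[float] | None = None
    variants = [(0, template.angles)]
    mirrored = template.mirrored()
    if mirrored != template.angles:
        variants.append((1, mirrored))
    for mflag, slots in variants:
        for ei, e_bearing in enumerate(bearings):
            for sj, slot in enumerate(slots):
                rotation = e_bearing - slot
                rotated = [_norm(s + rotation) for s in slots]
                cand = sorted(
                    (_circ_diff(b, r), bi, si)
                    for bi, b in enumerate(bearings)
                    for si, r in enumerate(rotated)
                )
                assign: dict[int, int] = {}
                used: set[int] = set()
                for dev, bi, si in cand:
                    if bi in assign or si in used:
                        continue
                    assign[bi] = si
                    used.add(si)
                if len(assign) != len(bearings):
                    continue
                deltas = [
                    _signed_diff(rotated[assign[bi]], bearings[bi])
                    for bi in range(len(bearings))
                ]
                if any(
                    abs(deltas[bi]) > ANGLE_TOLERANCE and neighbours[bi] in ring
                    for bi in range(len(bearings))
                ):
                    continue
                displacement = sum(abs(d) for d in deltas)
                # round so float noise cannot invert the documented tie-break
                key = (round(displacement, 6), mflag, sj, ei)
                if best is None or key < best:
                    best = key
                    best_targets = [rotated[assign[bi]] for bi in range(len(bearings))]
    if best is None or best_targets is None:
        raise RefitError("every refit assignment requires moving a ring bond")

    out = mol.copy()
    for bi, n in enumerate(neighbours):
        if n in ring:
            continue
        delta = _signed_diff(best_targets[bi], bearings[bi])
        if abs(delta) < 1e-9:
            continue
        branch = out.connected_component(n, skip_bond=out.find_bond(atom, n))
        branch.discard(atom)
        _rotate_atoms_about(out, branch, centre.x, centre.y, delta)
    return out


def _rotate_atoms_about(
    mol: Molecule, atoms: set[int], cx: float, cy: float, degrees: float
) -> None:
    rad = math.radians(degrees)
    c, s = math.cos(rad), math.sin(rad)
    for i in atoms:
        a = mol.atoms[i]
        dx, dy = a.x - cx, a.y - cy
        a.x = cx + dx * c - dy * s
        a.y = cy + dx * s + dy * c
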