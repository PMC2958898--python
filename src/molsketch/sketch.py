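"""Geometry-aware structure growth primitives.

These primitives create or rearrange bonds without any pointer input: the
engine proposes candidate directions from the geometry-template machinery
and resolves degeneracy with the congestion score, always extending new
bonds to the default 1.5 A length.
"""

from __future__ import annotations

import logging
import math

from .geometry import (
    ANGLE_TOLERANCE,
    GeometryTemplate,
    GEOMETRY_TEMPLATES,
    bond_angles_at,
    enumerate_plausible_geometries,
    match_template,
    point_congestion,
    propose_new_bond_angles,
    refit_to_geometry,
    RefitError,
)
from .structures import (
    DEFAULT_BOND_LENGTH,
    Atom,
    Bond,
    SketchState,
    subject_atoms,
)

__all__ = [
    "new_bond_with_order",
    "new_bond_with_style",
    "new_bond_with_geometry",
    "set_geometry",
    "switch_geometry",
]

log = logging.getLogger(__name__)


def _resolve_template(t: GeometryTemplate | str) -> GeometryTemplate:
    if isinstance(t, GeometryTemplate):
        return t
    return GEOMETRY_TEMPLATES[t]


def _least_congested(state: SketchState, atom: int, angles: list[float]) -> float:
    """The candidate angle whose implied atom position is least congested.

    Candidate positions sit one default bond length from ``atom``. Ties break
    toward the smallest angle (candidates are scanned in ascending order with
    a strict improvement test).
    """
    mol = state.molecule
    a = mol.atoms[atom]
    best_angle = None
    best_score = math.inf
    for angle in sorted(angles):
        x = a.x + DEFAULT_BOND_LENGTH * math.cos(math.radians(angle))
        y = a.y + DEFAULT_BOND_LENGTH * math.sin(math.radians(angle))
        score = point_congestion(mol, x, y)
        if score < best_score - 1e-12:
            best_score = score
            best_angle = angle
    return best_angle


def _place_new_atom(
    state: SketchState, atom: int, angle: float, order: int, stereo: str = "none"
) -> SketchState:
    out = state.copy()
    mol = out.molecule
    a = mol.atoms[atom]
    x = a.x + DEFAULT_BOND_LENGTH * math.cos(math.radians(angle))
    y = a.y + DEFAULT_BOND_LENGTH * math.sin(math.radians(angle))
    new_idx = mol.add_atom(Atom(element="C", x=x, y=y))
    mol.add_bond(Bond(frm=atom, to=new_idx, order=order, stereo=stereo))
    out.current_atom = new_idx
    out.current_bond = None
    out.selection = set()
    return out


def new_bond_with_order(state: SketchState, order: int = 1) -> SketchState:
    """Attach a new neutral carbon to each subject atom.

    Candidate directions come from the geometry-template inference for the
    requested bond order; the least congested candidate position wins. With
    several subject atoms each receives one new bond in turn (ascending
    index, against the evolving sketch); the last new atom becomes current.
    """
    subject = subject_atoms(state)
    if not subject:
        log.warning("new_bond_with_order: empty subject, no-op")
        return state.copy()
    out = state
    for atom in subject:
        angles = propose_new_bond_angles(out.molecule, atom, order)
        angle = _least_congested(out, atom, angles)
        out = _place_new_atom(out, atom, angle, order)
    return out


def new_bond_with_style(state: SketchState, style: str) -> SketchState:
    """Attach a new carbon by an order-1 bond with the given stereo style.

    Positioning is identical to :func:`new_bond_with_order` at order 1; the
    wedge emanates from the subject atom (it is the bond's *from* end).
    """
    subject = subject_atoms(state)
    if not subject:
        log.warning("new_bond_with_style: empty subject, no-op")
        return state.copy()
    out = state
    for atom in subject:
        angles = propose_new_bond_angles(out.molecule, atom, 1)
        angle = _least_congested(out, atom, angles)
        out = _place_new_atom(out, atom, angle, 1, stereo=style)
    return out


def new_bond_with_geometry(state: SketchState, template: GeometryTemplate | str) -> SketchState:
    """Attach a new carbon at a vacancy of the requested geometry.

    If the current bearings about the subject atom match the template (with
    at least one slot vacant), all implied vacancies are scored by congestion
    and the least congested receives the new atom; otherwise the operation
    maps to :func:`set_geometry`.
    """
    template = _resolve_template(template)
    subject = subject_atoms(state)
    if not subject:
        log.warning("new_bond_with_geometry: empty subject, no-op")
        return state.copy()
    out = state
    for atom in subject:
        bearings = bond_angles_at(out.molecule, atom)
        vacancies = match_template(bearings, template)
        if not vacancies:
            out = set_geometry(
                SketchState(molecule=out.molecule, current_atom=atom), template
            )
            out = SketchState(
                molecule=out.molecule,
                current_atom=state.current_atom,
                current_bond=state.current_bond,
                selection=set(state.selection),
            )
            continue
        angle = _least_congested(out, atom, vacancies)
        out = _place_new_atom(out, atom, angle, 1)
    return out


def set_geometry(state: SketchState, template: GeometryTemplate | str) -> SketchState:
    """Refit the bonds about each subject atom to the requested geometry.

    Atoms whose bearings already match the template are left untouched;
    atoms that cannot be refitted (every assignment would move a ring bond)
    are skipped. If no subject atom could be processed at all the state is
    returned unchanged with a warning.
    """
    template = _resolve_template(template)
    subject = subject_atoms(state)
    if not subject:
        log.warning("set_geometry: empty subject, no-op")
        return state.copy()
    out = state.copy()
    touched = False
    for atom in subject:
        try:
            out.molecule = refit_to_geometry(out.molecule, atom, template)
            touched = True
        except RefitError:
            continue
    if not touched:
        log.warning("set_geometry: no subject atom could be refitted")
    return out


def switch_geometry(state: SketchState) -> SketchState:
    """Rotate a terminal bond to the next vacancy of its perceived geometry.

    The subject must be a bond with exactly one terminal end. The geometry of
    the non-terminal end is estimated as if the bond were absent; vacancies
    that differ from the original bearing are viable, and the terminal atom
    rotates to the nearest one in the anti-clockwise direction (so repeated
    use cycles through all positions). If no geometry matches, or none of its
    vacancies differ from the original bearing, nothing happens.
    """
    if state.current_bond is None or state.selection:
        log.warning("switch_geometry: subject must be a current bond, no-op")
        return state.copy()
    mol = state.molecule
    bond = mol.bonds[state.current_bond]
    deg_f, deg_t = mol.degree(bond.frm), mol.degree(bond.to)
    if (deg_f == 1) == (deg_t == 1):
        log.warning("switch_geometry: bond must have exactly one terminal end, no-op")
        return state.copy()
    terminal, centre = (bond.frm, bond.to) if deg_f == 1 else (bond.to, bond.frm)

    # examine the centre atom as if the switched bond were not present
    probe = mol.copy()
    probe.remove_bonds({state.current_bond})
    bearings = bond_angles_at(probe, centre)
    c = mol.atoms[centre]
    t = mol.atoms[terminal]
    original = math.degrees(math.atan2(t.y - c.y, t.x - c.x)) % 360.0
    length = mol.distance(centre, terminal)

    viable: list[float] = []
    for template in enumerate_plausible_geometries(probe, centre, bond.order):
        vacancies = match_template(bearings, template)
        if not vacancies:
            continue
        viable = [v for v in vacancies if _circ_diff(v, original) > ANGLE_TOLERANCE]
        break
    if not viable:
        log.warning("switch_geometry: no alternate position available, no-op")
        return state.copy()
    chosen = min(viable, key=lambda v: (v - original) % 360.0)
    out = state.copy()
    ta = out.molecule.atoms[terminal]
    ta.x = c.x + length * math.cos(math.radians(chosen))
    ta.y = c.y + length * math.sin(math.radians(chosen))
    return out


def _circ_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)
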