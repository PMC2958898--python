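"""Template grafting: fusing predrawn fragments onto an existing sketch.

A :class:`Template` is a molecule fragment that may carry *guide atoms* --
``"*"`` placeholders marking the intended attachment point, direction and
bond distance. Grafting enumerates every plausible way of appending the
fragment to the sketch for the current subject (atom overlay, bond
alignment, bridging bond, guide mapping), merges overlapping atoms, scores
each candidate (congestion plus discrete penalties) and returns the ranked,
deduplicated list. The clipboard of a sketching UI is just a single
temporary template flowing through the same path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

from .geometry import propose_new_bond_angles, total_congestion
from .structures import (
    DEFAULT_BOND_LENGTH,
    OVERLAP_THRESHOLD,
    Atom,
    Bond,
    Molecule,
    SketchState,
    atom_exoticness,
    merge_overlapping_tracked,
    structures_equivalent,
    subject_atoms,
)

__all__ = [
    "Template",
    "GraftResult",
    "create_template",
    "graft_no_connection",
    "graft_atom_connection",
    "graft_bond_connection",
    "graft_multi_connection",
    "graft_with_guides",
    "score_graft_result",
    "rank_and_filter",
    "graft",
]

log = logging.getLogger(__name__)

GUIDE_SYMBOL = "*"

#: Scoring constants: per-merge penalty, irregular-angle penalty,
#: hypervalent C/N penalty, per-guide reward, and the exclusion threshold.
MERGE_PENALTY = 1.0
ANGLE_PENALTY = 50.0
HYPERVALENT_PENALTY = 1000.0
GUIDE_REWARD = 1.0
EXCLUSION_THRESHOLD = 1000.0
ANGLE_PENALTY_TOLERANCE = 5.0


@dataclass
class Template:
    """A molecule fragment, possibly carrying ``"*"`` guide placeholders."""

    fragment: Molecule
    name: str = ""

    @property
    def guide_atoms(self) -> list[int]:
        return [i for i, a in enumerate(self.fragment.atoms) if a.element == GUIDE_SYMBOL]

    def stripped(self) -> Molecule:
        """The fragment with guide atoms (and their bonds) removed."""
        out = self.fragment.copy()
        out.remove_atoms(set(self.guide_atoms))
        return out


@dataclass
class GraftResult:
    """One candidate fused structure with its score and provenance."""

    molecule: Molecule
    score: float = 0.0
    merged_count: int = 0
    guide_count: int = 0
    mode: str = ""
    new_bonds: frozenset[frozenset[int]] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Fragment transforms


def _mirrored(frag: Molecule) -> Molecule:
    """Mirror image (x -> -x); inclined and declined wedges interchange."""
    out = frag.copy()
    for a in out.atoms:
        a.x = -a.x
    swap = {"inclined": "declined", "declined": "inclined"}
    for b in out.bonds:
        b.stereo = swap.get(b.stereo, b.stereo)
    return out


def _transformed(frag: Molecule, rotation: float, pivot: tuple[float, float],
                 translation: tuple[float, float] = (0.0, 0.0)) -> Molecule:
    out = frag.copy()
    rad = math.radians(rotation)
    c, s = math.cos(rad), math.sin(rad)
    px, py = pivot
    tx, ty = translation
    for a in out.atoms:
        dx, dy = a.x - px, a.y - py
        a.x = px + dx * c - dy * s + tx
        a.y = py + dx * s + dy * c + ty
    return out


def _bearing(frag: Molecule, src: int, dst: int) -> float:
    a, b = frag.atoms[src], frag.atoms[dst]
    return math.degrees(math.atan2(b.y - a.y, b.x - a.x)) % 360.0


# ---------------------------------------------------------------------------
# Composition bookkeeping


class _Composition:
    """Base structure + placed fragment, with merge/index bookkeeping."""

    def __init__(self, base: Molecule, frag: Molecule):
        self.mol = base.copy()
        self.base_n = len(base.atoms)
        offset = self.base_n
        for a in frag.atoms:
            self.mol.atoms.append(a.copy())
        for b in frag.bonds:
            self.mol.bonds.append(replace(b, frm=b.frm + offset, to=b.to + offset))
        self.where: list[int] = list(range(len(self.mol.atoms)))
        self.merged = 0
        self._pre_bonds = [(b.frm, b.to) for b in base.bonds]

    def cur(self, orig: int) -> int:
        return self.where[orig]

    def frag_index(self, frag_orig: int) -> int:
        return self.cur(self.base_n + frag_orig)

    def add_bond(self, a_orig: int, b_orig: int, order: int = 1, stereo: str = "none") -> None:
        a, b = self.cur(a_orig), self.cur(b_orig)
        if a != b and self.mol.find_bond(a, b) is None:
            self.mol.bonds.append(Bond(a, b, order=order, stereo=stereo))

    def force_merge(self, keep_orig: int, drop_orig: int, coords_from: int) -> None:
        """Merge two atoms regardless of distance.

        Fields come from the more exotic atom (the ``keep_orig`` atom on a
        draw); coordinates always come from ``coords_from``.
        """
        keep, drop = self.cur(keep_orig), self.cur(drop_orig)
        if keep == drop:
            return
        ka, da = self.mol.atoms[keep], self.mol.atoms[drop]
        winner = da if atom_exoticness(da) > atom_exoticness(ka) else ka
        coords = self.mol.atoms[self.cur(coords_from)]
        self.mol.atoms[keep] = replace(winner, x=coords.x, y=coords.y)
        for b in self.mol.bonds:
            if b.frm == drop:
                b.frm = keep
            if b.to == drop:
                b.to = keep
        self.mol.bonds = [b for b in self.mol.bonds if b.frm != b.to]
        from .structures import _collapse_duplicate_bonds

        _collapse_duplicate_bonds(self.mol)
        mapping = self.mol.remove_atoms({drop})
        new_keep = mapping[keep]
        self.where = [
            new_keep if w == drop else mapping.get(w, w) for w in self.where
        ]
        self.merged += 1

    def finish(self, threshold: float = OVERLAP_THRESHOLD) -> tuple[Molecule, int, frozenset]:
        """Overlap-merge cross-partition atoms; return (mol, merges, new bonds)."""
        group_a = {self.cur(i) for i in range(self.base_n)}
        group_b = {
            self.cur(i) for i in range(self.base_n, len(self.where))
        } - group_a
        mol, n, mapping = merge_overlapping_tracked(self.mol, group_a, group_b, threshold)
        self.merged += n
        pre = {
            frozenset((mapping[self.cur(a)], mapping[self.cur(b)]))
            for a, b in self._pre_bonds
        }
        new_bonds = frozenset(
            frozenset((b.frm, b.to)) for b in mol.bonds if frozenset((b.frm, b.to)) not in pre
        )
        return mol, self.merged, new_bonds


def _compose(base: Molecule, frag: Molecule, mode: str, guide_count: int = 0,
             bridges: list[tuple[int, int, int, str]] | None = None,
             forced: list[tuple[int, int, int]] | None = None) -> GraftResult | None:
    """Combine base + placed fragment into a merged, scored GraftResult.

    ``bridges``: (base atom, fragment atom, order, stereo) bonds to add.
    ``forced``: (base atom, fragment atom, coords_from-side flag) pairs to
    merge unconditionally; flag 0 keeps base coordinates, 1 fragment's.
    """
    comp = _Composition(base, frag)
    for a, f, order, stereo in bridges or ():
        comp.add_bond(a, comp_base_frag(comp, f), order, stereo)
    for a, f, coords_side in forced or ():
        fo = comp.base_n + f
        comp.force_merge(a, fo, fo if coords_side else a)
    try:
        mol, merged, new_bonds = comp.finish()
    except ValueError:
        return None
    score = score_graft_result(mol, merged, guide_count, new_bonds)
    return GraftResult(mol, score, merged, guide_count, mode, new_bonds)


def comp_base_frag(comp: _Composition, frag_orig: int) -> int:
    return comp.base_n + frag_orig


# ---------------------------------------------------------------------------
# Template creation


def create_template(state: SketchState) -> Template:
    """Excise the subject atoms as a template fragment.

    Whole connected components copy verbatim; a partial selection also pulls
    in the immediately connected boundary atoms, converted into ``"*"``
    guide placeholders.
    """
    subject = subject_atoms(state)
    if not subject:
        raise ValueError("create_template requires a non-empty subject")
    mol = state.molecule
    sset = set(subject)
    boundary = sorted(
        {
            n
            for s in subject
            for n in mol.neighbours(s)
            if n not in sset
        }
    )
    order = sorted(sset) + boundary
    remap = {old: new for new, old in enumerate(order)}
    atoms = []
    for old in order:
        src = mol.atoms[old]
        if old in sset:
            atoms.append(src.copy())
        else:
            atoms.append(Atom(element=GUIDE_SYMBOL, x=src.x, y=src.y))
    bonds = []
    for b in mol.bonds:
        if b.frm in sset and b.to in sset:
            bonds.append(replace(b, frm=remap[b.frm], to=remap[b.to]))
        elif (b.frm in sset and b.to in remap) or (b.to in sset and b.frm in remap):
            bonds.append(replace(b, frm=remap[b.frm], to=remap[b.to]))
    return Template(Molecule(atoms, bonds))


# ---------------------------------------------------------------------------
# Grafting modes


def _variants(frag: Molecule) -> list[Molecule]:
    """The fragment and, when distinct, its mirror image."""
    mirror = _mirrored(frag)
    return [frag, mirror]


def graft_no_connection(base: Molecule, template: Template) -> list[GraftResult]:
    """Place the fragment clear of the existing content, at every rotation
    in multiples of 30 and 45 degrees (16 before deduplication)."""
    frag0 = template.stripped()
    if not frag0.atoms:
        return []
    rotations = sorted({r % 360 for r in range(0, 360, 30)} | {r % 360 for r in range(0, 360, 45)})
    results = []
    for rot in rotations:
        frag = _transformed(frag0, rot, frag0.centroid())
        fx0, fy0, fx1, fy1 = frag.bounding_box()
        if base.atoms:
            bx0, by0, bx1, by1 = base.bounding_box()
            dx = (bx1 + DEFAULT_BOND_LENGTH) - fx0
            dy = (by0 + by1) / 2.0 - (fy0 + fy1) / 2.0
        else:
            cx, cy = frag.centroid()
            dx, dy = -cx, -cy
        frag.translate(dx, dy)
        res = _compose(base, frag, "no_connection")
        if res is not None:
            results.append(res)
    return results


def graft_atom_connection(base: Molecule, subject: int, template: Template) -> list[GraftResult]:
    """Fuse the fragment to one subject atom, by overlay or by bridge.

    Direct connection superimposes a fragment atom N on the subject and
    rotates by theta1 - theta2 + 180 over all candidate-angle pairs; bridge
    connection places N one bond length out along theta1 and joins it to the
    subject with a single bond. Both repeat with the mirror image.
    """
    frag0 = template.stripped()
    if not frag0.atoms:
        return []
    theta1s = propose_new_bond_angles(base, subject, 1)
    spos = (base.atoms[subject].x, base.atoms[subject].y)
    results = []
    for frag in _variants(frag0):
        for n in range(len(frag.atoms)):
            theta2s = propose_new_bond_angles(frag, n, 1)
            npos = (frag.atoms[n].x, frag.atoms[n].y)
            for t1 in theta1s:
                for t2 in theta2s:
                    rot = t1 - t2 + 180.0
                    placed = _transformed(
                        frag, rot, npos, (spos[0] - npos[0], spos[1] - npos[1])
                    )
                    res = _compose(base, placed, "atom_direct")
                    if res is not None:
                        results.append(res)
                    bx = spos[0] + DEFAULT_BOND_LENGTH * math.cos(math.radians(t1))
                    by = spos[1] + DEFAULT_BOND_LENGTH * math.sin(math.radians(t1))
                    placed = _transformed(frag, rot, npos, (bx - npos[0], by - npos[1]))
                    res = _compose(
                        base, placed, "atom_bridge",
                        bridges=[(subject, n, 1, "none")],
                    )
                    if res is not None:
                        results.append(res)
    return results


def graft_bond_connection(base: Molecule, subject_bond: tuple[int, int],
                          template: Template) -> list[GraftResult]:
    """Fuse the fragment across the subject bond.

    Each fragment bond is centroid-aligned onto the subject bond, parallel
    and anti-parallel, for the fragment and its mirror; the matched bonds'
    atoms merge with the input structure's coordinates always retained.
    """
    frag0 = template.stripped()
    a1, a2 = subject_bond
    if base.find_bond(a1, a2) is None:
        raise ValueError("graft_bond_connection subject atoms are not bonded")
    p1, p2 = base.atoms[a1], base.atoms[a2]
    scx, scy = (p1.x + p2.x) / 2.0, (p1.y + p2.y) / 2.0
    sdir = math.degrees(math.atan2(p2.y - p1.y, p2.x - p1.x)) % 360.0
    results = []
    for frag in _variants(frag0):
        for bi, fb in enumerate(frag.bonds):
            f1, f2 = fb.frm, fb.to
            fp1, fp2 = frag.atoms[f1], frag.atoms[f2]
            fcx, fcy = (fp1.x + fp2.x) / 2.0, (fp1.y + fp2.y) / 2.0
            fdir = math.degrees(math.atan2(fp2.y - fp1.y, fp2.x - fp1.x)) % 360.0
            for anti in (False, True):
                rot = (sdir - fdir + (180.0 if anti else 0.0)) % 360.0
                placed = _transformed(frag, rot, (fcx, fcy), (scx - fcx, scy - fcy))
                # pair each matched fragment atom with the nearer subject atom
                if anti:
                    pairs = [(a1, f2), (a2, f1)]
                else:
                    pairs = [(a1, f1), (a2, f2)]
                res = _compose(
                    base, placed, "bond_connection",
                    forced=[(sa, fa, 0) for sa, fa in pairs],
                )
                if res is not None:
                    results.append(res)
    return results


def graft_multi_connection(base: Molecule, subject: list[int],
                           template: Template) -> list[GraftResult]:
    """Fuse the fragment by overlaying it onto several subject atoms.

    Fragment atom N1 translates onto the first subject atom and the fragment
    rotates so N1->N2 matches the first-two-subject direction; the graft is
    kept only if N2 and every remaining subject atom lands within the overlap
    threshold of a fragment atom. Repeated with the mirror image.
    """
    frag0 = template.stripped()
    if len(subject) < 2 or len(frag0.atoms) < 2:
        return []
    s1, s2 = subject[0], subject[1]
    p1 = (base.atoms[s1].x, base.atoms[s1].y)
    sdir = math.degrees(
        math.atan2(base.atoms[s2].y - p1[1], base.atoms[s2].x - p1[0])
    ) % 360.0
    results = []
    for frag in _variants(frag0):
        for n1 in range(len(frag.atoms)):
            for n2 in range(len(frag.atoms)):
                if n2 == n1:
                    continue
                fdir = _bearing(frag, n1, n2)
                npos = (frag.atoms[n1].x, frag.atoms[n1].y)
                placed = _transformed(
                    frag, sdir - fdir, npos, (p1[0] - npos[0], p1[1] - npos[1])
                )
                if not _overlaps(placed, n2, base.atoms[s2]):
                    continue
                ok = True
                for s in subject[2:]:
                    if not any(
                        _overlaps(placed, f, base.atoms[s])
                        for f in range(len(placed.atoms))
                    ):
                        ok = False
                        break
                if not ok:
                    continue
                res = _compose(base, placed, "multi_connection")
                if res is not None:
                    results.append(res)
    return results


def _overlaps(frag: Molecule, fidx: int, atom: Atom) -> bool:
    fa = frag.atoms[fidx]
    return math.hypot(fa.x - atom.x, fa.y - atom.y) < OVERLAP_THRESHOLD


# ---------------------------------------------------------------------------
# Guide-atom modes


def _guide_applicability(state: SketchState, template: Template) -> str | None:
    guides = template.guide_atoms
    if not guides:
        return None
    subject = subject_atoms(state)
    frag = template.fragment
    if len(subject) == 1 and len(guides) == 1:
        deg = frag.degree(guides[0])
        if deg == 1:
            return "one_guide_atom"
        if deg > 1:
            return "guide_median"
    if (
        len(subject) == 2
        and state.molecule.find_bond(subject[0], subject[1]) is not None
        and len(guides) == 1
        and frag.degree(guides[0]) == 1
    ):
        return "one_guide_bond"
    if len(subject) >= 2 and len(guides) == len(subject):
        return "multi_guide"
    return None


def graft_with_guides(base: Molecule, subject: list[int], template: Template,
                      mode: str | None = None,
                      subject_bonded: bool | None = None) -> list[GraftResult]:
    """Graft a guide-carrying template (all guide modes; mirrors included)."""
    frag = template.fragment
    guides = template.guide_atoms
    if mode is None:
        bonded = (
            subject_bonded
            if subject_bonded is not None
            else len(subject) == 2 and base.find_bond(subject[0], subject[1]) is not None
        )
        if len(subject) == 1 and len(guides) == 1:
            mode = "one_guide_atom" if frag.degree(guides[0]) == 1 else "guide_median"
        elif bonded and len(guides) == 1 and frag.degree(guides[0]) == 1:
            mode = "one_guide_bond"
        elif len(subject) >= 2 and len(guides) == len(subject):
            mode = "multi_guide"
        else:
            raise ValueError("no guide-grafting mode applies")
    if mode == "one_guide_atom":
        return _graft_one_guide_atom(base, subject[0], template)
    if mode == "guide_median":
        return _graft_guide_median(base, subject[0], template)
    if mode == "one_guide_bond":
        return _graft_one_guide_bond(base, (subject[0], subject[1]), template)
    if mode == "multi_guide":
        return _graft_multi_guide(base, subject, template)
    raise ValueError(f"unknown guide mode {mode!r}")


def _strip_one_guide(frag: Molecule, guide: int) -> tuple[Molecule, dict[int, int], list[Bond]]:
    """Remove one guide atom; return (fragment, index map, its former bonds)."""
    former = [frag.bonds[i].copy() for i in frag.bonds_at(guide)]
    out = frag.copy()
    mapping = out.remove_atoms({guide})
    return out, mapping, former


def _graft_one_guide_atom(base: Molecule, subject: int, template: Template) -> list[GraftResult]:
    """One subject atom, one guide with a single neighbour.

    The guide maps onto the subject atom; the projection direction comes from
    the subject's candidate angles and the bond distance from the guide-to-
    neighbour distance. The guide's bond is rewired to the subject.
    """
    results = []
    spos = (base.atoms[subject].x, base.atoms[subject].y)
    theta1s = propose_new_bond_angles(base, subject, 1)
    for frag in _variants(template.fragment):
        guide = next(i for i, a in enumerate(frag.atoms) if a.element == GUIDE_SYMBOL)
        neighbour = frag.neighbours(guide)[0]
        psi = _bearing(frag, guide, neighbour)
        gpos = (frag.atoms[guide].x, frag.atoms[guide].y)
        gbond = frag.bonds[frag.bonds_at(guide)[0]]
        for t1 in theta1s:
            placed = _transformed(
                frag, t1 - psi, gpos, (spos[0] - gpos[0], spos[1] - gpos[1])
            )
            stripped, mapping, _ = _strip_one_guide(placed, guide)
            res = _compose(
                base, stripped, "one_guide_atom", guide_count=1,
                bridges=[(subject, mapping[neighbour], gbond.order, gbond.stereo)],
            )
            if res is not None:
                results.append(res)
    return results


def _circular_median(angles: list[float]) -> float:
    x = sum(math.cos(math.radians(a)) for a in angles)
    y = sum(math.sin(math.radians(a)) for a in angles)
    return math.degrees(math.atan2(y, x)) % 360.0


def _graft_guide_median(base: Molecule, subject: int, template: Template) -> list[GraftResult]:
    """One subject atom, one guide with several neighbours (e.g. a chelate).

    The guide marks where the subject atom sits in the template; the median
    of the guide-to-neighbour angles is aligned with the subject's projected
    bond direction, the guide's bonds are rewired to the subject, and the
    guide is deleted.
    """
    results = []
    spos = (base.atoms[subject].x, base.atoms[subject].y)
    theta1s = propose_new_bond_angles(base, subject, 1)
    for frag in _variants(template.fragment):
        guide = next(i for i, a in enumerate(frag.atoms) if a.element == GUIDE_SYMBOL)
        neighbours = frag.neighbours(guide)
        psi = _circular_median([_bearing(frag, guide, n) for n in neighbours])
        gpos = (frag.atoms[guide].x, frag.atoms[guide].y)
        gbonds = [frag.bonds[i].copy() for i in frag.bonds_at(guide)]
        for t1 in theta1s:
            placed = _transformed(
                frag, t1 - psi, gpos, (spos[0] - gpos[0], spos[1] - gpos[1])
            )
            stripped, mapping, _ = _strip_one_guide(placed, guide)
            bridges = [
                (subject, mapping[b.other(guide)], b.order, b.stereo) for b in gbonds
            ]
            res = _compose(base, stripped, "guide_median", guide_count=1, bridges=bridges)
            if res is not None:
                results.append(res)
    return results


def _graft_one_guide_bond(base: Molecule, subject_bond: tuple[int, int],
                          template: Template) -> list[GraftResult]:
    """Subject bond mapped onto the guide-to-neighbour bond of the template.

    Four base permutations (mirror x parallel/anti-parallel); when the two
    bonds differ in length a further bifurcation keeps either the template's
    bond length (guide pinned to its subject atom) or the substrate's
    (neighbour pinned to the other subject atom).
    """
    a1, a2 = subject_bond
    results = []
    pa1 = (base.atoms[a1].x, base.atoms[a1].y)
    pa2 = (base.atoms[a2].x, base.atoms[a2].y)
    d_s = math.hypot(pa2[0] - pa1[0], pa2[1] - pa1[1])
    for frag in _variants(template.fragment):
        guide = next(i for i, a in enumerate(frag.atoms) if a.element == GUIDE_SYMBOL)
        neighbour = frag.neighbours(guide)[0]
        d_t = frag.distance(guide, neighbour)
        gbond = frag.bonds[frag.bonds_at(guide)[0]]
        for g_target, n_target in ((a1, a2), (a2, a1)):
            gt = (base.atoms[g_target].x, base.atoms[g_target].y)
            nt = (base.atoms[n_target].x, base.atoms[n_target].y)
            want = math.degrees(math.atan2(nt[1] - gt[1], nt[0] - gt[0])) % 360.0
            psi = _bearing(frag, guide, neighbour)
            cases = [0] if abs(d_s - d_t) < 1e-9 else [0, 1]
            for case in cases:
                gpos = (frag.atoms[guide].x, frag.atoms[guide].y)
                if case == 0:
                    # template bond length wins: pin the guide
                    placed = _transformed(
                        frag, want - psi, gpos, (gt[0] - gpos[0], gt[1] - gpos[1])
                    )
                    coords_side = 1
                else:
                    # substrate bond length wins: pin the neighbour
                    rotated = _transformed(frag, want - psi, gpos)
                    np_ = (rotated.atoms[neighbour].x, rotated.atoms[neighbour].y)
                    placed = rotated
                    placed.translate(nt[0] - np_[0], nt[1] - np_[1])
                    coords_side = 0
                stripped, mapping, _ = _strip_one_guide(placed, guide)
                res = _compose(
                    base, stripped, "one_guide_bond", guide_count=1,
                    bridges=[(g_target, mapping[neighbour], gbond.order, gbond.stereo)],
                    forced=[(n_target, mapping[neighbour], coords_side)],
                )
                if res is not None:
                    results.append(res)
    return results


def _graft_multi_guide(base: Molecule, subject: list[int], template: Template) -> list[GraftResult]:
    """k subject atoms mapped onto k guide atoms (k >= 2).

    Alignment works as in multi-connection grafting but iterates over guide
    atoms; on success each guide's bonds are rewired to its subject atom and
    the guides are deleted.
    """
    results = []
    s1, s2 = subject[0], subject[1]
    p1 = (base.atoms[s1].x, base.atoms[s1].y)
    sdir = math.degrees(
        math.atan2(base.atoms[s2].y - p1[1], base.atoms[s2].x - p1[0])
    ) % 360.0
    for frag in _variants(template.fragment):
        guides = [i for i, a in enumerate(frag.atoms) if a.element == GUIDE_SYMBOL]
        for g1 in guides:
            for g2 in guides:
                if g2 == g1:
                    continue
                fdir = _bearing(frag, g1, g2)
                gpos = (frag.atoms[g1].x, frag.atoms[g1].y)
                placed = _transformed(
                    frag, sdir - fdir, gpos, (p1[0] - gpos[0], p1[1] - gpos[1])
                )
                if not _overlaps(placed, g2, base.atoms[s2]):
                    continue
                assignment = {g1: s1, g2: s2}
                rest = [g for g in guides if g not in (g1, g2)]
                free = [s for s in subject[2:]]
                ok = True
                for g in rest:
                    match = None
                    for s in free:
                        if _overlaps(placed, g, base.atoms[s]):
                            match = s
                            break
                    if match is None:
                        ok = False
                        break
                    free.remove(match)
                    assignment[g] = match
                if not ok:
                    continue
                bridges = []
                for g, s in assignment.items():
                    for bi in placed.bonds_at(g):
                        b = placed.bonds[bi]
                        other = b.other(g)
                        if other in assignment:
                            continue  # guide-guide bonds vanish with the guides
                        bridges.append((s, other, b.order, b.stereo))
                stripped = placed.copy()
                mapping = stripped.remove_atoms(set(guides))
                bridges = [(s, mapping[o], order, st) for s, o, order, st in bridges]
                res = _compose(
                    base, stripped, "multi_guide", guide_count=len(guides),
                    bridges=bridges,
                )
                if res is not None:
                    results.append(res)
    return results


# ---------------------------------------------------------------------------
# Scoring and ranking


def _hybridisation(mol: Molecule, atom: int) -> str | None:
    """'sp', 'sp2' or 'sp3' when clearly so; None otherwise."""
    a = mol.atoms[atom]
    if a.element not in ("C", "N", "O", "P", "S") or a.charge != 0 or a.unpaired != 0:
        return None
    orders = [mol.bonds[i].order for i in mol.bonds_at(atom)]
    if not orders:
        return None
    triples = sum(1 for o in orders if o == 3)
    doubles = sum(1 for o in orders if o == 2)
    if any(o not in (1, 2, 3) for o in orders):
        return None
    if triples >= 1 or doubles >= 2:
        return "sp"
    if doubles == 1:
        return "sp2"
    return "sp3"


def score_graft_result(mol: Molecule, merged_count: int = 0, guide_count: int = 0,
                       new_bonds: frozenset = frozenset()) -> float:
    """Score a grafted candidate; lower is better.

    total congestion, +1 per positional merge, +50 per clearly-hybridised
    C/N/O/P/S atom whose new bond sits off the ideal angle (120 degrees for
    sp3/sp2, 180 for sp, 5 degree tolerance) from a pre-existing neighbour,
    +1000 per carbon or nitrogen with total bond order >= 5, and -1 per
    guide atom involved.
    """
    score = total_congestion(mol)
    score += MERGE_PENALTY * merged_count
    score -= GUIDE_REWARD * guide_count
    for i, a in enumerate(mol.atoms):
        if a.element in ("C", "N") and mol.total_bond_order(i) >= 5:
            score += HYPERVALENT_PENALTY
    if new_bonds:
        new_keys = set(new_bonds)
        for i in range(len(mol.atoms)):
            incident = mol.bonds_at(i)
            fresh = [b for b in incident if frozenset((mol.bonds[b].frm, mol.bonds[b].to)) in new_keys]
            old = [b for b in incident if frozenset((mol.bonds[b].frm, mol.bonds[b].to)) not in new_keys]
            if not fresh or not old:
                continue
            hyb = _hybridisation(mol, i)
            if hyb is None:
                continue
            ideal = 180.0 if hyb == "sp" else 120.0
            penalised = False
            ai = mol.atoms[i]
            for nb in fresh:
                ob = mol.bonds[nb]
                na = mol.atoms[ob.other(i)]
                new_dir = math.atan2(na.y - ai.y, na.x - ai.x)
                for obi in old:
                    bb = mol.bonds[obi]
                    oa = mol.atoms[bb.other(i)]
                    old_dir = math.atan2(oa.y - ai.y, oa.x - ai.x)
                    span = abs(math.degrees(new_dir - old_dir)) % 360.0
                    span = min(span, 360.0 - span)
                    if abs(span - ideal) > ANGLE_PENALTY_TOLERANCE:
                        penalised = True
                        break
                if penalised:
                    break
            if penalised:
                score += ANGLE_PENALTY
    return score


def rank_and_filter(results: list[GraftResult]) -> list[GraftResult]:
    """Deduplicate equivalent structures (keep the first), sort ascending by
    score, and -- when the best score is under 1000 -- drop candidates at or
    above 1000."""
    unique: list[GraftResult] = []
    for r in results:
        if any(structures_equivalent(r.molecule, u.molecule) for u in unique):
            continue
        unique.append(r)
    unique.sort(key=lambda r: r.score)
    if unique and unique[0].score < EXCLUSION_THRESHOLD:
        unique = [r for r in unique if r.score < EXCLUSION_THRESHOLD]
    return unique


def graft(state: SketchState, template: Template) -> list[GraftResult]:
    """Dispatch on subject shape and guide presence; return ranked results."""
    subject = subject_atoms(state)
    base = state.molecule
    guide_mode = _guide_applicability(state, template)
    if guide_mode is not None:
        candidates = graft_with_guides(base, subject, template, mode=guide_mode)
    elif not subject:
        candidates = graft_no_connection(base, template)
    elif len(subject) == 1:
        candidates = graft_atom_connection(base, subject[0], template)
    elif len(subject) == 2 and base.find_bond(subject[0], subject[1]) is not None:
        candidates = graft_bond_connection(base, (subject[0], subject[1]), template)
    else:
        candidates = graft_multi_connection(base, subject, template)
    ranked = rank_and_filter(candidates)
    log.info(
        "graft: %d candidates, %d after dedup/filter", len(candidates), len(ranked)
    )
    return ranked
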