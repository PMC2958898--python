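"""Geometry perception: congestion, template matching, new-bond inference."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from molsketch import (
    Atom,
    Bond,
    GEOMETRY_TEMPLATES,
    Molecule,
    bond_angles_at,
    enumerate_plausible_geometries,
    match_template,
    median_cut_angles,
    point_congestion,
    propose_new_bond_angles,
    refit_to_geometry,
    total_congestion,
)
from molsketch.geometry import RefitError
from molsketch.fixtures import regular_ring

from conftest import random_molecule


def brute_point_congestion(mol, x, y):
    return sum(1.0 / ((a.x - x) ** 2 + (a.y - y) ** 2 + 0.001) for a in mol.atoms)


def brute_total_congestion(mol):
    total = 0.0
    for i in range(len(mol.atoms)):
        for j in range(i + 1, len(mol.atoms)):
            a, b = mol.atoms[i], mol.atoms[j]
            total += 1.0 / ((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + 0.001)
    return total


def oracle_match(existing, template, tol=2.0, step=0.05):
    """Exhaustive-rotation oracle for template matching.

    Scans every rotation of the template (and its mirror) in small steps;
    each valid superposition is grouped by its slot assignment and only the
    best-fitting rotation of each group contributes vacancies -- an
    independent reconstruction of the seeded-and-refined search.
    """
    variants = [
        (0, template.angles),
        (1, tuple(sorted((360 - a) % 360 for a in template.angles))),
    ]
    best_by_assignment = {}
    k = 0
    while k * step < 360.0:
        rot = k * step
        k += 1
        for mirror, slots in variants:
            rotated = [(s + rot) % 360 for s in slots]
            used = set()
            assignment = []
            total = 0.0
            ok = True
            for e in existing:
                best = None
                for si, r in enumerate(rotated):
                    if si in used:
                        continue
                    d = abs(e - r) % 360
                    d = min(d, 360 - d)
                    if d <= tol and (best is None or d < best[0]):
                        best = (d, si)
                if best is None:
                    ok = False
                    break
                used.add(best[1])
                assignment.append(best[1])
                total += best[0]
            if not ok:
                continue
            key = (mirror, tuple(assignment))
            if key not in best_by_assignment or total < best_by_assignment[key][0]:
                vac = [r for si, r in enumerate(rotated) if si not in used]
                best_by_assignment[key] = (total, vac)
    found = [v for _, vacs in best_by_assignment.values() for v in vacs]
    out = []
    for v in sorted(found):
        if any(min(abs(v - e) % 360, 360 - abs(v - e) % 360) <= tol for e in existing):
            continue
        if not any(min(abs(v - w) % 360, 360 - abs(v - w) % 360) <= tol for w in out):
            out.append(v)
    return out


class TestCongestion:
    def test_point_at_atom_position(self):
        mol = Molecule([Atom("C")])
        assert point_congestion(mol, 0.0, 0.0) == pytest.approx(1000.0)

    def test_point_at_unit_distance(self):
        mol = Molecule([Atom("C")])
        assert point_congestion(mol, 1.0, 0.0) == pytest.approx(1 / 1.001)

    def test_two_atoms_sum(self):
        mol = Molecule([Atom("C"), Atom("C", x=2.0)])
        expected = 1 / (1.0 + 0.001) + 1 / (1.0 + 0.001)
        assert point_congestion(mol, 1.0, 0.0) == pytest.approx(expected)

    def test_total_congestion_pair(self):
        mol = Molecule([Atom("C"), Atom("C", x=1.5)])
        assert total_congestion(mol) == pytest.approx(1 / 2.251)

    def test_total_congestion_trivial_cases(self):
        assert total_congestion(Molecule()) == 0.0
        assert total_congestion(Molecule([Atom("C")])) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        mol = random_molecule(seed, n_max=20)
        assert total_congestion(mol) == pytest.approx(
            brute_total_congestion(mol), abs=1e-12
        )
        assert point_congestion(mol, 0.3, -0.7) == pytest.approx(
            brute_point_congestion(mol, 0.3, -0.7), abs=1e-12
        )


class TestBondAngles:
    def test_isolated_atom(self):
        assert bond_angles_at(Molecule([Atom("C")]), 0) == []

    def test_axis_neighbour(self):
        mol = Molecule([Atom("C"), Atom("C", x=1.5)], [Bond(0, 1)])
        assert bond_angles_at(mol, 0) == [pytest.approx(0.0)]

    def test_diagonal_neighbours(self):
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.0, y=1.0), Atom("C", x=-1.0, y=1.0)],
            [Bond(0, 1), Bond(0, 2)],
        )
        assert bond_angles_at(mol, 0) == [pytest.approx(45.0), pytest.approx(135.0)]


class TestEnumerateGeometries:
    def test_terminal_carbon_alkyne_like(self):
        mol = Molecule([Atom("C"), Atom("C", x=1.5)], [Bond(0, 1, order=3)])
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["linear"]

    def test_terminal_iron_gets_octahedral(self):
        mol = Molecule([Atom("Fe"), Atom("C", x=1.5)], [Bond(0, 1)])
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["octa1", "octa2"]

    def test_terminal_oxygen_trigonal(self):
        mol = Molecule([Atom("O"), Atom("C", x=1.5)], [Bond(0, 1)])
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["trigonal"]

    def test_carbon_two_singles_rule(self):
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.3, y=0.75), Atom("C", x=1.3, y=-0.75)],
            [Bond(0, 1), Bond(0, 2)],
        )
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["trigonal", "square_planar", "tetra1", "tetra2"]

    def test_carbon_gaining_double_bond_is_trigonal(self):
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.3, y=0.75), Atom("C", x=1.3, y=-0.75)],
            [Bond(0, 1), Bond(0, 2)],
        )
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 2)]
        assert names == ["trigonal"]

    def test_divalent_linear_p_block_square_planar(self):
        mol = Molecule(
            [Atom("S"), Atom("C", x=1.5), Atom("C", x=-1.5)],
            [Bond(0, 1), Bond(0, 2)],
        )
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["square_planar"]

    def test_divalent_linear_metal_octahedral(self):
        mol = Molecule(
            [Atom("Pt"), Atom("C", x=1.5), Atom("C", x=-1.5)],
            [Bond(0, 1), Bond(0, 2)],
        )
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["octa1", "octa2"]

    def test_non_element_symbol(self):
        mol = Molecule(
            [Atom("X"), Atom("C", x=1.3, y=0.75), Atom("C", x=1.3, y=-0.75)],
            [Bond(0, 1), Bond(0, 2)],
        )
        names = [t.name for t in enumerate_plausible_geometries(mol, 0, 1)]
        assert names == ["trigonal", "square_planar"]

    def test_never_empty(self):
        for el in ("C", "N", "Fe", "U", "Xx", "K", "I", "Sn"):
            mol = Molecule(
                [Atom(el), Atom("C", x=1.3, y=0.75), Atom("C", x=1.3, y=-0.75),
                 Atom("C", x=-1.5)],
                [Bond(0, 1), Bond(0, 2), Bond(0, 3)],
            )
            assert enumerate_plausible_geometries(mol, 0, 1)


class TestMatchTemplate:
    def test_single_bond_vs_trigonal(self):
        vac = match_template([0.0], GEOMETRY_TEMPLATES["trigonal"])
        assert vac == [pytest.approx(120.0), pytest.approx(240.0)]
        assert sorted(oracle_match([0.0], GEOMETRY_TEMPLATES["trigonal"])) == pytest.approx(vac, abs=0.1)

    def test_right_angle_vs_square_planar(self):
        vac = match_template([0.0, 90.0], GEOMETRY_TEMPLATES["square_planar"])
        assert vac == [pytest.approx(180.0), pytest.approx(270.0)]

    def test_out_of_tolerance_no_match(self):
        assert match_template([0.0, 100.0], GEOMETRY_TEMPLATES["trigonal"]) == []

    def test_split_tolerance_still_matches(self):
        # both bearings off by 2 deg in opposite directions: only the
        # refined intermediate rotation satisfies the tolerance
        vac = match_template([2.0, 118.0], GEOMETRY_TEMPLATES["trigonal"])
        assert len(vac) == 1
        assert vac[0] == pytest.approx(240.0, abs=0.1)

    @pytest.mark.parametrize("name", sorted(GEOMETRY_TEMPLATES))
    def test_agrees_with_rotation_scan_oracle(self, name):
        template = GEOMETRY_TEMPLATES[name]
        existing = [10.0, 130.0]
        got = match_template(existing, template)
        want = oracle_match(existing, template)
        assert len(got) == len(want)
        for g, w in zip(sorted(got), sorted(want)):
            assert abs(g - w) < 0.3 or 360 - abs(g - w) < 0.3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(base=st.floats(0, 360), shift=st.floats(0, 360))
    def test_rotation_invariance(self, base, shift):
        existing = [base % 360, (base + 120) % 360]
        t = GEOMETRY_TEMPLATES["trigonal"]
        v0 = match_template(existing, t)
        v1 = match_template([(e + shift) % 360 for e in existing], t)
        assert len(v0) == len(v1)
        if v0:
            rotated = sorted((v + shift) % 360 for v in v0)
            for a, b in zip(rotated, sorted(v1)):
                d = abs(a - b) % 360
                assert min(d, 360 - d) < 1e-6


class TestMedianCut:
    def test_two_bearings(self):
        assert median_cut_angles([0.0, 100.0]) == [pytest.approx(50.0), pytest.approx(230.0)]

    def test_wraparound_midpoint(self):
        got = median_cut_angles([350.0, 10.0])
        assert got == [pytest.approx(0.0, abs=1e-9), pytest.approx(180.0)]

    def test_count_equals_neighbour_count(self):
        bearings = [5.0, 77.0, 160.0, 301.0]
        assert len(median_cut_angles(bearings)) == 4


class TestProposeNewBondAngles:
    def test_isolated_atom_axis_angles(self):
        mol = Molecule([Atom("C")])
        assert propose_new_bond_angles(mol, 0, 1) == [0.0, 90.0, 180.0, 270.0]

    def test_terminal_oxygen_trigonal_vacancies(self):
        mol = Molecule([Atom("O"), Atom("C", x=1.5)], [Bond(0, 1)])
        got = propose_new_bond_angles(mol, 0, 1)
        assert got == [pytest.approx(120.0), pytest.approx(240.0)]

    def test_median_cut_fallback(self):
        # bearings 0 and 100 match no carbon template -> circular midpoints
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.5),
             Atom("C", x=1.5 * math.cos(math.radians(100)), y=1.5 * math.sin(math.radians(100)))],
            [Bond(0, 1), Bond(0, 2)],
        )
        got = propose_new_bond_angles(mol, 0, 2)  # double bond -> trigonal only
        assert got == [pytest.approx(50.0), pytest.approx(230.0)]

    @pytest.mark.parametrize("seed", range(10))
    def test_nonempty_and_avoids_existing_bearings(self, seed):
        mol = random_molecule(seed)
        for atom in range(len(mol.atoms)):
            if mol.degree(atom) == 0:
                continue
            bearings = bond_angles_at(mol, atom)
            if any(
                abs(a - b) < 2.0
                for i, a in enumerate(bearings)
                for b in bearings[:i]
            ):
                continue  # near-coincident bonds: midpoints degenerate
            angles = propose_new_bond_angles(mol, atom, 1)
            assert angles
            for angle in angles:
                for bearing in bearings:
                    d = abs(angle - bearing) % 360
                    assert min(d, 360 - d) > 1e-6


class TestRefit:
    def test_already_matching_is_untouched(self):
        # bent ether-like pair of bonds 120 deg apart is trigonal-compatible
        mol = Molecule(
            [Atom("O"), Atom("C", x=1.5),
             Atom("C", x=1.5 * math.cos(math.radians(120)), y=1.5 * math.sin(math.radians(120)))],
            [Bond(0, 1), Bond(0, 2)],
        )
        out = refit_to_geometry(mol, 0, GEOMETRY_TEMPLATES["trigonal"])
        assert out is mol

    def test_minimal_displacement_assignment(self):
        # bonds at 0 and 60 deg, target square planar: one bond rotates to 90
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.5),
             Atom("C", x=1.5 * math.cos(math.radians(60)), y=1.5 * math.sin(math.radians(60)))],
            [Bond(0, 1), Bond(0, 2)],
        )
        out = refit_to_geometry(mol, 0, GEOMETRY_TEMPLATES["square_planar"])
        got = bond_angles_at(out, 0)
        assert got == [pytest.approx(0.0, abs=1e-6), pytest.approx(90.0)]

    def test_branch_moves_rigidly(self):
        # neighbour carries a substituent; distances within the branch persist
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.5),
             Atom("C", x=1.5 * math.cos(math.radians(60)), y=1.5 * math.sin(math.radians(60))),
             Atom("N", x=1.5 * math.cos(math.radians(60)) + 1.5,
                  y=1.5 * math.sin(math.radians(60)))],
            [Bond(0, 1), Bond(0, 2), Bond(2, 3)],
        )
        out = refit_to_geometry(mol, 0, GEOMETRY_TEMPLATES["square_planar"])
        assert out.distance(2, 3) == pytest.approx(1.5, abs=1e-9)
        assert out.distance(0, 2) == pytest.approx(1.5, abs=1e-9)

    def test_ring_locked_atom_fails(self, benzene):
        with pytest.raises(RefitError):
            refit_to_geometry(benzene, 0, GEOMETRY_TEMPLATES["linear"])

    def test_ring_bonds_never_move(self):
        # ring atom with an exocyclic substituent: only the substituent moves
        mol = regular_ring(6)
        idx = mol.add_atom(Atom("C", x=0.4, y=mol.atoms[0].y + 1.45))
        mol.add_bond(Bond(0, idx))
        out = refit_to_geometry(mol, 0, GEOMETRY_TEMPLATES["trigonal"])
        for i in range(6):
            assert out.atoms[i].x == pytest.approx(mol.atoms[i].x)
            assert out.atoms[i].y == pytest.approx(mol.atoms[i].y)
        assert out.distance(0, idx) == pytest.approx(mol.distance(0, idx), abs=1e-9)
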