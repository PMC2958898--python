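"""Template creation, grafting modes, scoring and ranking."""

import math

import pytest

from molsketch import (
    Atom,
    Bond,
    GraftResult,
    Molecule,
    SketchState,
    Template,
    create_template,
    graft,
    rank_and_filter,
    score_graft_result,
    structures_equivalent,
    total_congestion,
)
from molsketch.grafting import (
    graft_atom_connection,
    graft_bond_connection,
    graft_multi_connection,
    graft_no_connection,
    graft_with_guides,
)
from molsketch.fixtures import builtin_templates, regular_ring

from conftest import graphs_isomorphic


def state_of(mol, select=(), current_atom=None, current_bond=None):
    return SketchState(
        molecule=mol,
        selection=set(select),
        current_atom=current_atom,
        current_bond=current_bond,
    )


class TestCreateTemplate:
    def test_whole_component_has_no_guides(self, benzene):
        tpl = create_template(state_of(benzene, select=set(range(6))))
        assert len(tpl.fragment.atoms) == 6
        assert tpl.guide_atoms == []

    def test_partial_selection_gains_boundary_guides(self, benzene):
        # a two-atom substituent on a ring: the attachment carbon becomes "*"
        mol = benzene.copy()
        o = mol.add_atom(Atom("O", x=5.0))
        c = mol.add_atom(Atom("C", x=6.5))
        mol.add_bond(Bond(0, o))
        mol.add_bond(Bond(o, c))
        tpl = create_template(state_of(mol, select={o, c}))
        assert len(tpl.fragment.atoms) == 3
        assert len(tpl.guide_atoms) == 1
        guide = tpl.fragment.atoms[tpl.guide_atoms[0]]
        assert guide.element == "*"
        assert len(tpl.fragment.bonds) == 2

    def test_single_atom_of_ethane(self, ethane):
        tpl = create_template(state_of(ethane, select={0}))
        assert len(tpl.fragment.atoms) == 2
        assert len(tpl.guide_atoms) == 1


class TestNoConnection:
    def test_asymmetric_fragment_sixteen_rotations(self):
        frag = Molecule(
            [Atom("C"), Atom("N", x=1.5), Atom("O", x=2.25, y=1.3)],
            [Bond(0, 1), Bond(1, 2)],
        )
        results = graft_no_connection(Molecule(), Template(frag))
        assert len(results) == 16  # 12 x 30deg union 8 x 45deg, 4 shared

    def test_placement_leaves_gap(self, benzene, ethane):
        results = graft_no_connection(benzene, builtin_templates()["cyclopentane"])
        _, _, max_x, _ = benzene.bounding_box()
        for r in results:
            new_atoms = r.molecule.atoms[6:]
            assert min(a.x for a in new_atoms) >= max_x + 1.5 - 1e-9

    def test_guides_stripped(self):
        frag = Molecule(
            [Atom("*"), Atom("C", x=1.5)], [Bond(0, 1)]
        )
        results = graft_no_connection(Molecule(), Template(frag))
        for r in results:
            assert all(a.element != "*" for a in r.molecule.atoms)


class TestAtomConnection:
    def test_bridge_extends_by_default_length(self, benzene):
        results = graft_atom_connection(benzene, 0, builtin_templates()["acetyl"])
        bridged = [r for r in results if r.mode == "atom_bridge"]
        assert bridged
        m = bridged[0].molecule
        assert len(m.atoms) == 9

    def test_mirror_symmetric_template_dedups_completely(self, benzene):
        # a single-atom template is its own mirror image: after ranking,
        # mirrored duplicates vanish
        tpl = Template(Molecule([Atom("N")]))
        ranked = rank_and_filter(graft_atom_connection(benzene, 0, tpl))
        seen = []
        for r in ranked:
            assert not any(structures_equivalent(r.molecule, s) for s in seen)
            seen.append(r.molecule)

    def test_direct_merges_subject_into_fragment(self):
        mol = Molecule([Atom("N")])
        results = graft_atom_connection(mol, 0, builtin_templates()["cyclopropane"])
        direct = [r for r in results if r.mode == "atom_direct"]
        assert direct
        assert all(len(r.molecule.atoms) == 3 for r in direct)
        assert all(r.merged_count == 1 for r in direct)
        # the more exotic nitrogen survives the overlay
        assert all(
            sorted(a.element for a in r.molecule.atoms) == ["C", "C", "N"]
            for r in direct
        )


class TestBondConnection:
    def test_benzene_on_benzene_gives_naphthalene(self, benzene):
        from molsketch.fixtures import generate_fixture

        # fusing across an order-2 ring bond keeps the shared bond double,
        # giving the central-double naphthalene Kekule form
        results = graft_bond_connection(benzene, (0, 1), builtin_templates()["benzene"])
        ref = generate_fixture("naphthalene")
        fused = [
            r
            for r in results
            if len(r.molecule.atoms) == 10 and len(r.molecule.bonds) == 11
        ]
        assert fused
        assert any(graphs_isomorphic(r.molecule, ref) for r in fused)

    def test_input_coordinates_retained_for_matched_atoms(self, benzene):
        shrunk = regular_ring(5, bond=1.2)
        results = graft_bond_connection(benzene, (0, 1), Template(shrunk))
        ring_pos = [(a.x, a.y) for a in benzene.atoms]
        for r in results:
            got = [(a.x, a.y) for a in r.molecule.atoms[:6]]
            for (x0, y0), (x1, y1) in zip(ring_pos, got):
                assert math.hypot(x0 - x1, y0 - y1) < 1e-9


class TestMultiConnection:
    def test_contiguous_arc_overlay_reproduces_ring(self):
        # two regular heptagons sharing a contiguous 4-atom arc must
        # coincide entirely: the only surviving candidate is the ring itself
        ring = regular_ring(7)
        results = graft_multi_connection(
            ring, [0, 1, 2, 3], builtin_templates()["cycloheptane"]
        )
        sizes = {(len(r.molecule.atoms), len(r.molecule.bonds)) for r in results}
        assert sizes == {(7, 7)}

    def test_one_three_pair_gives_bridged_bicycle(self):
        # overlaying on two non-bonded 1,3 atoms admits the flipped arc:
        # a 12-atom tricycle whose spare bridge atom deletion leaves
        # bicyclo[4.4.1]undecane
        ring = regular_ring(7)
        results = graft_multi_connection(
            ring, [0, 2], builtin_templates()["cycloheptane"]
        )
        sizes = {(len(r.molecule.atoms), len(r.molecule.bonds)) for r in results}
        assert (12, 14) in sizes

    def test_incompatible_spacing_rejected(self):
        mol = Molecule([Atom("C"), Atom("C", x=7.0)])
        results = graft_multi_connection(
            mol, [0, 1], builtin_templates()["benzene"]
        )
        assert results == []

    def test_scaled_down_template_rejected_not_rescaled(self):
        mol = regular_ring(6)  # bond 1.5
        small = regular_ring(6, bond=1.0)
        results = graft_multi_connection(mol, [0, 1, 2], Template(small))
        assert results == []


class TestGuides:
    def _guided_methyl(self):
        # template: *-C at a nondefault 1.9 A distance
        frag = Molecule([Atom("*"), Atom("C", x=1.9)], [Bond(0, 1)])
        return Template(frag)

    def test_one_guide_atom_preserves_distance(self, benzene):
        results = graft_with_guides(benzene, [0], self._guided_methyl())
        assert results
        for r in results:
            m = r.molecule
            assert len(m.atoms) == 7
            assert all(a.element != "*" for a in m.atoms)
            assert m.distance(0, 6) == pytest.approx(1.9, abs=1e-9)
            assert r.guide_count == 1

    def test_guide_median_rewires_all_guide_bonds(self):
        # chelate-like template: guide with two neighbours
        frag = Molecule(
            [Atom("*"), Atom("N", x=1.5, y=0.9), Atom("N", x=1.5, y=-0.9),
             Atom("C", x=2.7)],
            [Bond(0, 1), Bond(0, 2), Bond(1, 3), Bond(2, 3)],
        )
        metal = Molecule([Atom("Ru"), Atom("C", x=-1.5)], [Bond(0, 1)])
        results = graft_with_guides(metal, [0], Template(frag))
        assert results
        best = results[0].molecule
        assert len(best.atoms) == 5
        assert best.degree(0) == 3  # both chelating bonds land on the metal

    def test_two_guides_map_onto_two_subjects(self):
        # template with two anchor guides 1,3 on a ring-like arc
        ring = regular_ring(6)
        frag = regular_ring(6)
        frag.atoms[0].element = "*"
        frag.atoms[2].element = "*"
        results = graft_with_guides(ring, [0, 2], Template(frag))
        assert results
        for r in results:
            assert all(a.element != "*" for a in r.molecule.atoms)
            assert r.guide_count == 2


class TestScoring:
    def test_plain_molecule_scores_total_congestion(self, benzene):
        assert score_graft_result(benzene) == pytest.approx(total_congestion(benzene))

    def test_pentavalent_carbon_costs_exactly_1000(self):
        atoms = [Atom("C")] + [
            Atom("C", x=1.5 * math.cos(a), y=1.5 * math.sin(a))
            for a in (0.0, 1.3, 2.6, 3.9, 5.2)
        ]
        penta = Molecule(atoms, [Bond(0, i) for i in range(1, 6)])
        tetra = Molecule(atoms[:5], [Bond(0, i) for i in range(1, 5)])
        diff = (
            score_graft_result(penta)
            - total_congestion(penta)
            - (score_graft_result(tetra) - total_congestion(tetra))
        )
        assert diff == pytest.approx(1000.0)

    @pytest.mark.parametrize("angle,penalised", [(100.0, True), (118.0, False)])
    def test_irregular_angle_boundary(self, angle, penalised):
        mol = Molecule(
            [Atom("C"), Atom("C", x=1.5),
             Atom("C", x=1.5 * math.cos(math.radians(angle)),
                  y=1.5 * math.sin(math.radians(angle)))],
            [Bond(0, 1), Bond(0, 2)],
        )
        new_bonds = frozenset({frozenset((0, 2))})
        score = score_graft_result(mol, new_bonds=new_bonds)
        extra = score - total_congestion(mol)
        assert extra == pytest.approx(50.0 if penalised else 0.0)

    def test_merge_and_guide_terms(self, benzene):
        base = total_congestion(benzene)
        assert score_graft_result(benzene, merged_count=3) == pytest.approx(base + 3)
        assert score_graft_result(benzene, guide_count=2) == pytest.approx(base - 2)


class TestRankAndFilter:
    def _result(self, mol, score):
        return GraftResult(molecule=mol, score=score)

    def test_high_scores_excluded_when_best_is_good(self):
        a = Molecule([Atom("C")])
        b = Molecule([Atom("N")])
        ranked = rank_and_filter([self._result(a, 2000.0), self._result(b, 3.1)])
        assert [r.score for r in ranked] == [3.1]

    def test_all_kept_when_best_is_bad(self):
        a = Molecule([Atom("C")])
        b = Molecule([Atom("N")])
        ranked = rank_and_filter([self._result(a, 1200.0), self._result(b, 1500.0)])
        assert [r.score for r in ranked] == [1200.0, 1500.0]

    def test_duplicates_removed_keeping_first(self):
        a = Molecule([Atom("C")])
        ranked = rank_and_filter([self._result(a, 5.0), self._result(a.copy(), 4.0)])
        assert len(ranked) == 1
        assert ranked[0].score == 5.0

    def test_scores_non_decreasing(self, benzene):
        results = graft(
            state_of(benzene, current_atom=0), builtin_templates()["acetyl"]
        )
        scores = [r.score for r in results]
        assert scores == sorted(scores)


class TestGraftDispatcher:
    def test_empty_subject_uses_no_connection(self, benzene):
        results = graft(SketchState(), Template(benzene))
        assert results
        assert all(r.mode == "no_connection" for r in results)

    def test_bonded_pair_uses_bond_connection(self, benzene):
        results = graft(
            state_of(benzene, current_bond=0), builtin_templates()["cyclopentane"]
        )
        assert results
        assert all(r.mode == "bond_connection" for r in results)

    def test_guide_mode_takes_precedence_over_atom_connection(self, benzene):
        frag = Molecule([Atom("*"), Atom("C", x=1.5)], [Bond(0, 1)])
        results = graft(state_of(benzene, current_atom=0), Template(frag))
        assert results
        assert all(r.mode == "one_guide_atom" for r in results)

    def test_results_contain_no_overlaps_or_guides(self, benzene):
        frag = Molecule([Atom("*"), Atom("C", x=1.5)], [Bond(0, 1)])
        for template in (Template(frag), builtin_templates()["cyclopentane"]):
            for r in graft(state_of(benzene, current_atom=0), template):
                m = r.molecule
                assert all(a.element != "*" for a in m.atoms)
                for i in range(len(m.atoms)):
                    for j in range(i + 1, len(m.atoms)):
                        assert m.distance(i, j) >= 0.2
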