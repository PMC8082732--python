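"""Relational and multi-relational diagram construction and decomposition."""

import math

import pytest

from dcjindel.diagram import (
    ADJACENCY,
    ARTIFICIAL,
    CAP,
    EXTREMITY,
    INDEL,
    build_multi_relational,
    build_relational,
    capping_sets,
    component_census,
    consistent_decomposition,
    decompose,
    sibling_edges,
    sibling_sets,
)
from dcjindel.oracle import matched_singular_genomes
from dcjindel.simulate import make_fixture

from conftest import g, random_singular_pair


def all_edges(d):
    return [e.idx for e in d.edges]


class TestRelational:
    def test_fig1_component_census(self):
        A, B = make_fixture("fig1")
        d = build_relational(A, B)
        cc = component_census(decompose(d, all_edges(d)))
        assert cc["AB_cycle"] == 1
        assert cc["AB_path"] == 2
        assert cc["AA_path"] == 1
        assert cc["BB_path"] == 1

    def test_identical_genomes(self):
        A = g("A", "1 2 3")
        B = g("B", "1 2 3")
        d = build_relational(A, B)
        comps = decompose(d, all_edges(d))
        cc = component_census(comps)
        assert cc["AB_path"] == 2 and cc["AB_cycle"] == 2
        assert all(not c.indel_enclosing for c in comps)
        # the two cycles consist of two extremity edges (+2 adjacencies) each
        cycles = [c for c in comps if c.is_cycle]
        assert all(
            sum(1 for i in c.edge_walk if d.edges[i].kind == EXTREMITY) == 2
            for c in cycles
        )

    def test_fig6_paths_only(self):
        A, B = make_fixture("fig6")
        d = build_relational(A, B)
        cc = component_census(decompose(d, all_edges(d)))
        assert cc["AA_path"] == 2 and cc["BB_path"] == 2 and cc["AB_cycle"] == 0

    def test_rejects_duplicated_common_marker(self):
        with pytest.raises(ValueError):
            build_relational(g("A", "1 1 2"), g("B", "1 2"))

    def test_telomeres_and_ab_paths_are_even(self, rng):
        for _ in range(30):
            A, B = random_singular_pair(rng, max_common=6, max_excl=3)
            d = build_relational(A, B)
            comps = decompose(d, all_edges(d))
            n_ab = sum(1 for c in comps if c.cls == "AB_path")
            assert n_ab % 2 == 0
            assert (2 * (A.n_linear + B.n_linear)) % 2 == 0


class TestMultiRelational:
    def test_running_example_dimensions(self):
        A, B = make_fixture("sec2_running")
        d = build_multi_relational(A, B, capped=True)
        assert len(d.vertices) == 16 + 20 + 4  # 8+10 occurrences, p* = 1
        assert d.census.p_star == 1 and d.census.a_star == 0

    def test_running_example_indel_edges(self):
        A, B = make_fixture("sec2_running")
        d = build_multi_relational(A, B)
        idA = [e for e in d.edges if e.kind == INDEL and e.genome == "A"]
        idB = [e for e in d.edges if e.kind == INDEL and e.genome == "B"]
        assert {d.vertex(e.u).marker for e in idA} == {"4", "5"}
        assert {d.vertex(e.u).marker for e in idB} == {"1", "3", "6", "7"}
        # one indel edge per occurrence of each over-represented marker
        assert len(idA) == 2 + 2 and len(idB) == 3 + 3 + 1 + 1

    def test_singular_reduces_to_relational(self, rng):
        A, B = random_singular_pair(rng)
        d1 = build_relational(A, B)
        d2 = build_multi_relational(A, B, capped=False)
        assert [(e.kind, e.u, e.v) for e in d1.edges] == [
            (e.kind, e.u, e.v) for e in d2.edges
        ]

    def test_capping_structure(self):
        A = g("A", "1 2")  # 1 linear chromosome
        B = g("B", "1", "2")  # 2 linear chromosomes -> a* = 1 artificial in A
        d = build_multi_relational(A, B, capped=True)
        caps = [v for v in d.vertices if v.is_cap]
        assert len(caps) == 4 * d.census.p_star == 8
        art = [e for e in d.edges if e.kind == ARTIFICIAL]
        assert len(art) == 1 and art[0].genome == "A"
        cap_edges = [e for e in d.edges if e.kind == CAP]
        assert len(cap_edges) == (2 * d.census.p_star) ** 2
        # every telomere is wired to a distinct cap
        tel_adj = [
            e for e in d.edges if e.kind == ADJACENCY
            and (d.vertex(e.u).is_cap or d.vertex(e.v).is_cap)
        ]
        assert len(tel_adj) == 2 * A.n_linear + 2 * B.n_linear

    def test_vertex_ids_dense(self):
        A, B = make_fixture("fig1")
        d = build_multi_relational(A, B, capped=True)
        assert [v.vid for v in d.vertices] == list(range(1, len(d.vertices) + 1))


class TestDecompose:
    def test_degree_three_rejected(self):
        A, B = make_fixture("sec2_running")
        d = build_multi_relational(A, B)
        with pytest.raises(ValueError):
            decompose(d, all_edges(d))

    def test_missing_adjacency_rejected(self):
        A, B = make_fixture("fig6")
        d = build_relational(A, B)
        with pytest.raises(ValueError):
            decompose(d, all_edges(d)[1:])

    def test_indel_free_cycle_annotations(self):
        d = build_relational(g("A", "( 1 2"), g("B", "( 1 2"))
        comps = decompose(d, all_edges(d))
        assert all(c.is_cycle and c.Lambda == 0 and c.aleph == 0 for c in comps)
        assert all(not c.indel_enclosing for c in comps)

    def test_four_run_path(self):
        # a BB-path whose runs alternate between the genomes four times
        A = g("A", "( -1 -x 4 -y -2", "( -3")
        B = g("B", "( -2 p -4 q", "3", "-1")
        d = build_relational(A, B)
        comps = decompose(d, all_edges(d))
        (path,) = [c for c in comps if c.Lambda == 4]
        assert path.cls == "BB_path"
        assert path.run_signature == "AB"
        assert path.indel_enclosing

    def test_consistent_decomposition_routes_agree(self, rng):
        """Decomposing MR under a sibling set equals the relational diagram of
        the matched singular genomes."""
        from conftest import random_natural_pair

        def key(cs):
            return sorted(
                (c.cls, c.Lambda, c.run_signature, len(c.edge_walk)) for c in cs
            )

        for _ in range(12):
            A, B = random_natural_pair(rng, max_occ=6, max_copy=2)
            d = build_multi_relational(A, B)
            for matching in sibling_sets(d, bound=200):
                comps = decompose(d, consistent_decomposition(d, matching))
                As, Bs = matched_singular_genomes(A, B, matching)
                ds = build_relational(As, Bs)
                assert key(comps) == key(decompose(ds, all_edges(ds)))

    def test_capped_consistent_decomposition_is_cycles_only(self, rng):
        A, B = random_singular_pair(rng, max_common=5, max_excl=2)
        d = build_multi_relational(A, B, capped=True)
        matching = next(sibling_sets(d))
        capping = next(capping_sets(d))
        comps = decompose(d, consistent_decomposition(d, matching, capping))
        assert all(c.is_cycle for c in comps)
        assert sum(len(set(c.vertex_walk)) for c in comps) == len(d.vertices)


class TestSiblingSets:
    def test_injection_count(self):
        A = g("A", "1")
        B = g("B", "1 1 1")
        d = build_multi_relational(A, B)
        assert len(list(sibling_sets(d))) == 3

    def test_singular_single_set(self):
        A, B = make_fixture("fig1")
        d = build_multi_relational(A, B)
        sets = list(sibling_sets(d))
        assert len(sets) == 1

    def test_count_matches_product_formula(self):
        A, B = make_fixture("sec2_running")
        d = build_multi_relational(A, B)
        cen = d.census
        expected = 1
        for m in cen.common:
            p, q = sorted((cen.phiA[m], cen.phiB[m]))
            expected *= math.perm(q, p)
        assert len(list(sibling_sets(d))) == expected

    def test_guard(self):
        A = g("A", "1 1 1 1 1")
        B = g("B", "1 1 1 1 1")
        d = build_multi_relational(A, B)
        with pytest.raises(ValueError):
            list(sibling_sets(d, bound=10))

    def test_sibling_edges_pair_heads_with_tails(self):
        A, B = make_fixture("sec2_running")
        d = build_multi_relational(A, B)
        matching = next(sibling_sets(d))
        edges = sibling_edges(d, matching)
        assert len(edges) == 2 * d.census.n_star
        for i in edges:
            sib = d.edges[i].sibling
            assert sib is not None and d.edges[sib].sibling == i
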