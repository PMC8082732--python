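"""ILP construction, solving, and agreement with the closed form and oracles."""

import pytest

from dcjindel.diagram import (
    CAP,
    EXTREMITY,
    INDEL,
    build_multi_relational,
    capping_sets,
    component_census,
    consistent_decomposition,
    decompose,
    sibling_sets,
)
from dcjindel.genomes import Chromosome, Genome
from dcjindel.ilp import build_ilp, distance_natural, solve
from dcjindel.oracle import matched_singular_genomes, min_over_matchings
from dcjindel.simulate import make_fixture
from dcjindel.singular import (
    PathTypeCount,
    distance_singular,
    greedy_delta,
    indel_potential,
)

from conftest import g, random_natural_pair, random_singular_pair


class TestBuild:
    def test_requires_capped(self):
        A, B = make_fixture("fig6")
        with pytest.raises(ValueError):
            build_ilp(build_multi_relational(A, B, capped=False))

    def test_variable_counts_singular_pair(self):
        # one linear chromosome each: p* = 1, so 2x2 cap extremity edges
        A, B = g("A", "1 2"), g("B", "2 1")
        d = build_multi_relational(A, B, capped=True)
        assert sum(1 for e in d.edges if e.kind == CAP) == 4
        model = build_ilp(d)
        n_x = len(d.edges)
        assert model.y_offset == n_x
        assert model.n_vars == n_x + 3 * len(d.vertices) + len(model.t_cols) + len(
            model.s_cols
        )

    def test_no_circular_chromosomes_no_s_vars(self):
        A, B = make_fixture("fig1")
        model = build_ilp(build_multi_relational(A, B, capped=True))
        assert model.s_cols == {}

    def test_s_vars_only_for_fully_exclusive_circles(self):
        A = g("A", "( a b", "( 1 c")
        B = g("B", "1")
        model = build_ilp(build_multi_relational(A, B, capped=True))
        # (a b) qualifies; in (1 c) the occurrence of the common marker 1
        # carries no indel edge, so that chromosome can never be a singleton
        assert list(model.s_cols) == [("A", 0)]

    def test_s_vars_for_excess_copies(self):
        # both occurrences of 1 in A carry indel edges, so the circular
        # chromosome (1 c) could be entirely unmatched
        A = g("A", "( a b", "( 1 c", "1")
        B = g("B", "1")
        model = build_ilp(build_multi_relational(A, B, capped=True))
        assert list(model.s_cols) == [("A", 0), ("A", 1)]

    def test_deterministic_model(self):
        A, B = make_fixture("sec2_running")
        m1 = build_ilp(build_multi_relational(A, B, capped=True))
        m2 = build_ilp(build_multi_relational(A, B, capped=True))
        assert m1.names == m2.names
        assert m1.rows == m2.rows


class TestSolve:
    def test_identity_distance_zero(self):
        A, _ = make_fixture("sec2_running")
        sol = distance_natural(A, Genome("B", A.chromosomes))
        assert sol.status == "optimal" and sol.distance == 0

    def test_circular_singular_pair_matches_cycle_formula(self):
        A, B = g("A", "( 1 2 3 4"), g("B", "( 1 -3 -2 4")
        sol = distance_natural(A, B)
        assert sol.distance == distance_singular(A, B).distance

    def test_running_example(self):
        A, B = make_fixture("sec2_running")
        sol = distance_natural(A, B)
        assert sol.status == "optimal"
        assert sol.distance == min_over_matchings(A, B) == 6
        assert sol.n_star == 5 and sol.p_star == 1

    def test_matches_closed_form_on_singular_pairs(self, rng):
        for _ in range(25):
            A, B = random_singular_pair(rng, max_common=7, max_excl=3)
            assert distance_natural(A, B).distance == distance_singular(A, B).distance

    def test_matches_matching_oracle_on_natural_pairs(self, rng):
        for _ in range(15):
            A, B = random_natural_pair(rng, max_occ=7, max_copy=3)
            assert distance_natural(A, B).distance == min_over_matchings(A, B)

    def test_solution_decodes_to_consistent_decomposition(self, rng):
        """Recomputing the weight from the selected edges reproduces the
        objective: indel-free cycles - transitions/2 - circular singletons."""
        for _ in range(10):
            A, B = random_natural_pair(rng, max_occ=6, max_copy=2)
            sol = distance_natural(A, B)
            comps = sol.component_summary
            assert all(c.is_cycle for c in comps)
            w = sum(
                1 for c in comps if c.cls == "AB_cycle" and not c.indel_enclosing
            )
            w -= sum(c.aleph for c in comps) // 2
            w -= sum(1 for c in comps if c.cls == "circular_singleton")
            assert w == round(sol.objective)
            assert sol.distance == sol.n_star + sol.p_star - w

    def test_invariance_under_reversal_and_rotation(self):
        A, B = make_fixture("sec2_running")
        d0 = distance_natural(A, B).distance
        Arev = Genome("A", tuple(c.reversed() for c in A.chromosomes))
        assert distance_natural(Arev, B).distance == d0
        # rotating a circular chromosome is a no-op by canonicalization
        C = g("C", "( 1 2 3 4")
        C2 = g("C", "( 3 4 1 2")
        assert C.canonical() == C2.canonical()

    def test_no_common_markers(self):
        sol = distance_natural(g("A", "a b"), g("B", "c"))
        # delete segment "a b", insert "c" (under one matching of nothing)
        assert sol.distance == 2


class TestTheorem3:
    def test_optimal_capping_preserves_per_matching_distance(self, rng):
        """For every maximal sibling set S, the best capping set attains the
        uncapped weight: max_P w(Q[S,P]) = w(D[S]) + p*, i.e. the capped and
        uncapped distance formulas n* + p* - w(Q) and n* - w(D) coincide."""
        checked = 0
        while checked < 8:
            A, B = random_natural_pair(rng, max_occ=5, max_copy=2)
            if max(A.n_linear, B.n_linear) > 2:  # keep capping enumeration tiny
                continue
            d = build_multi_relational(A, B, capped=True)
            du = build_multi_relational(A, B, capped=False)
            p_star = d.census.p_star
            for matching in sibling_sets(d, bound=50):
                w_uncapped = _w_uncapped(du, A, B, matching)
                w_best = max(
                    _w_capped(d, matching, P) for P in capping_sets(d)
                )
                assert w_best == w_uncapped + p_star
            checked += 1


def _w_uncapped(diagram, A, B, matching) -> int:
    comps = decompose(diagram, consistent_decomposition(diagram, matching))
    c = sum(1 for k in comps if k.cls == "AB_cycle")
    i = sum(1 for k in comps if k.cls == "AB_path")
    lam = sum(indel_potential(k.Lambda) for k in comps)
    delta = greedy_delta(PathTypeCount.from_components(comps)).delta
    return c + i // 2 - lam + delta


def _w_capped(diagram, matching, capping) -> int:
    comps = decompose(diagram, consistent_decomposition(diagram, matching, capping))
    c = sum(1 for k in comps if k.cls == "AB_cycle")
    lam = sum(indel_potential(k.Lambda) for k in comps)
    return c - lam
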