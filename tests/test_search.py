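import math

import numpy as np
import pytest

from subpert import (
    AnnealParams,
    BruteForceCapError,
    ConfigurationError,
    EmptyPathwayError,
    Pathway,
    ScoredSubgraph,
    anneal_max_subgraph,
    brute_force_max_subgraph,
    initialize_subgraph,
    perturbation_score,
    propose_and_apply_move,
)
from conftest import random_instance

STAR = Pathway.from_edges("star", [("A", "B"), ("A", "C"), ("A", "D")])


class TestAnnealParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_start=1.0, t_end=2.0),
            dict(t_start=-1.0),
            dict(iteration_multiplier=0),
            dict(init_inclusion_prob=1.5),
            dict(seed=-3),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            AnnealParams(**kwargs)

    def test_cooling_closed_form(self):
        p = AnnealParams()
        n = p.n_iterations(37)
        assert p.t_start * p.cooling_factor(37) ** n == pytest.approx(
            p.t_end, rel=1e-9
        )


class TestInitialize:
    def test_extreme_probabilities(self, triangle):
        full = initialize_subgraph(triangle, AnnealParams(init_inclusion_prob=1.0))
        assert full.edges == triangle.interactions
        empty = initialize_subgraph(
            triangle, AnnealParams(init_inclusion_prob=0.0), scores={g: 0.0 for g in "ABC"}
        )
        assert empty.edges == frozenset() and empty.score == 0.0

    def test_mean_inclusion_fraction(self):
        """Binomial expectation: with p = 0.5 the mean included fraction over
        many seeds is 0.5 within 4 standard errors."""
        import networkx as nx

        g = nx.gnm_random_graph(40, 200, seed=0)
        pw = Pathway.from_edges("big", [(f"g{u}", f"g{v}") for u, v in g.edges])
        n_seeds, m = 200, pw.n_interactions
        fracs = [
            len(initialize_subgraph(pw, AnnealParams(seed=s)).edges) / m
            for s in range(n_seeds)
        ]
        se = 0.5 / math.sqrt(n_seeds * m)
        assert abs(np.mean(fracs) - 0.5) < 4 * se

    def test_empty_pathway(self):
        lonely = Pathway(name="x", genes=frozenset({"A"}), interactions=frozenset())
        with pytest.raises(EmptyPathwayError):
            initialize_subgraph(lonely, AnnealParams())


class TestProposeMove:
    def _current(self, edges):
        return ScoredSubgraph("star", frozenset(edges), float("nan"))

    def _force_element(self, pathway, element_index):
        """An rng whose next integers() call returns the wanted pool index."""

        class _Fixed:
            def integers(self, *a, **k):
                return element_index

        return _Fixed()

    def test_edge_toggle_removal(self):
        # pool: edges sorted first -> index 0 is ("A","B")
        out = propose_and_apply_move(
            self._current([("A", "B")]), STAR, self._force_element(STAR, 0)
        )
        assert out.edges == frozenset()

    def test_node_toggle_removes_all_incident(self):
        # index 3 = first node "A"
        out = propose_and_apply_move(
            self._current([("A", "B")]), STAR, self._force_element(STAR, 3)
        )
        assert out.edges == frozenset()

    def test_node_toggle_inserts_parent_edges(self):
        out = propose_and_apply_move(
            self._current([]), STAR, self._force_element(STAR, 3)
        )
        assert out.edges == STAR.interactions

    def test_leaf_node_toggle_only_touches_its_edge(self):
        # index 4 = node "B": absent -> insert only A-B
        out = propose_and_apply_move(
            self._current([]), STAR, self._force_element(STAR, 4)
        )
        assert out.edges == frozenset({("A", "B")})


class TestAnneal:
    def test_single_edge(self):
        pw = Pathway.from_edges("e", [("A", "B")])
        best = anneal_max_subgraph(pw, {"A": 2.0, "B": 2.0}, AnnealParams(seed=0))
        assert best.edges == pw.interactions
        assert best.score == pytest.approx(4 / math.sqrt(2), abs=1e-12)

    def test_two_disjoint_edges_optimum(self, two_disjoint_edges):
        pathway, z = two_disjoint_edges
        best = anneal_max_subgraph(pathway, z, AnnealParams(seed=0))
        assert best.edges == frozenset({("A", "B")})
        assert best.score == pytest.approx(6 / math.sqrt(2), abs=1e-12)

    def test_all_negative_returns_empty(self, triangle):
        z = {g: -5.0 for g in "ABC"}
        best = anneal_max_subgraph(triangle, z, AnnealParams(seed=1))
        assert best.edges == frozenset() and best.score == 0.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        pw, z = random_instance(rng)
        a = anneal_max_subgraph(pw, z, AnnealParams(seed=99))
        b = anneal_max_subgraph(pw, z, AnnealParams(seed=99))
        assert a.edges == b.edges and a.score == b.score

    def test_returned_score_matches_exact_formula(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            pw, z = random_instance(rng)
            best = anneal_max_subgraph(pw, z, AnnealParams(seed=int(rng.integers(100))))
            assert best.score == pytest.approx(
                perturbation_score(best.edges, z), abs=1e-9
            )

    def test_cooling_ends_at_t_end(self, triangle):
        diag = {}
        anneal_max_subgraph(
            triangle, {g: 0.0 for g in "ABC"}, AnnealParams(seed=0), diagnostics=diag
        )
        assert diag["final_temperature"] == pytest.approx(1e-5, rel=1e-9)
        assert diag["n_iterations"] == 300

    def test_monotone_reporting_in_iteration_budget(self):
        rng = np.random.default_rng(5)
        pw, z = random_instance(rng, max_edges=18)
        scores = [
            anneal_max_subgraph(
                pw, z, AnnealParams(seed=9, iteration_multiplier=mult)
            ).score
            for mult in (1, 5, 20, 100, 300)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_greedy_descent_empties_all_negative_start_full(self, triangle):
        """Acceptance contract at T -> 0+: with near-zero temperatures every
        worsening move is rejected, so from a full start with all-negative z
        the annealer can only improve, ending at the empty set."""
        z = {g: -1.0 for g in "ABC"}
        params = AnnealParams(
            t_start=1e-8, t_end=1e-9, init_inclusion_prob=1.0, seed=3,
            final_state=True,
        )
        final = anneal_max_subgraph(triangle, z, params)
        assert final.score >= 0.0
        assert final.edges == frozenset()

    def test_final_state_mode_never_beats_best_ever(self):
        rng = np.random.default_rng(8)
        pw, z = random_instance(rng)
        best = anneal_max_subgraph(pw, z, AnnealParams(seed=4))
        final = anneal_max_subgraph(pw, z, AnnealParams(seed=4, final_state=True))
        assert final.score <= best.score + 1e-12

    def test_quick_oracle_agreement(self):
        """Small-sample guard (the full 200-instance check lives in the
        acceptance suite): the annealer never exceeds the exhaustive optimum
        and usually attains it."""
        rng = np.random.default_rng(77)
        hits = 0
        for i in range(30):
            pw, z = random_instance(rng, max_edges=10)
            bf = brute_force_max_subgraph(pw, z)
            an = anneal_max_subgraph(pw, z, AnnealParams(seed=i))
            assert an.score <= bf.score + 1e-9
            hits += abs(an.score - bf.score) <= 1e-9
        assert hits >= 25


class TestBruteForce:
    def test_two_disjoint_edges(self, two_disjoint_edges):
        pathway, z = two_disjoint_edges
        best = brute_force_max_subgraph(pathway, z)
        assert best.edges == frozenset({("A", "B")})
        assert best.score == pytest.approx(6 / math.sqrt(2), abs=1e-12)

    def test_negative_single_edge_gives_empty(self):
        pw = Pathway.from_edges("e", [("A", "B")])
        best = brute_force_max_subgraph(pw, {"A": -1.0, "B": -1.0})
        assert best.edges == frozenset() and best.score == 0.0

    def test_triangle_all_ones(self, triangle):
        best = brute_force_max_subgraph(triangle, {g: 1.0 for g in "ABC"})
        assert best.edges == triangle.interactions
        assert best.score == pytest.approx(6 / math.sqrt(12), abs=1e-12)

    def test_cap_refusal(self):
        import networkx as nx

        g = nx.gnm_random_graph(10, 25, seed=1)
        pw = Pathway.from_edges("big", [(f"g{u}", f"g{v}") for u, v in g.edges])
        with pytest.raises(BruteForceCapError):
            brute_force_max_subgraph(pw, {n: 0.0 for n in pw.genes}, cap=20)

    def test_tie_break_prefers_fewest_edges(self):
        # both single edges score 0 exactly; empty set also scores 0 -> empty wins
        pw = Pathway.from_edges("t", [("A", "B"), ("C", "D")])
        z = {"A": 1.0, "B": -1.0, "C": 2.0, "D": -2.0}
        best = brute_force_max_subgraph(pw, z)
        assert best.edges == frozenset()
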