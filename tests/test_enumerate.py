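import sys

import numpy as np
import pytest

import bicliques as bc
from bicliques.enumerate import SearchState, expand_step
from bicliques.errors import ContractError, InputError
from bicliques.oracle import brute_force_bicliques


@pytest.fixture(params=["mbea", "imbea"])
def algorithm(request):
    return request.param


class TestEnumeration:
    def test_worked_example_two_bicliques(self, fig1, algorithm):
        result = bc.enumerate_maximal_bicliques(fig1, algorithm)
        assert result.count == 2
        assert set(result.bicliques) == {
            bc.Biclique(("u1", "u2"), ("v1", "v2", "v3")),
            bc.Biclique(("u3", "u4", "u5", "u6", "u7"), ("v5",)),
        }

    def test_complete_graph_single_biclique(self, k23, algorithm):
        result = bc.enumerate_maximal_bicliques(k23, algorithm)
        assert result.bicliques == [bc.Biclique(("a", "b"), ("x", "y", "z"))]

    def test_path_graph(self, path3, algorithm):
        result = bc.enumerate_maximal_bicliques(path3, algorithm)
        assert set(result.bicliques) == {
            bc.Biclique(("u1", "u2"), ("v1",)),
            bc.Biclique(("u2",), ("v1", "v2")),
        }

    def test_edgeless_graph_empty_result(self, algorithm):
        g = bc.BipartiteGraph("ab", "xy", [])
        assert bc.enumerate_maximal_bicliques(g, algorithm).count == 0

    @pytest.mark.parametrize("side", ["auto", "left", "right"])
    def test_side_choice_does_not_change_result(self, fig1, algorithm, side):
        result = bc.enumerate_maximal_bicliques(fig1, algorithm, side)
        assert result.count == 2

    def test_streaming_matches_collection(self, fig1, algorithm):
        streamed = []
        result = bc.enumerate_maximal_bicliques(
            fig1, algorithm, emit=streamed.append
        )
        assert result.bicliques is None
        assert result.count == 2
        assert streamed == bc.enumerate_maximal_bicliques(fig1, algorithm).bicliques

    def test_consumer_failure_propagates(self, fig1):
        class Boom(Exception):
            pass

        def consumer(b):
            raise Boom

        with pytest.raises(Boom):
            bc.enumerate_maximal_bicliques(fig1, emit=consumer)

    def test_invalid_arguments(self, fig1):
        with pytest.raises(InputError):
            bc.enumerate_maximal_bicliques(fig1, algorithm="newton")
        with pytest.raises(InputError):
            bc.enumerate_maximal_bicliques(fig1, side="top")

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_and_all_maximal(self, seed, algorithm):
        """Emitted set equals the subset-enumeration oracle; every emission
        is a complete, maximal biclique; none is emitted twice."""
        from conftest import random_cv, random_er

        g = random_er(seed) if seed % 2 else random_cv(seed)
        result = bc.enumerate_maximal_bicliques(g, algorithm)
        emitted = result.bicliques
        assert len(emitted) == len(set(emitted))
        assert set(emitted) == brute_force_bicliques(g)
        assert all(bc.is_maximal(g, b) for b in emitted)

    @pytest.mark.parametrize("seed", range(20))
    def test_node_count_bounds(self, seed, algorithm):
        from conftest import random_er

        g = random_er(seed, m_max=20, n_max=10)
        result = bc.enumerate_maximal_bicliques(g, algorithm)
        n = min(g.n_left, g.n_right)
        assert result.count <= result.nodes <= 2 ** max(n, 1)
        assert result.max_depth <= n

    def test_deterministic_emission_order(self, fig1, algorithm):
        runs = [
            [b.left for b in bc.enumerate_maximal_bicliques(fig1, algorithm)]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_deep_search_needs_no_interpreter_recursion(self):
        """On the complement-of-a-matching graph the leftmost branch dives
        one level per vertex; with the recursion limit pinned far below
        that depth the explicit-stack traversal must still proceed."""
        N = 150
        B = ~np.eye(N, dtype=bool)
        g = bc.BipartiteGraph.from_biadjacency(
            [f"u{i}" for i in range(N)], [f"v{i}" for i in range(N)], B
        )

        class Enough(Exception):
            pass

        seen = []

        def consumer(b):
            seen.append(b)
            if len(seen) >= N - 1:
                raise Enough

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(60)
        try:
            with pytest.raises(Enough):
                bc.enumerate_maximal_bicliques(g, "imbea", emit=consumer)
        finally:
            sys.setrecursionlimit(old)
        assert seen[-1].n_right == N - 1  # deepest seed reached


class TestInflationCorrespondence:
    @pytest.mark.parametrize("seed", range(15))
    def test_bicliques_biject_with_spanning_cliques(self, seed):
        from bicliques.oracle import brute_force_cliques
        from conftest import random_er

        g = random_er(seed, m_max=12, n_max=8)
        spanning = {
            c
            for c in brute_force_cliques(bc.inflate(g))
            if any(x.startswith("L:") for x in c)
            and any(x.startswith("R:") for x in c)
        }
        bicliques = {
            frozenset(f"L:{u}" for u in b.left) | frozenset(f"R:{v}" for v in b.right)
            for b in bc.enumerate_maximal_bicliques(g).bicliques
        }
        assert bicliques == spanning


class TestSelectCandidate:
    def _state(self, g, P):
        return SearchState(
            graph=g, L=frozenset(g.left_labels), R=frozenset(), P=P, Q=frozenset()
        )

    def test_imbea_picks_smallest_common_neighborhood(self, fig1):
        # degrees within L=U: v1,v2,v3 -> 2 and v5 -> 5
        state = self._state(fig1, ["v5", "v2", "v1"])
        assert bc.select_candidate(state, "imbea") == "v2"

    def test_mbea_picks_first_in_order(self, fig1):
        state = self._state(fig1, ["v5", "v2", "v1"])
        assert bc.select_candidate(state, "mbea") == "v5"

    def test_tie_broken_by_list_order(self, k23):
        state = self._state(k23, ["y", "x", "z"])
        assert bc.select_candidate(state, "imbea") == "y"

    def test_singleton(self, fig1):
        state = self._state(fig1, ["v5"])
        assert bc.select_candidate(state, "imbea") == "v5"

    def test_empty_candidate_set_is_contract_violation(self, fig1):
        with pytest.raises(ContractError):
            bc.select_candidate(self._state(fig1, []), "imbea")


class TestExpandStep:
    def test_root_expansion_absorbs_twin_candidates(self, fig1):
        """Expanding v1 at the root: L' = {u1,u2}; v2 and v3 share that
        whole neighborhood and are absorbed (S), v5 loses all neighbors
        and leaves P; the emitted biclique is already maximal."""
        state = SearchState(
            graph=fig1,
            L=frozenset(fig1.left_labels),
            R=frozenset(),
            P=["v1", "v2", "v3", "v5"],
            Q=frozenset(),
        )
        rec = expand_step(state, "v1")
        assert rec.L_new == {"u1", "u2"}
        assert rec.S == {"v2", "v3"}
        assert rec.S_eq == {"v2", "v3"}
        assert rec.R_new == {"v1", "v2", "v3"}
        assert rec.P_new == []
        assert rec.T == frozenset() and rec.is_maximal

    def test_former_candidate_prunes_branch(self, path3):
        # Q holds v1 whose neighborhood contains every L' candidate set
        state = SearchState(
            graph=path3,
            L=frozenset({"u1", "u2"}),
            R=frozenset(),
            P=["v2"],
            Q=frozenset({"v1"}),
        )
        rec = expand_step(state, "v2")
        assert rec.T == {"v1"}
        assert not rec.is_maximal

    def test_non_candidate_rejected(self, fig1):
        state = SearchState(
            graph=fig1, L=frozenset(fig1.left_labels), R=frozenset(),
            P=["v1"], Q=frozenset(),
        )
        with pytest.raises(ContractError):
            expand_step(state, "v5")


class TestMaximality:
    def test_worked_example(self, fig1):
        assert bc.is_maximal(fig1, bc.Biclique(("u1", "u2"), ("v1", "v2", "v3")))
        assert not bc.is_maximal(fig1, bc.Biclique(("u1",), ("v1",)))

    def test_whole_complete_graph(self, k23):
        assert bc.is_maximal(k23, bc.Biclique(("a", "b"), ("x", "y", "z")))

    def test_incomplete_biclique_is_contract_violation(self, fig1):
        with pytest.raises(ContractError):
            bc.is_maximal(fig1, bc.Biclique(("u1", "u3"), ("v1",)))


class TestExtremalSelection:
    def test_worked_example(self, fig1):
        result = bc.enumerate_maximal_bicliques(fig1)
        em = bc.edge_maximum(result)
        vm = bc.vertex_maximum(result)
        assert (em.n_edges, em.n_vertices) == (6, 5)
        assert (vm.n_vertices, vm.n_edges) == (6, 5)

    def test_complete_graph_is_its_own_maximum(self, k23):
        result = bc.enumerate_maximal_bicliques(k23)
        whole = bc.Biclique(("a", "b"), ("x", "y", "z"))
        assert bc.edge_maximum(result) == whole
        assert bc.vertex_maximum(result) == whole

    def test_ties_broken_by_canonical_order(self):
        a = bc.Biclique(("u2",), ("v2",))
        b = bc.Biclique(("u1",), ("v1",))
        assert bc.edge_maximum([a, b]) == b
        assert bc.vertex_maximum([a, b]) == b

    def test_empty_result_rejected(self):
        with pytest.raises(InputError):
            bc.edge_maximum([])
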