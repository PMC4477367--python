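"""Module score, annealing search, permutation calibration, merge/select."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_toy_network, toy_network
from survmod.modules import (
    AnnealConfig,
    CandidateModule,
    adjust_modules,
    exhaustive_max_module,
    merge_modules,
    module_score,
    null_score_distribution,
    permutation_adjust,
    select_candidates,
    simulated_annealing_search,
)


def path_network(node_weights, edge_weights):
    """Path graph a-b-c-... with the given weights."""
    names = [chr(ord("a") + i) for i in range(len(node_weights))]
    edges = {
        (names[i], names[i + 1]): w for i, w in enumerate(edge_weights)
    }
    return toy_network(dict(zip(names, node_weights)), edges)


class TestModuleScore:
    def test_closed_form_pair(self):
        net = toy_network({"a": 1.0, "b": 2.0}, {("a", "b"): 3.0})
        assert module_score(["a", "b"], net) == pytest.approx(6 / math.sqrt(3))

    def test_zero_weights_score_zero(self):
        net = toy_network({"a": 0.0, "b": 0.0}, {("a", "b"): 0.0})
        assert module_score(["a", "b"], net) == 0.0

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_tree_of_identical_nodes(self, k):
        """k nodes of weight w on a zero-weight path score k*w/sqrt(2k-1)."""
        w = 1.3
        net = path_network([w] * k, [0.0] * (k - 1))
        genes = [chr(ord("a") + i) for i in range(k)]
        assert module_score(genes, net) == pytest.approx(k * w / math.sqrt(2 * k - 1))

    def test_disconnected_set_rejected(self):
        net = path_network([1, 1, 1], [1, 1])
        with pytest.raises(ValueError, match="connected"):
            module_score(["a", "c"], net)

    def test_order_invariance(self):
        net = path_network([0.5, -1.0, 2.0], [1.0, 0.3])
        assert module_score(["a", "b", "c"], net) == module_score(["c", "a", "b"], net)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.1, 10.0), st.integers(0, 10_000))
    def test_scale_equivariance(self, c, seed):
        """Multiplying all weights by c > 0 multiplies every score by c."""
        rng = np.random.default_rng(seed)
        net = random_toy_network(8, 0.4, rng)
        genes = None
        for g, nbrs in net.adjacency.items():
            if nbrs:
                genes = [g, next(iter(nbrs))]
                break
        if genes is None:
            return
        scaled = toy_network(
            (net.node_weights * c).to_dict(),
            {
                (a, b): w * c
                for a, b, w in zip(net.edges["gene_a"], net.edges["gene_b"], net.edges["weight"])
            },
        )
        assert module_score(genes, scaled) == pytest.approx(
            c * module_score(genes, net), rel=1e-9
        )


class TestExhaustive:
    def test_triangle_prefers_best_pair(self):
        net = toy_network(
            {"a": 3.0, "b": 0.0, "c": 0.0},
            {("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0},
        )
        best = exhaustive_max_module(net, max_size=3)
        assert best.raw_score == pytest.approx(3 / math.sqrt(3))
        assert "a" in best.genes and best.n_genes == 2

    def test_all_negative_weights_pick_largest_adjacent_pair(self):
        net = path_network([-3.0, -1.0, -2.0, -5.0], [0.0, 0.0, 0.0])
        best = exhaustive_max_module(net, max_size=4)
        assert set(best.genes) == {"b", "c"}

    def test_large_network_guard(self):
        rng = np.random.default_rng(0)
        net = random_toy_network(16, 0.3, rng)
        with pytest.raises(ValueError, match="annealing"):
            exhaustive_max_module(net, max_size=4)


class TestSimulatedAnnealing:
    def test_recovers_full_path_when_favoured(self):
        net = path_network([2.0, 2.0, 2.0], [1.0, 1.0])
        cfg = AnnealConfig(n_iterations=500, n_restarts=3, max_module_size=3, seed=0)
        best_sa = simulated_annealing_search(net, cfg)[0]
        best_ex = exhaustive_max_module(net, max_size=3)
        assert set(best_sa.genes) == set(best_ex.genes) == {"a", "b", "c"}

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        net = random_toy_network(12, 0.3, rng)
        cfg = AnnealConfig(n_iterations=1000, n_restarts=4, seed=11)
        r1 = simulated_annealing_search(net, cfg)
        r2 = simulated_annealing_search(net, cfg)
        assert [m.genes for m in r1] == [m.genes for m in r2]

    def test_matches_exhaustive_on_small_graphs(self):
        """SA attains the enumerated optimum on most random 12-node graphs."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            net = random_toy_network(12, 0.3, rng)
            if net.edges.empty:
                wins += 1
                continue
            truth = exhaustive_max_module(net, max_size=6)
            cfg = AnnealConfig(n_iterations=2000, n_restarts=5, max_module_size=6, seed=seed)
            found = simulated_annealing_search(net, cfg)
            if found and found[0].raw_score >= truth.raw_score - 1e-9:
                wins += 1
        assert wins >= 19

    def test_beats_or_ties_greedy_hill_climbing(self):
        """SA's best never falls below a greedy expansion from the best edge."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            net = random_toy_network(12, 0.35, rng)
            if net.edges.empty:
                continue
            greedy = _greedy_best(net, max_size=6)
            cfg = AnnealConfig(n_iterations=2000, n_restarts=5, max_module_size=6, seed=seed)
            found = simulated_annealing_search(net, cfg)
            assert found[0].raw_score >= greedy - 1e-9


def _greedy_best(net, max_size):
    adj = net.adjacency
    best_overall = -np.inf
    edges = list(zip(net.edges["gene_a"], net.edges["gene_b"]))
    for a, b in edges:
        state = {a, b}
        score = module_score(state, net)
        best_overall = max(best_overall, score)
        while len(state) < max_size:
            frontier = {n for g in state for n in adj[g] if n not in state}
            if not frontier:
                break
            scored = [(module_score(state | {f}, net), f) for f in sorted(frontier)]
            new_score, pick = max(scored)
            if new_score <= score:
                break
            state.add(pick)
            score = new_score
            best_overall = max(best_overall, score)
    return best_overall


class TestPermutationAdjust:
    def test_score_at_null_mean_standardises_to_zero(self):
        net = path_network([1.0, 1.0, 1.0], [0.5, 0.5])
        mod = CandidateModule(genes=("a", "b"), raw_score=2.0, n_edges=1)
        nulls = np.array([1.0, 2.0, 3.0] * 100)
        adj = permutation_adjust(mod, net, null_scores=nulls)
        assert adj.adjusted_score == pytest.approx(0.0)
        assert adj.null_mean == pytest.approx(2.0)

    def test_empirical_p_uses_add_one_rule(self):
        net = path_network([1.0, 1.0], [0.5])
        mod = CandidateModule(genes=("a", "b"), raw_score=100.0, n_edges=1)
        adj = permutation_adjust(mod, net, null_scores=np.random.default_rng(0).normal(size=500))
        assert adj.empirical_p == pytest.approx(1 / 501)

    def test_null_sets_standardise_to_unit_scale(self, null_network):
        """Random 10-gene sets in a null network have adjusted scores with
        mean ~ 0 and sd ~ 1 (self-consistency of the standardisation)."""
        rng = np.random.default_rng(3)
        nulls = null_score_distribution(null_network, 10, 4000, rng)
        scored = null_score_distribution(null_network, 10, 200, np.random.default_rng(4))
        adjusted = (scored - nulls.mean()) / nulls.std(ddof=1)
        assert abs(adjusted.mean()) < 0.25
        assert 0.8 < adjusted.std(ddof=1) < 1.2

    def test_degenerate_null_raises(self):
        net = path_network([0.0, 0.0], [0.0])
        mod = CandidateModule(genes=("a", "b"), raw_score=0.0, n_edges=1)
        with pytest.raises(ValueError, match="degenerate"):
            permutation_adjust(mod, net, null_scores=np.zeros(200))


class TestMergeAndSelect:
    def _mods(self, gene_sets, net):
        return [
            CandidateModule(genes=tuple(sorted(s)), raw_score=0.0, n_edges=0)
            for s in gene_sets
        ]

    def test_identical_modules_collapse(self):
        net = path_network([1.0] * 4, [1.0] * 3)
        mods = self._mods([{"a", "b"}, {"a", "b"}], net)
        assert len(merge_modules(mods, net)) == 1

    def test_eighty_percent_overlap_triggers_merge(self):
        """|A|=|B|=12, |A∩B|=10 gives 10/12 > 0.8, so A and B merge."""
        names = [f"x{i:02d}" for i in range(14)]
        node_w = {n: 1.0 for n in names}
        edge_w = {(names[i], names[i + 1]): 1.0 for i in range(13)}
        net = toy_network(node_w, edge_w)
        a = set(names[:12])
        b = set(names[2:14])
        merged = merge_modules(self._mods([a, b], net), net)
        assert len(merged) == 1
        assert set(merged[0].genes) == a | b

    def test_disjoint_modules_unchanged_and_merge_idempotent(self):
        net = path_network([1.0] * 6, [1.0] * 5)
        mods = self._mods([{"a", "b"}, {"d", "e"}], net)
        once = merge_modules(mods, net)
        assert {frozenset(m.genes) for m in once} == {
            frozenset({"a", "b"}),
            frozenset({"d", "e"}),
        }
        twice = merge_modules(once, net)
        assert [m.genes for m in once] == [m.genes for m in twice]

    def test_selection_rank_and_p_filters(self):
        mods = [
            CandidateModule(
                genes=(f"g{i}", f"h{i}"),
                raw_score=float(i),
                n_edges=1,
                null_mean=0.0,
                null_sd=1.0,
                adjusted_score=float(i),
                empirical_p=0.001 if i != 99 else 0.5,
            )
            for i in range(100)
        ]
        selected, threshold = select_candidates(mods, top_fraction=0.01, p_cutoff=0.01)
        # rank filter keeps only the single top module, whose p=0.5 fails
        assert selected == []
        assert threshold == pytest.approx(99.0)
        mods[99] = CandidateModule(
            genes=mods[99].genes, raw_score=99.0, n_edges=1,
            null_mean=0.0, null_sd=1.0, adjusted_score=99.0, empirical_p=0.004,
        )
        selected, _ = select_candidates(mods, top_fraction=0.01, p_cutoff=0.01)
        assert len(selected) == 1 and selected[0].adjusted_score == 99.0

    def test_empty_input_selects_nothing(self):
        assert select_candidates([]) == ([], None)
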