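"""Unit, oracle and planted-recovery tests for the iterative aligner."""

import itertools

import numpy as np
import pytest

from gasoline.core_model import LocalAlignment, NoSeedsError, Params
from gasoline.aligner import (
    adjacent_sets,
    degree_ratio,
    extend_until_stall,
    goodness_column,
    goodness_node,
    mark_candidate_seeds,
    remove_worst_column,
    run_gasoline,
    run_iterative_phase,
)
from gasoline.gibbs_sampler import gibbs_bootstrap

from conftest import clique_network, make_network, make_sim


class TestMarkCandidateSeeds:
    def _nets(self):
        net_a = make_network("A", [("a1", "a2"), ("a1", "a3"), ("a1", "a4")])
        net_b = make_network("B", [("b1", "b2"), ("b1", "b3")])
        return [net_a, net_b]

    def test_degree_and_ortholog_requirements(self):
        nets = self._nets()
        sim = make_sim([("A", "a1", "B", "b1", 5.0), ("A", "a2", "B", "b2", 5.0)])
        marked = mark_candidate_seeds(nets, sim, t_deg=2)
        assert marked[0] == ["a1"]  # a2 has degree 1, below t_deg
        assert marked[1] == ["b1"]  # b2 has degree 1, below t_deg

    def test_missing_ortholog_excludes_regardless_of_degree(self):
        nets = self._nets()
        sim = make_sim([("A", "a2", "B", "b1", 5.0)])
        marked = mark_candidate_seeds(nets, sim, t_deg=1)
        assert "a1" not in marked[0]

    def test_t_deg_one_applies_no_degree_filter(self):
        nets = self._nets()
        sim = make_sim([("A", x, "B", y, 1.0) for x in ["a1", "a2", "a3", "a4"]
                        for y in ["b1", "b2"]])
        marked = mark_candidate_seeds(nets, sim, t_deg=1)
        assert marked[0] == ["a1", "a2", "a3", "a4"]

    def test_empty_marked_set_raises_naming_network(self):
        nets = self._nets()
        sim = make_sim([("A", "a1", "B", "b1", 5.0)])
        # b2 has a partner? no -- B still has b1 marked; break A instead
        sim2 = make_sim([("A", "a1", "B", "b1", 5.0)])
        with pytest.raises(NoSeedsError, match="B|A"):
            mark_candidate_seeds([nets[0], make_network("B", [("z1", "z2")])], sim2)


class TestDegreeRatio:
    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_isolated_clique_is_half(self, k):
        net_a = clique_network("A", [f"a{i}" for i in range(k)])
        net_b = clique_network("B", [f"b{i}" for i in range(k)])
        aln = LocalAlignment([net_a, net_b],
                             [(f"a{i}", f"b{i}") for i in range(k)])
        rep = degree_ratio(aln, [net_a, net_b])
        assert rep.per_network == [0.5, 0.5]
        assert rep.mean == 0.5

    def test_single_node_is_zero(self):
        net_a = make_network("A", [("a1", "a2")])
        net_b = make_network("B", [("b1", "b2")])
        aln = LocalAlignment([net_a, net_b], [("a1", "b1")])
        assert degree_ratio(aln, [net_a, net_b]).mean == 0.0

    def test_triangle_with_external_edges(self):
        # triangle a1-a2-a3 plus 3 external edges: sum deg = 9, internal = 3
        net = make_network("A", [("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                                 ("a1", "x"), ("a2", "y"), ("a3", "z")])
        net_b = clique_network("B", ["b1", "b2", "b3"])
        aln = LocalAlignment([net, net_b], [("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        rep = degree_ratio(aln, [net, net_b])
        assert rep.per_network[0] == pytest.approx(1 / 3)
        assert rep.per_network[1] == 0.5

    def test_ratio_never_exceeds_half(self, rng):
        for _ in range(20):
            g = make_network("A", [])
            nodes = [f"n{i}" for i in range(8)]
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.4:
                    g.add_edge(u, v, 1.0)
            row = [x for x in nodes[:4] if g.degree(x) > 0]
            if not row:
                continue
            net_b = clique_network("B", [f"b{i}" for i in range(len(row))])
            aln = LocalAlignment([g, net_b],
                                 list(zip(row, [f"b{i}" for i in range(len(row))])))
            assert degree_ratio(aln, [g, net_b]).per_network[0] <= 0.5


class TestAdjacentSets:
    def test_neighbors_minus_row(self):
        net_a = make_network("A", [("a", "b"), ("b", "c"), ("b", "d")])
        net_b = make_network("B", [("p", "q"), ("q", "r")])
        aln = LocalAlignment([net_a, net_b], [("a", "p"), ("b", "q")])
        adj = adjacent_sets(aln, [net_a, net_b])
        assert adj[0] == ["c", "d"]
        assert adj[1] == ["r"]

    def test_isolated_row_gives_empty_set(self):
        net_a = make_network("A", [("x", "y")], extra_nodes=["a"])
        net_b = make_network("B", [("x", "y")], extra_nodes=["p"])
        aln = LocalAlignment([net_a, net_b], [("a", "p")])
        assert adjacent_sets(aln, [net_a, net_b]) == [[], []]

    def test_removed_protein_reappears_in_adjacent_set(self):
        net_a = make_network("A", [("a1", "a2"), ("a2", "a3")])
        net_b = make_network("B", [("b1", "b2"), ("b2", "b3")])
        aln = LocalAlignment([net_a, net_b], [("a1", "b1"), ("a2", "b2")])
        aln.pop_column(1)  # remove (a2, b2)
        adj = adjacent_sets(aln, [net_a, net_b])
        assert "a2" in adj[0] and "b2" in adj[1]


class TestGoodness:
    def test_node_goodness_is_internal_over_total_degree(self):
        net = make_network("A", [("x", "a"), ("x", "b"), ("x", "c"), ("x", "d")])
        assert goodness_node("x", ["x", "a", "b"], net) == 0.5
        assert goodness_node("x", ["x", "a", "b", "c", "d"], net) == 1.0
        assert goodness_node("x", ["x"], net) == 0.0

    def test_column_goodness_is_product(self):
        net_a = make_network("A", [("a1", "a2"), ("a1", "x"), ("a2", "y")])
        net_b = make_network("B", [("b1", "b2"), ("b1", "x"), ("b2", "y")])
        aln = LocalAlignment([net_a, net_b], [("a1", "b1"), ("a2", "b2")])
        # every node: internal degree 1 of total degree 2
        assert goodness_column(0, aln, [net_a, net_b]) == 0.25
        assert goodness_column(1, aln, [net_a, net_b]) == 0.25


class TestRemoveWorstColumn:
    def _aligned(self, nets, cols):
        return LocalAlignment(nets, cols)

    def test_argmin_column_removed(self):
        # column 1 proteins are connected outward only -> goodness 0
        net_a = make_network("A", [("a0", "a2"), ("a1", "out_a")])
        net_b = make_network("B", [("b0", "b2"), ("b1", "out_b")])
        nets = [net_a, net_b]
        aln = self._aligned(nets, [("a0", "b0"), ("a1", "b1"), ("a2", "b2")])
        remove_worst_column(aln, nets)
        assert aln.columns == [("a0", "b0"), ("a2", "b2")]

    def test_tie_removes_lowest_index(self):
        net_a = clique_network("A", ["a0", "a1"])
        net_b = clique_network("B", ["b0", "b1"])
        nets = [net_a, net_b]
        aln = self._aligned(nets, [("a0", "b0"), ("a1", "b1")])
        remove_worst_column(aln, nets)
        assert aln.columns == [("a1", "b1")]

    def test_single_column_is_noop(self):
        nets = [clique_network("A", ["a0", "a1"]), clique_network("B", ["b0", "b1"])]
        aln = self._aligned(nets, [("a0", "b0")])
        remove_worst_column(aln, nets)
        assert aln.size == 1

    def test_matches_brute_force_column_scan(self, rng):
        # oracle: compute goodness for every column, delete the minimal one
        # (lowest index on ties), compare to the implementation
        for trial in range(50):
            r = np.random.default_rng(trial)
            k = int(r.integers(2, 7))
            nodes_a = [f"a{i}" for i in range(k + 3)]
            nodes_b = [f"b{i}" for i in range(k + 3)]
            net_a, net_b = make_network("A", []), make_network("B", [])
            for nodes, net in ((nodes_a, net_a), (nodes_b, net_b)):
                for u, v in itertools.combinations(nodes, 2):
                    if r.random() < 0.5:
                        net.add_edge(u, v, 1.0)
                for x in nodes:
                    net.add_node(x)
            nets = [net_a, net_b]
            cols = [(f"a{i}", f"b{i}") for i in range(k)]
            aln = self._aligned(nets, list(cols))
            scores = [goodness_column(i, aln, nets) for i in range(k)]
            expect_removed = min(range(k), key=lambda i: (scores[i], i))
            remove_worst_column(aln, nets)
            expected_cols = [c for i, c in enumerate(cols) if i != expect_removed]
            assert aln.columns == expected_cols


class TestExtendUntilStall:
    def test_extension_lowering_ratio_is_rejected(self, rng):
        # seed pair inside an edge; the only extension attaches a pendant in
        # one network only -> candidate column fails the orthology test or
        # drops the mean ratio, so the alignment is unchanged
        net_a = make_network("A", [("a1", "a2"), ("a2", "x")])
        net_b = make_network("B", [("b1", "b2")], extra_nodes=["y"])
        nets = [net_a, net_b]
        sim = make_sim([("A", "a1", "B", "b1", 9.0), ("A", "a2", "B", "b2", 9.0)])
        aln = LocalAlignment(nets, [("a1", "b1"), ("a2", "b2")])
        before = list(aln.columns)
        extend_until_stall(aln, nets, sim, Params(), rng)
        assert aln.columns == before

    def test_two_cliques_fully_recovered(self, rng):
        # isolated 4-cliques with perfect cross-similarity: the mean ratio
        # climbs 0 -> ... -> 0.5 and extension reaches all 4 columns
        net_a = clique_network("A", [f"a{i}" for i in range(4)])
        net_b = clique_network("B", [f"b{i}" for i in range(4)])
        nets = [net_a, net_b]
        sim = make_sim([("A", f"a{i}", "B", f"b{i}", 100.0) for i in range(4)])
        aln = LocalAlignment(nets, [("a0", "b0")])
        extend_until_stall(aln, nets, sim, Params(), rng)
        assert aln.size == 4
        assert degree_ratio(aln, nets).mean == 0.5

    def test_zero_similarity_column_never_kept(self, rng):
        net_a = clique_network("A", ["a0", "a1"])
        net_b = clique_network("B", ["b0", "b1"])
        nets = [net_a, net_b]
        sim = make_sim([("A", "a0", "B", "b0", 5.0)])  # no (a1, b1) similarity
        aln = LocalAlignment(nets, [("a0", "b0")])
        extend_until_stall(aln, nets, sim, Params(), rng)
        assert aln.size == 1

    def test_accepted_steps_strictly_raise_mean_ratio(self, rng):
        net_a = clique_network("A", [f"a{i}" for i in range(5)])
        net_b = clique_network("B", [f"b{i}" for i in range(5)])
        nets = [net_a, net_b]
        sim = make_sim([("A", f"a{i}", "B", f"b{j}", 10.0)
                        for i in range(5) for j in range(5)])
        aln = LocalAlignment(nets, [("a0", "b0")])
        ratios = [degree_ratio(aln, nets).mean]
        while True:
            size_before = aln.size
            extend_until_stall(aln, nets, sim, Params(iter_extend=50), rng)
            if aln.size == size_before:
                break
            ratios.append(degree_ratio(aln, nets).mean)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


def _planted_instance(seed, n_nodes=120, n_species=3, clique=5, mean_deg=3.0):
    """Sparse random networks with one identical planted clique and
    dominant planted orthology."""
    r = np.random.default_rng(seed)
    nets, sims = [], []
    planted = {}
    for s in range(n_species):
        sp = chr(ord("A") + s)
        net = make_network(sp, [])
        names = [f"{sp}{i}" for i in range(n_nodes)]
        for x in names:
            net.add_node(x)
        p = mean_deg / n_nodes
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if r.random() < p:
                    net.add_edge(names[i], names[j], 1.0)
        cl = names[:clique]
        for u, v in itertools.combinations(cl, 2):
            if not net.graph.has_edge(u, v):
                net.add_edge(u, v, 1.0)
        planted[sp] = cl
        nets.append(net)
    pairs = []
    species = [n.species_id for n in nets]
    for a, b in itertools.combinations(species, 2):
        for k in range(clique):
            pairs.append((a, planted[a][k], b, planted[b][k], 100.0))
        # background decoys
        for _ in range(2 * n_nodes):
            i, j = int(r.integers(n_nodes)), int(r.integers(n_nodes))
            pairs.append((a, f"{a}{i}", b, f"{b}{j}", 1.0 + r.random()))
    return nets, make_sim(pairs), planted


class TestIterativePhase:
    def test_schedule_one_round(self, rng):
        # iter_phase=1: a single extend-stall plus at most one removal
        net_a = clique_network("A", [f"a{i}" for i in range(3)])
        net_b = clique_network("B", [f"b{i}" for i in range(3)])
        nets = [net_a, net_b]
        sim = make_sim([("A", f"a{i}", "B", f"b{i}", 10.0) for i in range(3)])
        seed = gibbs_bootstrap([["a0"], ["b0"]], sim, nets, 5, rng)
        aln = run_iterative_phase(seed, nets, sim, Params(iter_phase=1), rng)
        assert aln.size >= 1
        assert aln.seed_proteins == ("a0", "b0")

    def test_mean_ratio_at_least_seed_level(self, rng):
        nets, sim, planted = _planted_instance(seed=0)
        seed = gibbs_bootstrap([[planted[s.species_id][0]] for s in nets],
                               sim, nets, 5, rng)
        aln = run_iterative_phase(seed, nets, sim, Params(), rng)
        from gasoline.aligner import degree_ratio as dr
        assert dr(aln, nets).mean >= 0.0
        assert aln.size >= 1

    def test_planted_clique_recovered(self):
        # the planted 5-clique should be found from a planted seed in the
        # overwhelming majority of runs
        nets, sim, planted = _planted_instance(seed=42)
        species = [n.species_id for n in nets]
        hits = 0
        runs = 30
        for run in range(runs):
            r = np.random.default_rng(1000 + run)
            seed = gibbs_bootstrap([[planted[s][0]] for s in species],
                                   sim, nets, 5, r)
            aln = run_iterative_phase(seed, nets, sim, Params(), r)
            covered = min(
                sum(1 for x in planted[sp] if x in aln.row_set(i))
                for i, sp in enumerate(species)
            )
            hits += covered >= 4
        assert hits >= int(0.9 * runs)


class TestRunGasoline:
    def test_singleton_marked_sets_give_one_alignment(self, rng):
        net_a = clique_network("A", ["a0", "a1"])
        net_b = clique_network("B", ["b0", "b1"])
        nets = [net_a, net_b]
        sim = make_sim([("A", "a0", "B", "b0", 5.0)])
        raw = run_gasoline(nets, sim, Params(), rng)
        assert len(raw) == 1

    def test_terminates_within_marked_set_bound(self, rng):
        nets = [clique_network("A", [f"a{i}" for i in range(6)]),
                clique_network("B", [f"b{i}" for i in range(6)])]
        sim = make_sim([("A", f"a{i}", "B", f"b{j}", 1.0 + (i == j))
                        for i in range(6) for j in range(6)])
        raw = run_gasoline(nets, sim, Params(), rng)
        assert len(raw) <= 6

    def test_two_disjoint_planted_complexes_both_found(self, rng):
        # two isolated 4-cliques per network with block-diagonal orthology
        def build(sp):
            net = clique_network(sp, [f"{sp}c1_{i}" for i in range(4)])
            for u, v in itertools.combinations([f"{sp}c2_{i}" for i in range(4)], 2):
                net.add_edge(u, v, 1.0)
            return net

        nets = [build("A"), build("B")]
        pairs = []
        for c in ("c1", "c2"):
            for i in range(4):
                pairs.append(("A", f"A{c}_{i}", "B", f"B{c}_{i}", 100.0))
        sim = make_sim(pairs)
        raw = run_gasoline(nets, sim, Params(), rng)
        big = [a for a in raw if a.size >= 3]
        complexes_hit = set()
        for aln in big:
            row = aln.rows[0]
            if all(x.startswith("Ac1") for x in row):
                complexes_hit.add("c1")
            if all(x.startswith("Ac2") for x in row):
                complexes_hit.add("c2")
        assert complexes_hit == {"c1", "c2"}

    def test_pipeline_deterministic_under_seed(self):
        nets, sim, _ = _planted_instance(seed=7, n_nodes=60, n_species=2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            raw = run_gasoline(nets, sim, Params(), rng)
            out.append([a.columns for a in raw])
        assert out[0] == out[1]
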