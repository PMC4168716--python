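"""Synthetic splicing graphs, read samplers, hardness gadget, regression
fixture family."""

import itertools

import networkx as nx
import pytest

from pathcover import (
    GadgetError,
    Instance,
    SimulationParams,
    check_feasibility,
    hardness_gadget,
    named_source_graph,
    overlap_chain_fixture,
    random_splicing_dag,
    sample_long_reads,
    sample_paired_reads,
    simulate_instance,
    solve_mpc_psc,
    solve_mpc_sc,
    verify_cover,
)
from pathcover.verify import contains_contiguous


class TestSplicingSimulation:
    def test_transcripts_are_paths_covering_all_nodes(self):
        params = SimulationParams(num_exons=12, num_transcripts=3, seed=1)
        dag, transcripts = random_splicing_dag(params)
        assert len(transcripts) == 3
        covered = set()
        for t in transcripts:
            assert dag.is_path(t)
            covered |= set(t)
        assert covered == dag.nodes

    def test_single_transcript_is_a_chain(self):
        params = SimulationParams(num_exons=6, num_transcripts=1, seed=3)
        dag, transcripts = random_splicing_dag(params)
        assert dag.m == dag.n - 1
        assert transcripts[0] == tuple(sorted(dag.nodes))

    def test_seeded_determinism(self):
        params = SimulationParams(seed=42)
        a = random_splicing_dag(params)
        b = random_splicing_dag(params)
        assert a[0].edges == b[0].edges and a[1] == b[1]

    def test_long_reads_are_transcript_windows(self):
        params = SimulationParams(num_exons=10, num_transcripts=2,
                                  num_long_reads=8, seed=7)
        dag, transcripts = random_splicing_dag(params)
        reads = sample_long_reads(dag, transcripts, params)
        assert len(reads) == 8
        for r in reads:
            assert dag.is_path(r)
            assert any(contains_contiguous(t, r) for t in transcripts)

    def test_read_longer_than_transcript_returns_whole_transcript(self):
        params = SimulationParams(num_exons=4, num_transcripts=1,
                                  read_length=99, num_long_reads=1, seed=0)
        dag, transcripts = random_splicing_dag(params)
        reads = sample_long_reads(dag, transcripts, params)
        assert reads[0] == transcripts[0]

    def test_zero_reads(self):
        params = SimulationParams(num_long_reads=0, num_pairs=0, seed=0)
        dag, transcripts = random_splicing_dag(params)
        assert sample_long_reads(dag, transcripts, params) == ()

    def test_pairs_are_ordered_disjoint_windows_of_one_transcript(self):
        params = SimulationParams(num_exons=15, num_transcripts=2,
                                  num_pairs=6, seed=11)
        dag, transcripts = random_splicing_dag(params)
        pairs = sample_paired_reads(dag, transcripts, params)
        assert len(pairs) == 6
        for a, b in pairs:
            host = next(
                t for t in transcripts
                if contains_contiguous(t, a) and contains_contiguous(t, b)
            )
            ia = host.index(a[0])
            ib = host.index(b[0])
            assert ia + len(a) <= ib  # ordered and disjoint
            assert not set(a) & set(b)

    def test_sampled_instances_are_feasible_and_recoverable(self):
        inst, transcripts = simulate_instance(SimulationParams(seed=5))
        check_feasibility(Instance(inst.dag.copy(), pairs=inst.pairs))
        sc_only = Instance(
            inst.dag.copy(),
            required_nodes=inst.required_nodes,
            subpaths=inst.subpaths,
        )
        sol = solve_mpc_sc(sc_only)
        assert sol.k <= len(transcripts)


class TestHardnessGadget:
    def test_k3_gadget_structure(self):
        g = hardness_gadget(named_source_graph("k3"))
        inst = g.instance
        # 3 vertex blocks + 3 edge blocks, 3 branches each, plus backbone/tail
        assert inst.c_pair == 3 * 2 + 3 * 3  # edge pairings + tail pairings
        assert inst.required_nodes == set() and inst.required_edges == set()
        for p, q in inst.pairs:
            assert inst.dag.is_path(p) and inst.dag.is_path(q)

    @pytest.mark.parametrize(
        "name, expected_k",
        [("k3", 3), ("c5", 3), ("k4", 4)],
    )
    def test_optimum_equals_source_chromatic_number(self, name, expected_k):
        g = hardness_gadget(named_source_graph(name))
        sol = solve_mpc_psc(g.instance, max_classes=40)
        assert sol.k == expected_k
        ok, violations = verify_cover(g.instance, sol.paths)
        assert ok, violations

    def test_bipartite_source_rejected(self):
        with pytest.raises(GadgetError):
            hardness_gadget(nx.cycle_graph(4))

    def test_isolated_vertex_rejected(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        g.add_node(3)
        with pytest.raises(GadgetError):
            hardness_gadget(g)

    def test_biconditional_on_small_source_graphs(self):
        """OPT(P(G)) = 3 iff chi(G) = 3, over all non-bipartite graphs on
        4 vertices plus a seeded sample on 5 vertices."""
        import random

        def brute_chromatic(g):
            n = g.number_of_nodes()
            nodes = sorted(g.nodes())
            for k in range(1, n + 1):
                for a in itertools.product(range(k), repeat=n):
                    assign = dict(zip(nodes, a))
                    if all(assign[u] != assign[v] for u, v in g.edges()):
                        return k
            return n

        cases = []
        all_pairs4 = list(itertools.combinations(range(4), 2))
        for mask in range(2 ** len(all_pairs4)):
            g = nx.Graph([all_pairs4[k] for k in range(len(all_pairs4)) if mask >> k & 1])
            g.add_nodes_from(range(4))
            if g.number_of_edges() and not nx.is_bipartite(g) and min(
                d for _, d in g.degree()
            ) > 0:
                cases.append(g)
        rng = random.Random(0)
        all_pairs5 = list(itertools.combinations(range(5), 2))
        attempts = 0
        while len([c for c in cases if c.number_of_nodes() == 5]) < 8 and attempts < 200:
            attempts += 1
            chosen = [p for p in all_pairs5 if rng.random() < 0.5]
            g = nx.Graph(chosen)
            g.add_nodes_from(range(5))
            if g.number_of_edges() and not nx.is_bipartite(g) and min(
                d for _, d in g.degree()
            ) > 0:
                cases.append(g)
        assert cases
        for g in cases:
            chi = brute_chromatic(g)
            sol = solve_mpc_psc(hardness_gadget(g).instance, max_classes=40)
            assert (sol.k == 3) == (chi == 3), (sorted(g.edges()), chi, sol.k)


class TestOverlapChainFixture:
    @pytest.mark.parametrize("depth", [2, 3, 4, 5])
    def test_constraints_are_valid_staggered_paths(self, depth):
        inst = overlap_chain_fixture(depth)
        assert len(inst.subpaths) == depth
        for p in inst.subpaths:
            assert inst.dag.is_path(p)

    def test_depth3_has_two_different_length_overlaps_of_p1(self):
        inst = overlap_chain_fixture(3)
        from pathcover import longest_suffix_prefix_overlap

        p1, p2, p3 = inst.subpaths
        assert longest_suffix_prefix_overlap(p1, p2) == 2
        assert longest_suffix_prefix_overlap(p1, p3) == 1

    def test_full_pipeline_is_optimal_on_all_depths(self):
        from pathcover import brute_force_cover

        for depth in (2, 3, 4, 5):
            inst = overlap_chain_fixture(depth)
            assert solve_mpc_sc(inst).k == brute_force_cover(inst).k == 1
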