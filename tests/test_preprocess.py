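"""The constraint-normalization and merge pipeline, and solution lifting."""

import pytest

from pathcover import (
    Dag,
    Instance,
    brute_force_cover,
    lift_solution,
    longest_suffix_prefix_overlap,
    merge_subpaths_iteratively,
    normalize_constraints,
    reduce_to_classic_mpc,
    remove_contained_subpaths,
    solve_mpc_sc,
    verify_cover,
)
from pathcover.preprocess import (
    subdivide_edge_constraints,
    subpaths_to_edge_constraints,
    transform_to_node_constraints,
)
from pathcover.simulate import random_constrained_instance


class TestNormalize:
    def test_edge_constraint_absorbs_its_endpoints(self, chain):
        inst = Instance(chain.copy(), required_nodes={"1", "2"},
                        required_edges={("1", "2")})
        norm, _ = normalize_constraints(inst)
        assert norm.required_nodes == set()
        assert norm.required_edges == {("1", "2")}

    def test_subpath_absorbs_nodes_and_edges(self, diamond):
        inst = Instance(
            diamond.copy(),
            required_nodes={"1", "2", "3", "4"},
            required_edges={("1", "2")},
            subpaths=(("1", "2", "4"),),
        )
        norm, _ = normalize_constraints(inst)
        assert norm.required_nodes == {"3"}
        assert norm.required_edges == set()

    def test_single_node_subpath_becomes_node_constraint(self, diamond):
        inst = Instance(diamond.copy(), subpaths=(("3",),))
        norm, trace = normalize_constraints(inst)
        assert norm.subpaths == ()
        assert norm.required_nodes == {"3"}
        assert trace.singleton_promotions == {"3"}


class TestContainment:
    @pytest.mark.parametrize(
        "family, expected",
        [
            (((("1", "2", "3")), ("2", "3")), (("1", "2", "3"),)),
            ((("1", "2"), ("1", "2")), (("1", "2"),)),
            ((("1", "2", "3"), ("3", "4", "5")), (("1", "2", "3"), ("3", "4", "5"))),
        ],
    )
    def test_examples(self, family, expected):
        assert remove_contained_subpaths(family) == expected


class TestOverlap:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            (("a", "b", "c"), ("b", "c", "d"), 2),
            (("a", "b"), ("c", "d"), 0),
            (("1", "2", "3"), ("3", "4", "5"), 1),
        ],
    )
    def test_examples(self, p, q, expected):
        assert longest_suffix_prefix_overlap(p, q) == expected


class TestMerge:
    def test_longest_first_merge_of_staggered_chain(self, chain5):
        family = (("1", "2", "3"), ("2", "3", "4"), ("3", "4", "5"))
        merged, log = merge_subpaths_iteratively(family, chain5)
        assert merged == (("1", "2", "3", "4", "5"),)
        assert [(i, j, ln) for i, j, ln, _ in log] == [(0, 1, 2), (0, 1, 2)]
        assert log[0][3] == ("1", "2", "3", "4")

    def test_disjoint_families_untouched(self):
        family = (("a", "b", "c"), ("d", "e", "f"))
        merged, log = merge_subpaths_iteratively(family)
        assert merged == family and log == []

    def test_single_merge(self, chain):
        merged, _ = merge_subpaths_iteratively((("1", "2"), ("2", "3")), chain)
        assert merged == (("1", "2", "3"),)

    def test_idempotent(self, chain5):
        family = (("1", "2", "3"), ("3", "4", "5"))
        once, _ = merge_subpaths_iteratively(family, chain5)
        twice, log = merge_subpaths_iteratively(once, chain5)
        assert twice == once and log == []
        # no residual overlaps or containments
        for p in twice:
            for q in twice:
                if p != q:
                    assert longest_suffix_prefix_overlap(p, q) == 0


class TestShortcutAndSubdivision:
    def test_subpath_becomes_shortcut_edge(self, diamond):
        occ, new_keys, shortcut = subpaths_to_edge_constraints(
            diamond, (("1", "2", "4"),)
        )
        assert ("1", "4", ("sub", 0)) in occ
        assert shortcut[("sub", 0)] == ("1", "2", "4")
        assert len(new_keys) == 1

    def test_parallel_shortcuts_get_distinct_midpoints(self, diamond):
        # two constraints with identical endpoints -> two parallel edges
        occ, new_keys, shortcut = subpaths_to_edge_constraints(
            diamond, (("1", "2", "4"), ("1", "3", "4"))
        )
        dag2, midmap, required = subdivide_edge_constraints(
            diamond.nodes, occ, new_keys, shortcut
        )
        assert len(midmap) == 2 and len(required) == 2
        # simple again: no duplicate edges possible in a set-backed Dag
        mids = sorted(midmap)
        for mid in mids:
            assert ("1", mid) in dag2.edges and (mid, "4") in dag2.edges

    def test_empty_family_is_identity(self, diamond):
        occ, new_keys, shortcut = subpaths_to_edge_constraints(diamond, ())
        dag2, midmap, _ = subdivide_edge_constraints(
            diamond.nodes, occ, new_keys, shortcut
        )
        assert dag2.edges == diamond.edges and midmap == {}


class TestReduceAndLift:
    def test_diamond_with_subpath_reduces_to_two_incomparable_nodes(self, diamond):
        inst = Instance(
            diamond.copy(),
            required_nodes={"1", "2", "3", "4"},
            subpaths=(("1", "2", "4"),),
        )
        reduced, trace = reduce_to_classic_mpc(inst)
        mids = set(trace.midpoint_map)
        assert len(mids) == 1
        assert reduced.nodes == {"3"} | mids
        assert reduced.edges == set()  # 3 and the midpoint are incomparable

    def test_chain_required_endpoints_keeps_closure_edge(self, chain):
        inst = Instance(chain.copy(), required_nodes={"1", "3"})
        reduced, trace = reduce_to_classic_mpc(inst)
        assert reduced.nodes == {"1", "3"}
        assert reduced.edges == {("1", "3")}
        sol = lift_solution([("1", "3")], trace)
        assert sol.paths == [("1", "2", "3")]

    def test_empty_constraints_reduce_to_empty_graph(self, diamond):
        inst = Instance(diamond.copy())
        reduced, trace = reduce_to_classic_mpc(inst)
        assert reduced.nodes == set()
        sol = lift_solution([], trace)
        assert sol.paths == []

    def test_lift_expands_midpoint_to_subpath(self, diamond):
        inst = Instance(
            diamond.copy(),
            required_nodes={"1", "2", "3", "4"},
            subpaths=(("1", "2", "4"),),
        )
        reduced, trace = reduce_to_classic_mpc(inst)
        mid = next(iter(trace.midpoint_map))
        sol = lift_solution([(mid,), ("3",)], trace)
        assert ("1", "2", "4") in sol.paths
        ok, _ = verify_cover(inst, sol.paths)
        assert ok

    def test_trace_serializes(self, diamond):
        inst = Instance(diamond.copy(), required_nodes={"3"},
                        subpaths=(("1", "2", "4"),))
        _, trace = reduce_to_classic_mpc(inst)
        doc = trace.to_json_dict()
        assert doc["required_after"] and "midpoints" in doc


class TestOptimumPreservation:
    """The merge stages preserve the optimum (checked against the oracle)."""

    @pytest.mark.parametrize("seed", range(25))
    def test_merged_pipeline_matches_oracle(self, seed):
        inst = random_constrained_instance(n=5 + seed % 4, seed=seed, max_subpaths=4)
        sol = solve_mpc_sc(inst)
        ref = brute_force_cover(inst)
        assert ref is not None
        assert sol.k == ref.k
        ok, violations = verify_cover(inst, sol.paths)
        assert ok, violations

    @pytest.mark.parametrize("seed", range(10))
    def test_steps_one_to_four_preserve_satisfiability(self, seed):
        """A cover of the transformed constraints still satisfies the
        original ones (the merged family dominates the original)."""
        inst = random_constrained_instance(n=6, seed=100 + seed, max_subpaths=4)
        trace = transform_to_node_constraints(inst)
        merged = trace.final_subpaths
        cover_like = Instance(inst.dag.copy(), subpaths=merged)
        ref = brute_force_cover(cover_like)
        ok, violations = verify_cover(
            Instance(inst.dag.copy(), subpaths=inst.subpaths), ref.paths
        )
        assert ok, violations
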