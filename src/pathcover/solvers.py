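"""Public solvers for the path-cover problem family.

* :func:`solve_mpc` -- classical (optionally weighted) minimum path cover of
  a node subset of a DAG.
* :func:`solve_mpc_sc` -- minimum path cover with subpath constraints, by
  reduction to classical MPC (preprocessing stages 1-8, solve, lift).
* :func:`solve_mw_mpc_sc` -- minimum-weight minimum path cover with subpath
  constraints and start/end node sets, by min-cost circulation
  (stages 1-6 only; coverage becomes flow lower bounds).

Every solution is verified against the original constraints before it is
returned.
"""

from __future__ import annotations

from typing import Optional, Set

from .errors import ValidationError
from .flow import (
    build_mincost_network,
    build_minflow_network,
    decompose_flow_to_paths,
    min_cost_circulation,
    min_flow,
    network_path_to_node_path,
)
from .graph import CoverSolution, Dag, Instance, NodeId, cover_weight, path_weight
from .preprocess import (
    expand_midpoints,
    lift_solution,
    reduce_to_classic_mpc,
    transform_to_node_constraints,
)
from .verify import verify_cover


def solve_mpc(
    dag: Dag,
    required: Optional[Set[NodeId]] = None,
    weighted: bool = False,
    starts: Optional[Set[NodeId]] = None,
    ends: Optional[Set[NodeId]] = None,
) -> CoverSolution:
    """Minimum path cover of ``required`` (default: all nodes) in a DAG.

    Non-required nodes may be used as through-nodes.  With ``weighted``,
    among minimum-cardinality covers one of minimum total edge weight is
    returned (each path's edges summed, shared edges counted per use), and
    paths are constrained to start in ``starts`` / end in ``ends``
    (defaulting to the sources/sinks of the graph).
    """
    required = set(dag.nodes) if required is None else {str(v) for v in required}
    if not required <= dag.nodes:
        raise ValidationError("required nodes must belong to the graph")
    if weighted:
        inst = Instance(
            dag.copy(),
            required_nodes=required,
            starts=set(starts) if starts else set(dag.sources()),
            ends=set(ends) if ends else set(dag.sinks()),
        )
        sol = solve_mw_mpc_sc(inst)
        sol.problem = "mpc"
        return sol
    net, _split = build_minflow_network(dag, required)
    flow = min_flow(net)
    paths = [network_path_to_node_path(p) for p in decompose_flow_to_paths(flow)]
    ok, violations = verify_cover(Instance(dag.copy(), required_nodes=required), paths)
    if not ok:  # pragma: no cover - bug guard
        raise AssertionError(f"unverified MPC solution: {violations}")
    return CoverSolution(
        paths=paths,
        total_weight=cover_weight(dag, paths),
        problem="mpc",
        satisfied=True,
    )


def solve_mpc_sc(instance: Instance, engine: str = "flow") -> CoverSolution:
    """Minimum path cover with subpath constraints (unweighted).

    Runs preprocessing stages 1-8, solves classical MPC on the reduced graph
    (with the min-flow engine, or ``engine="matching"`` for the
    Fulkerson-style oracle), and lifts the cover back through the trace.
    The lift re-verifies all original constraints.
    """
    if instance.pairs:
        raise ValidationError("instance has paired constraints; use solve_mpc_psc")
    reduced, trace = reduce_to_classic_mpc(instance)
    if not reduced.nodes:
        return lift_solution([], trace, problem="mpc-sc")
    if engine == "matching":
        from .oracle import mpc_by_matching

        reduced_paths = mpc_by_matching(reduced).paths
    elif engine == "flow":
        net, _split = build_minflow_network(reduced, set(reduced.nodes))
        flow = min_flow(net)
        reduced_paths = [
            network_path_to_node_path(p) for p in decompose_flow_to_paths(flow)
        ]
    else:
        raise ValueError(f"unknown engine {engine!r}")
    sol = lift_solution(reduced_paths, trace, problem="mpc-sc")
    return sol


def solve_mw_mpc_sc(instance: Instance) -> CoverSolution:
    """Minimum-weight minimum path cover with subpath constraints.

    Preprocessing stages 1-6 model every subpath/edge constraint as a
    required midpoint node; coverage requirements then become flow lower
    bounds in a min-cost circulation whose return-arc cost enforces
    lexicographic (path count, then total weight) optimality.  Paths start
    in S and end in T.
    """
    if instance.pairs:
        raise ValidationError("instance has paired constraints; use solve_mpc_psc")
    dag = instance.dag
    starts = set(instance.starts) if instance.starts else set(dag.sources())
    ends = set(instance.ends) if instance.ends else set(dag.sinks())
    trace = transform_to_node_constraints(instance)
    tdag = trace.transformed_dag
    midpoint_costs = {}
    for mid, (kind, payload) in trace.midpoint_map.items():
        if kind == "subpath":
            midpoint_costs[mid] = path_weight(dag, payload)
        else:  # original required edge: keep its weight on the midpoint arc
            midpoint_costs[mid] = dag.edge_weight(tuple(payload))
    net, _split = build_mincost_network(
        tdag, trace.required_after, starts, ends, midpoint_costs
    )
    circulation = min_cost_circulation(net)
    transformed_paths = [
        network_path_to_node_path(p) for p in decompose_flow_to_paths(circulation)
    ]
    lifted = [expand_midpoints(p, trace.midpoint_map) for p in transformed_paths]
    check = instance.copy()
    check.starts, check.ends = starts, ends
    ok, violations = verify_cover(check, lifted, require_st=True)
    if not ok:  # pragma: no cover - bug guard
        raise AssertionError(f"unverified weighted solution: {violations}")
    return CoverSolution(
        paths=lifted,
        total_weight=cover_weight(dag, lifted),
        problem="mw-mpc-sc",
        satisfied=True,
    )
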