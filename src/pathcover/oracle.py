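"""Independent ground-truth solvers used to cross-check the flow pipeline.

* :func:`mpc_by_matching` -- the classical Dilworth/Fulkerson construction:
  a maximum matching in a bipartite graph on two copies of V with the
  transitive-closure edges yields a cover of n - |matching| paths.
* :func:`max_antichain` -- a maximum set of pairwise-unreachable nodes, by
  exhaustive branch-and-bound for small graphs or by a verified Koenig
  vertex-cover construction for larger ones.
* :func:`brute_force_cover` -- exhaustive enumeration over all simple paths,
  exact for every problem variant on tiny instances.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import LimitError
from .graph import (
    CoverSolution,
    Dag,
    Instance,
    NodeId,
    Path,
    Reachability,
    cover_weight,
    transitive_closure_with_witness,
)
from .verify import verify_cover


def mpc_by_matching(dag: Dag) -> CoverSolution:
    """Minimum path cover via maximum bipartite matching on the closure.

    Matched pairs (u, v) chain into paths of the closure; closure edges are
    then expanded through their witness paths so the output paths live in
    the input graph.
    """
    if not dag.nodes:
        return CoverSolution(paths=[], problem="mpc")
    closure, witness = transitive_closure_with_witness(dag)
    B = nx.Graph()
    left = {v: ("L", v) for v in dag.nodes}
    right = {v: ("R", v) for v in dag.nodes}
    B.add_nodes_from(left.values(), bipartite=0)
    B.add_nodes_from(right.values(), bipartite=1)
    for u, v in closure.edges:
        B.add_edge(left[u], right[v])
    matching = nx.bipartite.hopcroft_karp_matching(B, top_nodes=set(left.values()))
    succ = {}
    has_pred = set()
    for node, mate in matching.items():
        if node[0] == "L":
            succ[node[1]] = mate[1]
            has_pred.add(mate[1])
    paths: List[Path] = []
    for v in sorted(dag.nodes - has_pred):
        chain = [v]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        expanded: List[NodeId] = [chain[0]]
        for a, b in zip(chain, chain[1:]):
            expanded.extend(witness[(a, b)][1:])
        paths.append(tuple(expanded))
    sol = CoverSolution(
        paths=paths, total_weight=cover_weight(dag, paths), problem="mpc"
    )
    ok, violations = verify_cover(Instance(dag.copy(), required_nodes=set(dag.nodes)), paths)
    assert ok, violations
    return sol


def max_antichain(dag: Dag, enumeration_limit: int = 20) -> Set[NodeId]:
    """A maximum antichain (pairwise-unreachable node set).

    Up to ``enumeration_limit`` nodes: exhaustive branch-and-bound over
    subsets.  Beyond: the Koenig vertex cover of the closure bipartite graph
    yields a candidate of provably optimal size n - |max matching|, which is
    verified to be a genuine antichain before being returned.
    """
    if not dag.nodes:
        return set()
    reach = Reachability(dag)
    nodes = sorted(dag.nodes)
    if len(nodes) <= enumeration_limit:
        comparable = {
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and (reach(u, v) or reach(v, u))
        }
        best: List[NodeId] = []

        def extend(candidates: List[NodeId], chosen: List[NodeId]) -> None:
            nonlocal best
            if len(chosen) + len(candidates) <= len(best):
                return
            if not candidates:
                if len(chosen) > len(best):
                    best = list(chosen)
                return
            head, rest = candidates[0], candidates[1:]
            extend(
                [v for v in rest if (head, v) not in comparable],
                chosen + [head],
            )
            extend(rest, chosen)

        extend(nodes, [])
        return set(best)
    # Koenig construction on the closure bipartite graph, then verify.
    closure, _ = transitive_closure_with_witness(dag)
    B = nx.Graph()
    top = {("L", v) for v in nodes}
    B.add_nodes_from(top, bipartite=0)
    B.add_nodes_from((("R", v) for v in nodes), bipartite=1)
    for u, v in closure.edges:
        B.add_edge(("L", u), ("R", v))
    matching = nx.bipartite.hopcroft_karp_matching(B, top_nodes=top)
    cover = nx.bipartite.to_vertex_cover(B, matching, top_nodes=top)
    antichain = {v for v in nodes if ("L", v) not in cover and ("R", v) not in cover}
    expected = len(nodes) - len(matching) // 2
    if len(antichain) != expected:  # pragma: no cover - certificate guard
        raise LimitError("Koenig antichain certificate failed")
    for u, v in combinations(sorted(antichain), 2):
        if reach(u, v) or reach(v, u):  # pragma: no cover - certificate guard
            raise LimitError("Koenig antichain contains comparable nodes")
    return antichain


def all_simple_directed_paths(dag: Dag) -> List[Path]:
    """Every directed path (length >= 1 node) of a small DAG, sorted."""
    succ = {v: dag.successors(v) for v in dag.nodes}
    out: List[Path] = []

    def extend(path: List[NodeId]) -> None:
        out.append(tuple(path))
        for w in succ[path[-1]]:
            path.append(w)
            extend(path)
            path.pop()

    for v in sorted(dag.nodes):
        extend([v])
    return sorted(out)


def _paths_between(dag: Dag, starts: Set[NodeId], ends: Set[NodeId]) -> List[Path]:
    """All simple paths starting in ``starts`` and ending in ``ends``."""
    succ = {v: dag.successors(v) for v in dag.nodes}
    out: List[Path] = []

    def extend(path: List[NodeId]) -> None:
        if path[-1] in ends:
            out.append(tuple(path))
        for w in succ[path[-1]]:
            path.append(w)
            extend(path)
            path.pop()

    for v in sorted(starts):
        extend([v])
    return sorted(out)


def brute_force_cover(
    instance: Instance,
    k_max: Optional[int] = None,
    weighted: bool = False,
    max_nodes: int = 10,
    max_paths: int = 2500,
) -> Optional[CoverSolution]:
    """Exact cover by exhaustive enumeration (test oracle; tiny inputs only).

    Tries k = 0, 1, 2, ... subsets of all simple paths until one satisfies
    every constraint of the instance; with ``weighted`` (or when the
    instance carries S/T sets) the minimum total weight among all covers of
    the first feasible cardinality is returned.  Returns None when no cover
    of size <= k_max exists (possible only with paired constraints).
    """
    dag = instance.dag
    if dag.n > max_nodes:
        raise LimitError(f"brute force limited to {max_nodes} nodes (got {dag.n})")
    restrict_st = instance.weighted_fields_present()
    if restrict_st:
        starts = instance.starts or set(dag.sources())
        ends = instance.ends or set(dag.sinks())
        candidates = _paths_between(dag, starts, ends)
    else:
        # Unweighted: any cover extends to one of maximal (source-to-sink)
        # paths without changing cardinality or breaking a constraint.
        candidates = _paths_between(dag, set(dag.sources()), set(dag.sinks()))
    if len(candidates) > max_paths:
        raise LimitError(f"too many candidate paths ({len(candidates)})")
    k_cap = dag.n if k_max is None else k_max
    problem = "mpc-psc" if instance.pairs else ("mw-mpc-sc" if restrict_st else "mpc-sc")
    for k in range(0, k_cap + 1):
        feasible: List[Tuple[Path, ...]] = []
        for combo in combinations(candidates, k):
            ok, _ = verify_cover(instance, combo, require_st=restrict_st)
            if ok:
                if not (weighted or restrict_st):
                    return CoverSolution(
                        paths=list(combo),
                        total_weight=cover_weight(dag, combo),
                        problem=problem,
                    )
                feasible.append(combo)
        if feasible:
            best = min(feasible, key=lambda c: (cover_weight(dag, c), c))
            return CoverSolution(
                paths=list(best),
                total_weight=cover_weight(dag, best),
                problem=problem,
            )
    return None
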