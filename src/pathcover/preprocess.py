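"""Reduction of subpath-constrained path cover to classical path cover.

The pipeline turns an :class:`~pathcover.graph.Instance` with required nodes
V', required edges E' and subpath constraints into a plain DAG whose
classical minimum path cover has the same optimum, and lifts covers of the
reduced graph back to the original one.  The stages are:

1-2. normalization: drop from V'/E' anything already covered by an E' edge
     or a subpath constraint;
3.   drop subpath constraints contained in another;
4.   iteratively merge constraints whose suffix equals another's prefix,
     longest overlap first (this is the stage whose omission makes earlier
     reductions incorrect);
5.   replace each remaining subpath by a shortcut edge constraint;
6.   subdivide each edge constraint with a required midpoint node;
7.   take the transitive closure (with witness paths);
8.   restrict to the required nodes.

A :class:`ReductionTrace` records every transformation so that
:func:`lift_solution` can revert them in reverse order and re-verify the
result against the *original* constraints.

The weighted solver uses only stages 1-6 (coverage becomes flow lower
bounds there), via :func:`transform_to_node_constraints`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .errors import LiftError, MergeError
from .graph import (
    CoverSolution,
    Dag,
    Edge,
    Instance,
    NodeId,
    Path,
    cover_weight,
    transitive_closure_with_witness,
)
from .verify import verify_cover

# A midpoint stands for an original required edge or for a whole subpath.
MidpointOrigin = Tuple[str, object]  # ("edge", (u, v)) | ("subpath", Path)


@dataclass
class ReductionTrace:
    """Replayable record of the reduction stages, sufficient for lifting."""

    original: Instance
    dropped_nodes: Set[NodeId] = field(default_factory=set)
    dropped_edges: Set[Edge] = field(default_factory=set)
    singleton_promotions: Set[NodeId] = field(default_factory=set)
    contained_removed: List[Path] = field(default_factory=list)
    merge_log: List[Tuple[int, int, int, Path]] = field(default_factory=list)
    final_subpaths: Tuple[Path, ...] = ()
    shortcut_map: Dict[object, Path] = field(default_factory=dict)
    midpoint_map: Dict[NodeId, MidpointOrigin] = field(default_factory=dict)
    transformed_dag: Optional[Dag] = None
    required_after: Set[NodeId] = field(default_factory=set)
    closure_witness: Dict[Edge, Path] = field(default_factory=dict)
    removed_nodes: Set[NodeId] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        """Serializable summary for debugging."""
        return {
            "dropped_nodes": sorted(self.dropped_nodes),
            "dropped_edges": sorted(map(list, self.dropped_edges)),
            "singleton_promotions": sorted(self.singleton_promotions),
            "contained_removed": [list(p) for p in self.contained_removed],
            "merge_log": [
                {"i": i, "j": j, "len": ln, "merged": list(p)}
                for i, j, ln, p in self.merge_log
            ],
            "final_subpaths": [list(p) for p in self.final_subpaths],
            "midpoints": {
                v: {"kind": kind, "payload": list(payload)}
                for v, (kind, payload) in sorted(self.midpoint_map.items())
            },
            "required_after": sorted(self.required_after),
            "removed_nodes": sorted(self.removed_nodes),
        }


def normalize_constraints(instance: Instance) -> Tuple[Instance, ReductionTrace]:
    """Stages 1-2 plus the degenerate single-node-subpath rule.

    Single-node subpaths become plain node constraints.  Then every endpoint
    of an E' edge leaves V', and every node/edge lying on a subpath
    constraint leaves V'/E'.
    """
    trace = ReductionTrace(original=instance.copy())
    v_req = set(instance.required_nodes)
    e_req = set(instance.required_edges)
    subpaths: List[Path] = []
    for p in instance.subpaths:
        if len(p) == 1:
            trace.singleton_promotions.add(p[0])
            v_req.add(p[0])
        else:
            subpaths.append(p)
    for u, v in e_req:
        trace.dropped_nodes |= {u, v} & v_req
        v_req -= {u, v}
    for p in subpaths:
        on_path = set(p)
        trace.dropped_nodes |= on_path & v_req
        v_req -= on_path
        for e in zip(p, p[1:]):
            if e in e_req:
                trace.dropped_edges.add(e)
                e_req.discard(e)
    normalized = Instance(
        instance.dag.copy(),
        v_req,
        e_req,
        tuple(subpaths),
        instance.pairs,
        set(instance.starts),
        set(instance.ends),
    )
    return normalized, trace


def _contains_contiguous(big: Path, small: Path) -> bool:
    if len(small) > len(big):
        return False
    return any(big[k : k + len(small)] == small for k in range(len(big) - len(small) + 1))


def remove_contained_subpaths(subpaths: Sequence[Path]) -> Tuple[Path, ...]:
    """Stage 3: drop constraints contained in another; deduplicate (keep the
    lowest index)."""
    kept: List[Path] = []
    for i, p in enumerate(subpaths):
        redundant = False
        for j, q in enumerate(subpaths):
            if i == j:
                continue
            if p == q:
                if j < i:
                    redundant = True
                    break
            elif _contains_contiguous(q, p):
                redundant = True
                break
        if not redundant:
            kept.append(p)
    return tuple(kept)


def longest_suffix_prefix_overlap(p: Path, q: Path) -> int:
    """Largest len >= 1 with suffix(p, len) == prefix(q, len), else 0.

    Overlaps equal to a whole constraint are containments (already removed),
    so only proper overlaps, len < min(|p|, |q|), are considered.
    """
    for ln in range(min(len(p), len(q)) - 1, 0, -1):
        if p[-ln:] == q[:ln]:
            return ln
    return 0


def merge_subpaths_iteratively(
    subpaths: Sequence[Path], dag: Optional[Dag] = None
) -> Tuple[Tuple[Path, ...], List[Tuple[int, int, int, Path]]]:
    """Stage 4: merge suffix/prefix-overlapping constraints, longest first.

    Ties break by smallest first index, then smallest second index; the
    merged path replaces the earlier of the two positions.  Afterwards the
    family is defensively re-checked for containments (a violation signals
    corrupted state, not valid input).
    """
    family: List[Path] = list(subpaths)
    log: List[Tuple[int, int, int, Path]] = []
    while True:
        best: Optional[Tuple[int, int, int]] = None  # (len, i, j) with len negated? keep explicit
        for i, p in enumerate(family):
            for j, q in enumerate(family):
                if i == j:
                    continue
                ln = longest_suffix_prefix_overlap(p, q)
                if ln >= 1 and (
                    best is None
                    or ln > best[0]
                    or (ln == best[0] and (i, j) < (best[1], best[2]))
                ):
                    best = (ln, i, j)
        if best is None:
            break
        ln, i, j = best
        merged = family[i] + family[j][ln:]
        if dag is not None and not dag.is_path(merged):
            raise MergeError(f"merged constraint {merged} is not a path of the graph")
        log.append((i, j, ln, merged))
        lo, hi = min(i, j), max(i, j)
        del family[hi]
        family[lo] = merged
    if remove_contained_subpaths(family) != tuple(family):
        raise MergeError("containment among constraints after merging; corrupted state")
    return tuple(family), log


def subpaths_to_edge_constraints(
    dag: Dag, subpaths: Sequence[Path]
) -> Tuple[List[Tuple[NodeId, NodeId, object]], List[object], Dict[object, Path]]:
    """Stage 5: one shortcut edge constraint per remaining subpath.

    Returns the edge occurrences of the (transient) multigraph -- original
    edges keyed ``("orig", u, v)`` plus one ``("sub", idx)`` occurrence per
    subpath -- the new edge-constraint keys, and the shortcut map from key to
    originating subpath.  Parallel occurrences are legal here; stage 6
    subdivides them into parallel length-2 paths, making the graph simple
    again.
    """
    occurrences: List[Tuple[NodeId, NodeId, object]] = [
        (u, v, ("orig", u, v)) for (u, v) in sorted(dag.edges)
    ]
    new_keys: List[object] = []
    shortcut: Dict[object, Path] = {}
    for idx, p in enumerate(subpaths):
        key = ("sub", idx)
        occurrences.append((p[0], p[-1], key))
        new_keys.append(key)
        shortcut[key] = p
    return occurrences, new_keys, shortcut


def subdivide_edge_constraints(
    nodes: Set[NodeId],
    occurrences: List[Tuple[NodeId, NodeId, object]],
    constraint_keys: Sequence[object],
    shortcut: Dict[object, Path],
) -> Tuple[Dag, Dict[NodeId, MidpointOrigin], Set[NodeId]]:
    """Stage 6: subdivide every edge constraint with a fresh required midpoint.

    Each constrained occurrence (u, v) is replaced by u -> v_e -> v; v_e is
    recorded as standing for an original edge or a whole subpath.  The result
    is a simple Dag.
    """
    keyset = set(constraint_keys)
    midpoint_map: Dict[NodeId, MidpointOrigin] = {}
    new_nodes = set(nodes)
    new_edges: Set[Edge] = set()
    counter = 0
    for u, v, key in occurrences:
        if key in keyset:
            mid = f"__m{counter}__"
            counter += 1
            while mid in new_nodes:  # paranoid clash guard
                mid = f"__m{counter}__"
                counter += 1
            new_nodes.add(mid)
            new_edges.add((u, mid))
            new_edges.add((mid, v))
            if key in shortcut:
                midpoint_map[mid] = ("subpath", shortcut[key])
            else:
                midpoint_map[mid] = ("edge", (u, v))
        else:
            new_edges.add((u, v))
    return Dag(new_nodes, new_edges), midpoint_map, set(midpoint_map)


def transform_to_node_constraints(
    instance: Instance, skip_merge: bool = False
) -> ReductionTrace:
    """Stages 1-6: everything before the closure; shared by the unweighted
    and weighted pipelines.

    ``skip_merge`` omits stages 3-4 (the naive variant, exposed for testing
    only; it reproduces the incomplete earlier reduction and mis-handles
    overlapping constraints).
    """
    normalized, trace = normalize_constraints(instance)
    subs = normalized.subpaths
    if not skip_merge:
        kept = remove_contained_subpaths(subs)
        trace.contained_removed = _removed_constraints(subs, kept)
        subs, trace.merge_log = merge_subpaths_iteratively(kept, instance.dag)
    trace.final_subpaths = subs
    occurrences, new_keys, shortcut = subpaths_to_edge_constraints(instance.dag, subs)
    constraint_keys = [("orig", u, v) for (u, v) in sorted(normalized.required_edges)]
    constraint_keys += new_keys
    trace.shortcut_map = shortcut
    dag2, midpoint_map, midpoints = subdivide_edge_constraints(
        instance.dag.nodes, occurrences, constraint_keys, shortcut
    )
    # Carry original edge weights over to the surviving edges.
    dag2.weight = {
        e: w for e, w in instance.dag.weight.items() if e in dag2.edges
    }
    trace.midpoint_map = midpoint_map
    trace.transformed_dag = dag2
    trace.required_after = set(normalized.required_nodes) | midpoints
    return trace


def _removed_constraints(before: Sequence[Path], after: Sequence[Path]) -> List[Path]:
    remaining = list(after)
    removed = []
    for p in before:
        if p in remaining:
            remaining.remove(p)
        else:
            removed.append(p)
    return removed


def reduce_to_classic_mpc(
    instance: Instance, skip_merge: bool = False
) -> Tuple[Dag, ReductionTrace]:
    """Stages 1-8: produce the classical MPC instance (reduced Dag over the
    required nodes only) plus the trace needed to lift covers back."""
    trace = transform_to_node_constraints(instance, skip_merge=skip_merge)
    dag2 = trace.transformed_dag
    closure, witness = transitive_closure_with_witness(dag2)
    trace.closure_witness = witness
    required = trace.required_after
    trace.removed_nodes = dag2.nodes - required
    reduced = Dag(
        set(required),
        {(u, v) for (u, v) in closure.edges if u in required and v in required},
    )
    return reduced, trace


def _expand_append(out: List[NodeId], piece: Sequence[NodeId]) -> None:
    for v in piece:
        if not out or out[-1] != v:
            out.append(v)


def expand_midpoints(
    path: Sequence[NodeId], midpoint_map: Dict[NodeId, MidpointOrigin]
) -> Path:
    """Replace each midpoint node in a transformed-graph path by the original
    edge or subpath it stands for."""
    out: List[NodeId] = []
    for v in path:
        if v in midpoint_map:
            kind, payload = midpoint_map[v]
            piece = payload if kind == "subpath" else payload  # both are node sequences
            _expand_append(out, piece)
        else:
            _expand_append(out, (v,))
    return tuple(out)


def lift_solution(
    reduced_paths: Sequence[Sequence[NodeId]],
    trace: ReductionTrace,
    problem: str = "mpc-sc",
) -> CoverSolution:
    """Stage 10: revert stages 8..1 on a cover of the reduced graph.

    Closure edges expand through their witness paths, midpoints expand to
    their originating edge or subpath, and the final paths are re-verified
    against the ORIGINAL constraints; failure raises :class:`LiftError`
    (a bug indicator, never valid-input behavior).
    """
    original = trace.original
    lifted: List[Path] = []
    for rpath in reduced_paths:
        walk: List[NodeId] = []
        if len(rpath) == 1:
            walk = [rpath[0]]
        else:
            for a, b in zip(rpath, rpath[1:]):
                wit = trace.closure_witness.get((a, b))
                if wit is None:
                    raise LiftError(f"reduced edge ({a}, {b}) has no closure witness")
                _expand_append(walk, wit)
        full = expand_midpoints(walk, trace.midpoint_map)
        if not original.dag.is_path(full):
            raise LiftError(f"lifted sequence {full} is not a path of the original graph")
        lifted.append(full)
    ok, violations = verify_cover(original, lifted)
    if not ok:
        raise LiftError(f"lifted cover violates original constraints: {violations}")
    return CoverSolution(
        paths=lifted,
        total_weight=cover_weight(original.dag, lifted),
        problem=problem,
        satisfied=True,
    )
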