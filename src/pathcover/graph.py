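"""Core data model: DAGs, paths, problem instances and cover solutions.

Nodes are opaque strings.  A :class:`Dag` is a simple directed acyclic graph
with optional non-negative edge weights.  An :class:`Instance` bundles a Dag
with the constraint sets of the path-cover problems solved by this package:
required nodes V', required edges E', subpath constraints (long reads /
transfrags), paired subpath constraints (read mates), and optional start/end
node sets S and T for the weighted problem.

All tie-breaking in this package is lexicographic by node ID, then by
declaration order, so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import CycleError, ValidationError

NodeId = str
Edge = Tuple[NodeId, NodeId]
Path = Tuple[NodeId, ...]


def as_path(nodes: Iterable) -> Path:
    """Coerce an iterable of node IDs to a Path tuple of strings."""
    return tuple(str(v) for v in nodes)


@dataclass
class Dag:
    """A simple directed acyclic graph with optional edge weights.

    ``weight`` maps an edge to a non-negative real; absent edges default to 0
    when queried through :meth:`edge_weight`.
    """

    nodes: Set[NodeId] = field(default_factory=set)
    edges: Set[Edge] = field(default_factory=set)
    weight: Dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = {str(v) for v in self.nodes}
        self.edges = {(str(u), str(v)) for u, v in self.edges}
        self.weight = {(str(u), str(v)): w for (u, v), w in self.weight.items()}
        self.validate()

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def validate(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop at node {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(f"edge ({u!r}, {v!r}) uses an undeclared node")
        for e, w in self.weight.items():
            if e not in self.edges:
                raise ValidationError(f"weight given for missing edge {e!r}")
            if w < 0:
                raise ValidationError(f"negative weight on edge {e!r}")
        topological_order(self)  # raises CycleError on a cycle

    def edge_weight(self, e: Edge) -> float:
        return self.weight.get(e, 0.0)

    def successors(self, v: NodeId) -> List[NodeId]:
        return sorted(w for (u, w) in self.edges if u == v)

    def predecessors(self, v: NodeId) -> List[NodeId]:
        return sorted(u for (u, w) in self.edges if w == v)

    def sources(self) -> List[NodeId]:
        heads = {v for _, v in self.edges}
        return sorted(v for v in self.nodes if v not in heads)

    def sinks(self) -> List[NodeId]:
        tails = {u for u, _ in self.edges}
        return sorted(v for v in self.nodes if v not in tails)

    def is_path(self, path: Sequence[NodeId]) -> bool:
        """True iff ``path`` is a (length >= 1) directed path of this graph."""
        if len(path) == 0:
            return False
        if any(v not in self.nodes for v in path):
            return False
        if len(set(path)) != len(path):
            return False
        return all((path[i], path[i + 1]) in self.edges for i in range(len(path) - 1))

    def copy(self) -> "Dag":
        return Dag(set(self.nodes), set(self.edges), dict(self.weight))


def topological_order(dag: Dag) -> Tuple[NodeId, ...]:
    """A deterministic topological order (Kahn's algorithm, lexicographic ties).

    Raises :class:`CycleError` if the edge set contains a directed cycle.
    """
    import heapq

    indeg = {v: 0 for v in dag.nodes}
    succ: Dict[NodeId, List[NodeId]] = {v: [] for v in dag.nodes}
    for u, v in dag.edges:
        indeg[v] += 1
        succ[u].append(v)
    ready = [v for v, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: List[NodeId] = []
    while ready:
        v = heapq.heappop(ready)
        order.append(v)
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                heapq.heappush(ready, w)
    if len(order) != len(dag.nodes):
        raise CycleError("graph contains a directed cycle")
    return tuple(order)


class Reachability:
    """Reflexive reachability relation of a Dag.

    ``reach(u, v)`` is true iff there is a directed path (possibly of length
    0, i.e. u == v) from u to v.  Materialized as per-node descendant sets;
    construction is a reverse-topological sweep.
    """

    def __init__(self, dag: Dag):
        order = topological_order(dag)
        succ: Dict[NodeId, List[NodeId]] = {v: [] for v in dag.nodes}
        for u, v in dag.edges:
            succ[u].append(v)
        self._desc: Dict[NodeId, Set[NodeId]] = {}
        for v in reversed(order):
            d = {v}
            for w in succ[v]:
                d |= self._desc[w]
            self._desc[v] = d

    def reach(self, u: NodeId, v: NodeId) -> bool:
        return v in self._desc.get(u, set())

    __call__ = reach

    def descendants(self, u: NodeId) -> Set[NodeId]:
        return set(self._desc[u])


def reachability(dag: Dag) -> Reachability:
    return Reachability(dag)


def transitive_closure_with_witness(
    dag: Dag,
) -> Tuple[Dag, Dict[Edge, Path]]:
    """The transitive closure T(G) together with one witness path per edge.

    The closure has an edge (u, v) for every ordered pair with u != v and v
    reachable from u.  ``witness[(u, v)]`` is a concrete u->v path of the
    *input* graph; every input edge is its own witness.  Witnesses are chosen
    by shortest hop count with lexicographic tie-breaking, so the result is
    deterministic.
    """
    order = topological_order(dag)
    succ: Dict[NodeId, List[NodeId]] = {v: sorted(dag.successors(v)) for v in dag.nodes}
    witness: Dict[Edge, Path] = {}
    for src in order:
        # Deterministic BFS from src: first time a node is reached gives the
        # shortest witness; ties broken by scanning successors in sorted order.
        parent: Dict[NodeId, NodeId] = {}
        frontier = [src]
        seen = {src}
        while frontier:
            nxt: List[NodeId] = []
            for u in frontier:
                for w in succ[u]:
                    if w not in seen:
                        seen.add(w)
                        parent[w] = u
                        nxt.append(w)
            frontier = sorted(nxt)
        for v in seen - {src}:
            back = [v]
            while back[-1] != src:
                back.append(parent[back[-1]])
            witness[(src, v)] = tuple(reversed(back))
    closure = Dag(set(dag.nodes), set(witness.keys()))
    # Keep original edges as their own (length-2) witnesses.
    for e in dag.edges:
        witness[e] = e
    return closure, witness


@dataclass
class Instance:
    """A path-cover problem instance: a Dag plus constraint sets.

    required_nodes (V'), required_edges (E'), subpaths (long-read
    constraints), pairs (paired-end constraints), starts (S) and ends (T).
    Empty S and T mean "unconstrained" for the unweighted problems; the
    weighted solver defaults them to the sources/sinks of the graph.
    """

    dag: Dag
    required_nodes: Set[NodeId] = field(default_factory=set)
    required_edges: Set[Edge] = field(default_factory=set)
    subpaths: Tuple[Path, ...] = ()
    pairs: Tuple[Tuple[Path, Path], ...] = ()
    starts: Set[NodeId] = field(default_factory=set)
    ends: Set[NodeId] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.required_nodes = {str(v) for v in self.required_nodes}
        self.required_edges = {(str(u), str(v)) for u, v in self.required_edges}
        self.subpaths = tuple(as_path(p) for p in self.subpaths)
        self.pairs = tuple((as_path(p), as_path(q)) for p, q in self.pairs)
        self.starts = {str(v) for v in self.starts}
        self.ends = {str(v) for v in self.ends}
        self.validate()

    def validate(self) -> None:
        dag = self.dag
        bad = self.required_nodes - dag.nodes
        if bad:
            raise ValidationError(f"required nodes not in graph: {sorted(bad)}")
        for e in self.required_edges:
            if e not in dag.edges:
                raise ValidationError(f"required edge {e} not in graph")
        for p in self.subpaths:
            if not dag.is_path(p):
                raise ValidationError(f"subpath constraint {p} is not a path of the graph")
        for p, q in self.pairs:
            for part in (p, q):
                if not dag.is_path(part):
                    raise ValidationError(f"paired constraint member {part} is not a path")
        for v in self.starts | self.ends:
            if v not in dag.nodes:
                raise ValidationError(f"start/end node {v!r} not in graph")
        if self.weighted_fields_present():
            missing_s = set(dag.sources()) - self.starts
            if missing_s:
                raise ValidationError(f"S must contain every source; missing {sorted(missing_s)}")
            missing_t = set(dag.sinks()) - self.ends
            if missing_t:
                raise ValidationError(f"T must contain every sink; missing {sorted(missing_t)}")

    def weighted_fields_present(self) -> bool:
        return bool(self.starts or self.ends)

    # --- constraint accounting (c, N, C in the complexity statements) ---
    @property
    def c_sub(self) -> int:
        return len(self.subpaths)

    @property
    def c_pair(self) -> int:
        return len(self.pairs)

    @property
    def c(self) -> int:
        return self.c_sub + self.c_pair + len(self.required_edges)

    @property
    def N(self) -> int:
        return sum(len(p) for p in self.subpaths)

    @property
    def C(self) -> int:
        return len(self.required_nodes) + len(self.required_edges) + self.c_sub + self.c_pair

    def copy(self) -> "Instance":
        return Instance(
            self.dag.copy(),
            set(self.required_nodes),
            set(self.required_edges),
            tuple(self.subpaths),
            tuple(self.pairs),
            set(self.starts),
            set(self.ends),
        )


@dataclass
class CoverSolution:
    """A set of solution paths with its satisfaction certificate."""

    paths: List[Path]
    total_weight: float = 0.0
    problem: str = "mpc"
    satisfied: bool = True

    @property
    def k(self) -> int:
        return len(self.paths)


def path_weight(dag: Dag, path: Sequence[NodeId]) -> float:
    return sum(dag.edge_weight((path[i], path[i + 1])) for i in range(len(path) - 1))


def cover_weight(dag: Dag, paths: Iterable[Sequence[NodeId]]) -> float:
    """Total edge weight of a cover; shared edges are counted per use."""
    return sum(path_weight(dag, p) for p in paths)
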