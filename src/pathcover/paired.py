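"""Paired-subpath-constraint solver (the NP-hard problem, solved exactly).

With paired-end constraints the cover problem becomes NP-hard, but it is
fixed-parameter tractable in the total constraint count C.  Two constraints
are *compatible* when one directed path of the graph contains both
entirely; a set of pairwise-compatible constraints is always jointly
realizable by a single path (the union of the constraints has width 1).
The optimum is therefore the chromatic number of the *incompatibility
graph* (constraints as vertices, edges between incompatible ones), each
color class realized as one witness path.  OPT = 2 is decidable in
polynomial time: it holds exactly when the incompatibility graph is
bipartite and has at least one edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import InfeasibleError, LimitError, RealizationError
from .graph import (
    CoverSolution,
    Dag,
    Instance,
    NodeId,
    Path,
    Reachability,
    cover_weight,
    topological_order,
)
from .verify import contains_contiguous, verify_cover


@dataclass(frozen=True)
class ConstraintAtom:
    """One constraint: a required node, a required edge, a single subpath,
    or a pair of subpaths that must share a solution path."""

    kind: str  # "node" | "edge" | "path" | "pair"
    payload: tuple
    index: int

    def members(self) -> Tuple[Path, ...]:
        """The subpaths this atom forces onto a single path."""
        if self.kind == "node":
            return ((self.payload[0],),)
        if self.kind == "edge":
            return (tuple(self.payload),)
        if self.kind == "path":
            return (tuple(self.payload),)
        if self.kind == "pair":
            return (tuple(self.payload[0]), tuple(self.payload[1]))
        raise ValueError(f"unknown atom kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "pair":
            return f"pair ({'-'.join(self.payload[0])}, {'-'.join(self.payload[1])})"
        return f"{self.kind} {self.payload}"


def atoms_from_instance(instance: Instance) -> List[ConstraintAtom]:
    atoms: List[ConstraintAtom] = []
    for v in sorted(instance.required_nodes):
        atoms.append(ConstraintAtom("node", (v,), len(atoms)))
    for e in sorted(instance.required_edges):
        atoms.append(ConstraintAtom("edge", tuple(e), len(atoms)))
    for p in instance.subpaths:
        atoms.append(ConstraintAtom("path", tuple(p), len(atoms)))
    for p, q in instance.pairs:
        atoms.append(ConstraintAtom("pair", (tuple(p), tuple(q)), len(atoms)))
    return atoms


class _DagContext:
    """Cached reachability and topological positions for one Dag."""

    def __init__(self, dag: Dag):
        self.dag = dag
        self.reach = Reachability(dag)
        self.topo_pos = {v: i for i, v in enumerate(topological_order(dag))}
        self.succ = {v: dag.successors(v) for v in dag.nodes}


def _merge_two(a: Path, b: Path) -> Optional[Path]:
    """Merge two subpaths sharing at least one node into one aligned
    segment, or None if their alignments conflict."""
    shared = set(a) & set(b)
    x = next(iter(shared))
    d = a.index(x) - b.index(x)  # position of b[0] within a's coordinates
    lo = min(0, d)
    hi = max(len(a), d + len(b))
    merged: List[Optional[NodeId]] = []
    for pos in range(lo, hi):
        va = a[pos] if 0 <= pos < len(a) else None
        vb = b[pos - d] if 0 <= pos - d < len(b) else None
        if va is not None and vb is not None and va != vb:
            return None
        v = va if va is not None else vb
        if v is None:  # the two intervals do not overlap -- cannot happen
            return None  # pragma: no cover
        merged.append(v)
    out = tuple(merged)
    if len(set(out)) != len(out):  # a shared node at inconsistent offsets
        return None
    return out


def single_path_contains_all(
    dag: Dag,
    subpaths: Sequence[Path],
    ctx: Optional[_DagContext] = None,
) -> Tuple[bool, Optional[Path]]:
    """Decide whether one directed path contains every given subpath as a
    contiguous block, and produce a witness path if so.

    Subpaths sharing nodes are merged (conflicting alignments mean no);
    the resulting node-disjoint segments must be totally orderable by
    reachability from each segment's last node to the next segment's first
    node; the witness chains them with deterministic shortest connectors.
    """
    segments = [tuple(p) for p in subpaths if p]
    if not segments:
        return True, None
    ctx = ctx or _DagContext(dag)
    # Merge segments that share nodes until pairwise disjoint.
    changed = True
    while changed:
        changed = False
        for i in range(len(segments)):
            for j in range(i + 1, len(segments)):
                if set(segments[i]) & set(segments[j]):
                    merged = _merge_two(segments[i], segments[j])
                    if merged is None or not dag.is_path(merged):
                        return False, None
                    segments[i] = merged
                    del segments[j]
                    changed = True
                    break
            if changed:
                break
    segments.sort(key=lambda seg: ctx.topo_pos[seg[0]])
    for s1, s2 in zip(segments, segments[1:]):
        if not ctx.reach(s1[-1], s2[0]):
            return False, None
    witness: List[NodeId] = list(segments[0])
    for seg in segments[1:]:
        connector = _shortest_path(ctx, witness[-1], seg[0])
        witness.extend(connector[1:])
        witness.extend(seg[1:] if witness[-1] == seg[0] else seg)
    wit = tuple(witness)
    if not dag.is_path(wit):  # pragma: no cover - bug guard
        return False, None
    if not all(contains_contiguous(wit, p) for p in subpaths):
        return False, None
    return True, wit


def _shortest_path(ctx: _DagContext, src: NodeId, dst: NodeId) -> List[NodeId]:
    """Deterministic shortest-hop path (BFS, lexicographic tie-break)."""
    if src == dst:
        return [src]
    from collections import deque

    prev: Dict[NodeId, NodeId] = {}
    seen = {src}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for w in ctx.succ[u]:
            if w not in seen:
                seen.add(w)
                prev[w] = u
                if w == dst:
                    path = [dst]
                    while path[-1] != src:
                        path.append(prev[path[-1]])
                    return list(reversed(path))
                queue.append(w)
    raise RealizationError(f"no path from {src} to {dst}")  # pre-checked reachable


def compatible(
    x: ConstraintAtom,
    y: ConstraintAtom,
    dag: Dag,
    ctx: Optional[_DagContext] = None,
) -> bool:
    """True iff a single directed path contains both constraints entirely."""
    ok, _ = single_path_contains_all(dag, x.members() + y.members(), ctx)
    return ok


def check_feasibility(instance: Instance) -> List[ConstraintAtom]:
    """Every atom must be individually satisfiable by some path; returns the
    atom list, or raises InfeasibleError naming the first offender."""
    atoms = atoms_from_instance(instance)
    ctx = _DagContext(instance.dag)
    for atom in atoms:
        ok, _ = single_path_contains_all(instance.dag, atom.members(), ctx)
        if not ok:
            raise InfeasibleError(f"constraint is unsatisfiable: {atom.describe()}")
    return atoms


@dataclass
class IncompatibilityGraph:
    atoms: List[ConstraintAtom]
    graph: nx.Graph  # vertices are atom indices

    def to_dot(self) -> str:
        lines = ["graph incompatibility {"]
        for atom in self.atoms:
            lines.append(f'  {atom.index} [label="{atom.describe()}"];')
        for u, v in sorted(self.graph.edges()):
            lines.append(f"  {u} -- {v};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_incompatibility_graph(instance: Instance) -> IncompatibilityGraph:
    """All-pairs compatibility; an edge joins every incompatible atom pair."""
    atoms = check_feasibility(instance)
    ctx = _DagContext(instance.dag)
    g = nx.Graph()
    g.add_nodes_from(a.index for a in atoms)
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if not compatible(atoms[i], atoms[j], instance.dag, ctx):
                g.add_edge(i, j)
    return IncompatibilityGraph(atoms, g)


def realize_class(
    dag: Dag,
    atoms: Sequence[ConstraintAtom],
    ctx: Optional[_DagContext] = None,
) -> Path:
    """One witness path satisfying a pairwise-compatible atom class.

    The witness is verified against every atom; failure raises
    :class:`RealizationError` (it would be a counterexample to the
    pairwise-implies-joint property, and is reported, not papered over).
    """
    if not atoms:
        raise RealizationError("cannot realize an empty constraint class")
    subpaths: List[Path] = []
    for atom in atoms:
        subpaths.extend(atom.members())
    ok, witness = single_path_contains_all(dag, subpaths, ctx)
    if not ok or witness is None:
        raise RealizationError(
            f"no single path realizes atom class {[a.describe() for a in atoms]}"
        )
    for atom in atoms:
        if not all(contains_contiguous(witness, p) for p in atom.members()):
            raise RealizationError(f"witness {witness} misses {atom.describe()}")
    return witness


def _greedy_coloring(g: nx.Graph) -> Dict[int, int]:
    return nx.coloring.greedy_color(g, strategy="largest_first")


def _max_clique(g: nx.Graph) -> List[int]:
    best: List[int] = []
    for clique in nx.find_cliques(g):
        if len(clique) > len(best):
            best = clique
    return sorted(best)


def _k_coloring(g: nx.Graph, k: int, clique: Sequence[int]) -> Optional[Dict[int, int]]:
    """DSATUR-style backtracking k-coloring; a maximum clique is pre-colored
    to break color symmetry.  Returns an assignment or None."""
    if len(clique) > k:
        return None
    color: Dict[int, int] = {v: i for i, v in enumerate(clique)}
    vertices = [v for v in g.nodes() if v not in color]
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}

    def select() -> Optional[int]:
        best_v, best_key = None, None
        for v in vertices:
            if v in color:
                continue
            sat = len({color[w] for w in adj[v] if w in color})
            key = (-sat, -len(adj[v]), v)
            if best_key is None or key < best_key:
                best_v, best_key = v, key
        return best_v

    def backtrack() -> bool:
        v = select()
        if v is None:
            return True
        used = {color[w] for w in adj[v] if w in color}
        max_new = min(k, (max(color.values()) + 2) if color else 1)
        for c in range(max_new):
            if c in used:
                continue
            color[v] = c
            if backtrack():
                return True
            del color[v]
        return False

    return dict(color) if backtrack() else None


def chromatic_coloring(g: nx.Graph) -> Dict[int, int]:
    """An optimal proper coloring (exact chromatic number) of a small graph.

    Clique lower bound and greedy upper bound sandwich a branch-and-bound
    k-colorability search.
    """
    if g.number_of_nodes() == 0:
        return {}
    if g.number_of_edges() == 0:
        return {v: 0 for v in g.nodes()}
    greedy = _greedy_coloring(g)
    ub = max(greedy.values()) + 1
    clique = _max_clique(g)
    lb = len(clique)
    best = greedy
    for k in range(lb, ub):
        attempt = _k_coloring(g, k, clique)
        if attempt is not None:
            best = attempt
            break
    return best


def solve_opt2(instance: Instance) -> Optional[CoverSolution]:
    """Polynomial decision of OPT <= 2 for paired constraints.

    Returns a 0-, 1- or 2-path solution when the incompatibility graph is
    edgeless or bipartite, else None (OPT >= 3).
    """
    inc = build_incompatibility_graph(instance)
    ctx = _DagContext(instance.dag)
    if not inc.atoms:
        return CoverSolution(paths=[], problem="mpc-psc")
    if inc.graph.number_of_edges() == 0:
        paths = [realize_class(instance.dag, inc.atoms, ctx)]
    elif nx.is_bipartite(inc.graph):
        side = nx.algorithms.bipartite.color(inc.graph)
        classes = [
            [a for a in inc.atoms if side[a.index] == c] for c in (0, 1)
        ]
        paths = [realize_class(instance.dag, cls, ctx) for cls in classes if cls]
    else:
        return None
    ok, violations = verify_cover(instance, paths)
    if not ok:  # pragma: no cover - bug guard
        raise AssertionError(f"unverified OPT<=2 solution: {violations}")
    return CoverSolution(
        paths=paths,
        total_weight=cover_weight(instance.dag, paths),
        problem="mpc-psc",
        satisfied=True,
    )


def solve_mpc_psc(instance: Instance, max_classes: int = 20) -> CoverSolution:
    """Exact FPT solver: minimum partition of the constraints into
    pairwise-compatible classes = chromatic number of the incompatibility
    graph; each color class is realized as one witness path.

    ``max_classes`` bounds the constraint count C accepted (the running time
    is exponential only in C); beyond it a :class:`LimitError` is raised.
    """
    atoms = atoms_from_instance(instance)
    if len(atoms) > max_classes:
        raise LimitError(
            f"{len(atoms)} constraints exceed the FPT budget of {max_classes}"
        )
    inc = build_incompatibility_graph(instance)
    if not inc.atoms:
        return CoverSolution(paths=[], problem="mpc-psc")
    coloring = chromatic_coloring(inc.graph)
    ctx = _DagContext(instance.dag)
    classes: Dict[int, List[ConstraintAtom]] = {}
    for atom in inc.atoms:
        classes.setdefault(coloring[atom.index], []).append(atom)
    paths = [realize_class(instance.dag, cls, ctx) for _, cls in sorted(classes.items())]
    ok, violations = verify_cover(instance, paths)
    if not ok:  # pragma: no cover - bug guard
        raise AssertionError(f"unverified FPT solution: {violations}")
    return CoverSolution(
        paths=paths,
        total_weight=cover_weight(instance.dag, paths),
        problem="mpc-psc",
        satisfied=True,
    )
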