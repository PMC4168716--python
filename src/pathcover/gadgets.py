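"""Hardness gadget and regression fixture families.

:func:`hardness_gadget` builds the reduction showing that path cover with
paired constraints is NP-hard: from a non-bipartite undirected graph G it
constructs a two-stage DAG P(G) with paired subpath constraints such that
P(G) admits a 3-path solution iff G is 3-colorable.  The construction: a
backbone b_0 .. b_{n+m+1}; one first-stage block per vertex v_k of G with
three parallel length-2 branches labeled v_k, X_k, Y_k; one second-stage
block per edge e_k = {v_i, v_j} with branches labeled [v_i], [v_j] and one
unlabeled; and a tail edge.  Paired constraints tie each second-stage
branch [v] to the first-stage branch v, and tie every first-stage branch to
the tail edge so that all three branches of each block are forced into the
cover using *only* paired constraints.  Three solution paths then pick up
vertex branches exactly as three color classes would.

:func:`overlap_chain_fixture` builds the family of chained overlapping
subpath constraints (a suffix of one constraint is a prefix of the next,
with alternating overlap lengths) on which reductions that skip the
containment/merge preprocessing return strictly too many paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import networkx as nx

from .errors import GadgetError, ValidationError
from .graph import Dag, Instance, Path


@dataclass
class HardnessGadget:
    source_graph: nx.Graph
    instance: Instance
    labels: Dict[str, Path]  # label -> labeled branch path in the DAG


def named_source_graph(name: str) -> nx.Graph:
    """Small named undirected graphs for the gadget (k3, c5, k4, ...)."""
    name = name.lower()
    if name.startswith("k") and name[1:].isdigit():
        return nx.complete_graph(int(name[1:]))
    if name.startswith("c") and name[1:].isdigit():
        return nx.cycle_graph(int(name[1:]))
    raise ValidationError(f"unknown source graph {name!r} (use k<N> or c<N>)")


def hardness_gadget(source: nx.Graph) -> HardnessGadget:
    """Build P(G) and its paired constraints from a non-bipartite graph G.

    Raises :class:`GadgetError` when G is bipartite (the 3-colorability
    question would be trivial) or has isolated vertices.
    """
    if source.number_of_nodes() == 0:
        raise GadgetError("source graph is empty")
    if any(d == 0 for _, d in source.degree()):
        raise GadgetError("source graph has isolated vertices")
    if nx.is_bipartite(source):
        raise GadgetError("source graph is bipartite; its chromatic number is trivial")
    vertices = sorted(source.nodes(), key=str)
    v_index = {v: k + 1 for k, v in enumerate(vertices)}
    edge_list = sorted(
        (tuple(sorted((v_index[a], v_index[b]))) for a, b in source.edges()),
    )
    n, m = len(vertices), len(edge_list)
    width = len(str(n + m + 1))
    backbone = [f"b{i:0{width}d}" for i in range(n + m + 2)]
    nodes = set(backbone)
    edges = set()
    labels: Dict[str, Path] = {}

    def add_branch(block: int, mid: str, label: str | None) -> Path:
        mid_node = mid
        nodes.add(mid_node)
        edges.add((backbone[block - 1], mid_node))
        edges.add((mid_node, backbone[block]))
        branch = (backbone[block - 1], mid_node, backbone[block])
        if label is not None:
            labels[label] = branch
        return branch

    # First stage: one block per vertex, branches v_k, X_k, Y_k.
    for k in range(1, n + 1):
        add_branch(k, f"v{k}m", f"v{k}")
        add_branch(k, f"X{k}m", f"X{k}")
        add_branch(k, f"Y{k}m", f"Y{k}")
    # Second stage: one block per edge, branches [v_i], [v_j], one unlabeled.
    for idx, (i, j) in enumerate(edge_list, start=1):
        block = n + idx
        add_branch(block, f"E{idx}v{i}m", f"[v{i}]@e{idx}")
        add_branch(block, f"E{idx}v{j}m", f"[v{j}]@e{idx}")
        add_branch(block, f"E{idx}um", None)
    # Tail edge, the pairing anchor that forces first-stage coverage.
    edges.add((backbone[n + m], backbone[n + m + 1]))
    tail: Path = (backbone[n + m], backbone[n + m + 1])
    labels["tail"] = tail

    pairs: List[Tuple[Path, Path]] = []
    for idx, (i, j) in enumerate(edge_list, start=1):
        pairs.append((labels[f"v{i}"], labels[f"[v{i}]@e{idx}"]))
        pairs.append((labels[f"v{j}"], labels[f"[v{j}]@e{idx}"]))
    for k in range(1, n + 1):
        pairs.append((labels[f"v{k}"], tail))
        pairs.append((labels[f"X{k}"], tail))
        pairs.append((labels[f"Y{k}"], tail))

    instance = Instance(Dag(nodes, edges), pairs=tuple(pairs))
    return HardnessGadget(source_graph=source, instance=instance, labels=labels)


def overlap_chain_fixture(depth: int) -> Instance:
    """Chain DAG with ``depth`` staggered subpath constraints.

    Constraint 1 spans nodes 1-4; each later constraint starts inside the
    previous one, alternating overlap lengths 2 and 1 with its predecessor
    (so constraint 1 has a length-2 suffix that prefixes constraint 2 *and*
    a length-1 suffix that prefixes constraint 3 -- the pattern that breaks
    reductions without the merge stage).  All nodes are required; the merged
    pipeline needs exactly one path.
    """
    if depth < 2:
        raise ValidationError("depth must be >= 2")
    spans: List[Tuple[int, int]] = [(1, 4)]
    for k in range(2, depth + 1):
        s_prev, _ = spans[-1]
        if k % 2 == 0:
            start, length = s_prev + 2, 3
        else:
            start, length = s_prev + 1, 4
        spans.append((start, start + length - 1))
    last = max(b for _, b in spans)
    width = len(str(last))
    name = lambda i: f"n{i:0{width}d}"
    nodes = {name(i) for i in range(1, last + 1)}
    edges = {(name(i), name(i + 1)) for i in range(1, last)}
    subpaths = tuple(
        tuple(name(i) for i in range(a, b + 1)) for a, b in spans
    )
    return Instance(
        Dag(nodes, edges),
        required_nodes=set(nodes),
        subpaths=subpaths,
    )
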