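"""Flow engines: min-flow with lower bounds and min-cost circulation.

Covering a node set with a minimum number of paths is a minimum *flow*
problem: each graph node v becomes an arc (v_in, v_out) with flow lower
bound 1 when v must be covered, original edges become free arcs, and a
global source/sink pair is wired to the graph's sources and sinks.  The
minimum feasible flow value equals the maximum antichain size (the DAG
width restricted to the required nodes), and any decomposition of the flow
into s-t paths is a minimum path cover.

The weighted problems use a min-cost *circulation* instead: a return arc
(t, s) whose per-unit cost exceeds the weight of any single path makes
every min-cost circulation simultaneously a min-flow, so the solver
optimizes path count first and total weight second (lexicographically).

``min_flow`` follows the classical two-phase scheme: a greedy feasible flow
saturating each lower bound, then one max-flow computation from t to s on
the residual network to cancel all surplus.  ``min_cost_circulation``
removes lower bounds by the standard demand transformation and solves the
resulting ordinary min-cost flow with network simplex (exact, on rational
costs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Hashable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .errors import DecompositionError, InfeasibleError
from .graph import Dag, NodeId, Path

NetNode = Hashable
SOURCE: NetNode = ("s",)
SINK: NetNode = ("t",)


@dataclass
class Arc:
    tail: NetNode
    head: NetNode
    lower: int = 0
    capacity: Optional[int] = None  # None = unbounded
    cost: float = 0.0


@dataclass
class FlowNetwork:
    """Arc list with a distinguished global source/sink and an optional
    circulation (return) arc, stored as an index into ``arcs``."""

    arcs: List[Arc] = field(default_factory=list)
    source: NetNode = SOURCE
    sink: NetNode = SINK
    circulation_arc: Optional[int] = None

    def add(self, tail, head, lower=0, capacity=None, cost=0.0) -> int:
        if capacity is not None and lower > capacity:
            raise ValueError("lower bound exceeds capacity")
        if cost < 0:
            raise ValueError("negative cost")
        self.arcs.append(Arc(tail, head, lower, capacity, cost))
        return len(self.arcs) - 1

    def nodes(self) -> Set[NetNode]:
        out = {self.source, self.sink}
        for a in self.arcs:
            out.add(a.tail)
            out.add(a.head)
        return out


@dataclass
class Flow:
    """Integer flow values per arc of a FlowNetwork."""

    network: FlowNetwork
    values: List[int]

    @property
    def value(self) -> int:
        net = self.network
        if net.circulation_arc is not None:
            return self.values[net.circulation_arc]
        return sum(
            v for a, v in zip(net.arcs, self.values) if a.tail == net.source
        ) - sum(v for a, v in zip(net.arcs, self.values) if a.head == net.source)

    def check(self) -> None:
        """Assert conservation, lower bounds and capacities."""
        balance: Dict[NetNode, int] = {}
        for arc, v in zip(self.network.arcs, self.values):
            if v < arc.lower:
                raise InfeasibleError(f"arc {arc} below lower bound ({v})")
            if arc.capacity is not None and v > arc.capacity:
                raise InfeasibleError(f"arc {arc} above capacity ({v})")
            balance[arc.tail] = balance.get(arc.tail, 0) - v
            balance[arc.head] = balance.get(arc.head, 0) + v
        free = (
            {self.network.source, self.network.sink}
            if self.network.circulation_arc is None
            else set()
        )
        for node, b in balance.items():
            if node not in free and b != 0:
                raise DecompositionError(f"conservation violated at {node}: {b}")


def split_nodes(v: NodeId) -> Tuple[NetNode, NetNode]:
    return ("in", v), ("out", v)


def build_minflow_network(
    dag: Dag, required: Set[NodeId]
) -> Tuple[FlowNetwork, Dict[NodeId, Tuple[NetNode, NetNode]]]:
    """Node-splitting reduction of path cover to min-flow.

    Every node v becomes an arc (v_in, v_out) with lower bound 1 iff v is
    required; edges become free arcs between the out/in sides; the global
    source feeds every source of the DAG and every sink drains to the global
    sink.
    """
    net = FlowNetwork()
    split = {v: split_nodes(v) for v in dag.nodes}
    for v in sorted(dag.nodes):
        vin, vout = split[v]
        net.add(vin, vout, lower=1 if v in required else 0)
    for u, v in sorted(dag.edges):
        net.add(split[u][1], split[v][0])
    for v in dag.sources():
        net.add(net.source, split[v][0])
    for v in dag.sinks():
        net.add(split[v][1], net.sink)
    return net, split


def _residual_bfs(
    n_arcs: int,
    arcs: List[Arc],
    flow: List[int],
    adj: Dict[NetNode, List[Tuple[int, int]]],
    start: NetNode,
    goal: NetNode,
) -> Optional[List[Tuple[int, int]]]:
    """Shortest augmenting route from start to goal over residual arcs.

    ``adj`` maps a node to (arc index, direction) pairs; direction +1 uses
    spare capacity forwards, -1 cancels existing flow above its lower bound.
    Returns the arc/direction sequence, or None.
    """
    from collections import deque

    prev: Dict[NetNode, Tuple[NetNode, int, int]] = {}
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node == goal:
            route = []
            while node != start:
                pnode, ai, d = prev[node]
                route.append((ai, d))
                node = pnode
            return list(reversed(route))
        for ai, d in adj.get(node, ()):
            arc = arcs[ai]
            if d == +1:
                residual = (
                    float("inf") if arc.capacity is None else arc.capacity - flow[ai]
                )
                nxt = arc.head
            else:
                residual = flow[ai] - arc.lower
                nxt = arc.tail
            if residual > 0 and nxt not in seen:
                seen.add(nxt)
                prev[nxt] = (node, ai, d)
                queue.append(nxt)
    return None


def _residual_adj(arcs: List[Arc]) -> Dict[NetNode, List[Tuple[int, int]]]:
    adj: Dict[NetNode, List[Tuple[int, int]]] = {}
    for i, arc in enumerate(arcs):
        adj.setdefault(arc.tail, []).append((i, +1))
        adj.setdefault(arc.head, []).append((i, -1))
    # Deterministic scan order.
    for node in adj:
        adj[node].sort(key=lambda t: (repr(arcs[t[0]].head if t[1] > 0 else arcs[t[0]].tail), t))
    return adj


def min_flow(network: FlowNetwork) -> Flow:
    """Minimum-value integer flow satisfying all lower bounds.

    Phase 1 greedily routes one unit through each unsaturated lower-bound
    arc; phase 2 is a max-flow from sink to source on the residual network,
    cancelling every unit the lower bounds do not force.
    """
    arcs = network.arcs
    flow = [0] * len(arcs)
    adj = _residual_adj(arcs)
    s, t = network.source, network.sink
    for i, arc in enumerate(arcs):
        while flow[i] < arc.lower:
            # Route s -> tail(arc), then the arc itself, then head(arc) -> t,
            # using residual capacities so earlier units are not displaced.
            left = (
                [] if arc.tail == s else _residual_bfs(len(arcs), arcs, flow, adj, s, arc.tail)
            )
            right = (
                [] if arc.head == t else _residual_bfs(len(arcs), arcs, flow, adj, arc.head, t)
            )
            if left is None or right is None:
                raise InfeasibleError(f"lower bound on arc {arc} cannot be satisfied")
            for ai, d in left + [(i, +1)] + right:
                flow[ai] += d
    # Phase 2: cancel surplus via max-flow t -> s on the residual network.
    while True:
        route = _residual_bfs(len(arcs), arcs, flow, adj, t, s)
        if route is None:
            break
        bottleneck = min(
            (arcs[ai].capacity - flow[ai]) if d > 0 and arcs[ai].capacity is not None
            else (flow[ai] - arcs[ai].lower) if d < 0
            else float("inf")
            for ai, d in route
        )
        bottleneck = int(bottleneck) if bottleneck != float("inf") else 1
        for ai, d in route:
            flow[ai] += d * bottleneck
    result = Flow(network, flow)
    result.check()
    return result


def _to_fraction(x) -> Fraction:
    if isinstance(x, float):
        return Fraction(repr(x))  # decimal reading of the printed value
    return Fraction(x)


def build_mincost_network(
    dag: Dag,
    required: Set[NodeId],
    starts: Set[NodeId],
    ends: Set[NodeId],
    midpoint_costs: Optional[Dict[NodeId, float]] = None,
) -> Tuple[FlowNetwork, Dict[NodeId, Tuple[NetNode, NetNode]]]:
    """Min-cost-circulation reduction for the weighted cover problems.

    Node-split arcs carry lower bound 1 iff required and the midpoint cost
    (the weight of the subpath or original edge a midpoint stands for);
    edge arcs carry the edge weight; the source feeds exactly S and the sink
    drains exactly T.  The return arc (t, s) costs one more than the total
    of all arc costs, which strictly exceeds the weight of any single path,
    so min-cost circulations are simultaneously min-flows.
    """
    midpoint_costs = midpoint_costs or {}
    net = FlowNetwork()
    split = {v: split_nodes(v) for v in dag.nodes}
    total_cost = Fraction(0)
    for v in sorted(dag.nodes):
        vin, vout = split[v]
        cost = _to_fraction(midpoint_costs.get(v, 0))
        total_cost += cost
        net.add(vin, vout, lower=1 if v in required else 0, cost=cost)
    for u, v in sorted(dag.edges):
        cost = _to_fraction(dag.edge_weight((u, v)))
        total_cost += cost
        net.add(split[u][1], split[v][0], cost=cost)
    for v in sorted(starts):
        net.add(net.source, split[v][0])
    for v in sorted(ends):
        net.add(split[v][1], net.sink)
    net.circulation_arc = net.add(net.sink, net.source, cost=total_cost + 1)
    return net, split


def min_cost_circulation(network: FlowNetwork) -> Flow:
    """Exact integer min-cost circulation satisfying all lower bounds.

    Lower bounds are removed by the standard transformation (a bound of l on
    (u, v) becomes a demand of +l at u and -l at v), the remaining ordinary
    min-cost flow is solved by network simplex, and bounds are added back.
    Unbounded capacities are capped at one more than the sum of all lower
    bounds, which no min-cost circulation of these networks can exceed.
    """
    if network.circulation_arc is None:
        raise ValueError("network has no circulation arc")
    arcs = network.arcs
    cap_default = sum(a.lower for a in arcs) + 1
    G = nx.DiGraph()
    demand: Dict[NetNode, int] = {v: 0 for v in network.nodes()}
    relay_of: Dict[int, NetNode] = {}
    for i, arc in enumerate(arcs):
        cap = (arc.capacity if arc.capacity is not None else max(cap_default, arc.lower))
        u, v = arc.tail, arc.head
        if G.has_edge(u, v):  # parallel arc: relay through a synthetic node
            relay = ("relay", i)
            relay_of[i] = relay
            G.add_edge(u, relay, capacity=cap - arc.lower, weight=_to_fraction(arc.cost))
            G.add_edge(relay, v, capacity=cap - arc.lower, weight=Fraction(0))
        else:
            G.add_edge(u, v, capacity=cap - arc.lower, weight=_to_fraction(arc.cost))
        demand[u] += arc.lower
        demand[v] -= arc.lower
    for v, d in demand.items():
        G.add_node(v, demand=d)
    try:
        flow_dict = nx.min_cost_flow(G)
    except nx.NetworkXUnfeasible as exc:
        raise InfeasibleError("no circulation satisfies the lower bounds") from exc
    values = []
    for i, arc in enumerate(arcs):
        if i in relay_of:
            f = flow_dict[arc.tail][relay_of[i]]
        else:
            f = flow_dict[arc.tail][arc.head]
        values.append(int(f) + arc.lower)
    result = Flow(network, values)
    result.check()
    return result


def decompose_flow_to_paths(flow: Flow) -> List[Tuple[NetNode, ...]]:
    """Decompose an s-t flow into exactly ``value`` unit paths.

    The circulation arc (if any) is ignored.  Paths are peeled off by
    walking from the source along arcs with remaining flow, smallest head
    first, decrementing as we go; flow conservation guarantees every walk
    reaches the sink.
    """
    net = flow.network
    remaining = list(flow.values)
    if net.circulation_arc is not None:
        remaining[net.circulation_arc] = 0
    out_arcs: Dict[NetNode, List[int]] = {}
    for i, arc in enumerate(net.arcs):
        if net.circulation_arc == i:
            continue
        out_arcs.setdefault(arc.tail, []).append(i)
    for node in out_arcs:
        out_arcs[node].sort(key=lambda i: repr(net.arcs[i].head))
    value = sum(remaining[i] for i, a in enumerate(net.arcs)
                if a.tail == net.source and i != net.circulation_arc)
    paths: List[Tuple[NetNode, ...]] = []
    for _ in range(value):
        node = net.source
        path = [node]
        while node != net.sink:
            ai = next((i for i in out_arcs.get(node, ()) if remaining[i] > 0), None)
            if ai is None:
                raise DecompositionError(f"flow stranded at {node}")
            remaining[ai] -= 1
            node = net.arcs[ai].head
            path.append(node)
        paths.append(tuple(path))
    leftovers = [net.arcs[i] for i in range(len(net.arcs))
                 if remaining[i] > 0 and i != net.circulation_arc]
    if leftovers:
        raise DecompositionError(f"flow not fully decomposed: {leftovers}")
    return paths


def network_path_to_node_path(path: Sequence[NetNode]) -> Path:
    """Collapse a network path (s, v_in, v_out, ..., t) to original node IDs."""
    out: List[NodeId] = []
    for node in path:
        if isinstance(node, tuple) and len(node) == 2 and node[0] in ("in", "out"):
            v = node[1]
            if not out or out[-1] != v:
                out.append(v)
    return tuple(out)
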