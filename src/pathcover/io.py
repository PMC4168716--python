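"""Instance and solution file I/O (JSON dialect) and DOT export.

Instance files are JSON objects with keys ``nodes``, ``edges`` (lists
``[u, v]`` or ``[u, v, w]``), ``required_nodes``, ``required_edges``,
``subpaths`` (list of node lists), ``pairs`` (list of two node lists),
``starts`` and ``ends``.  Missing keys default to empty; nothing is
implicitly "all required".  Node IDs may be JSON integers and are stored as
strings.
"""

from __future__ import annotations

import json
from typing import IO, Iterable, Union

from .errors import FormatError, ValidationError
from .graph import CoverSolution, Dag, Instance, as_path

Stream = Union[IO[str], str]

_INSTANCE_KEYS = {
    "nodes", "edges", "required_nodes", "required_edges",
    "subpaths", "pairs", "starts", "ends",
}


def read_instance(stream: Stream) -> Instance:
    """Parse an instance file; raises FormatError / ValidationError."""
    text = stream if isinstance(stream, str) else stream.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("instance file must hold a JSON object")
    unknown = set(doc) - _INSTANCE_KEYS
    if unknown:
        raise FormatError(f"unknown instance keys: {sorted(unknown)}")
    try:
        nodes = {str(v) for v in doc.get("nodes", [])}
        edges = set()
        weight = {}
        for item in doc.get("edges", []):
            if not isinstance(item, (list, tuple)) or len(item) not in (2, 3):
                raise FormatError(f"edge entry must be [u, v] or [u, v, w], got {item!r}")
            u, v = str(item[0]), str(item[1])
            edges.add((u, v))
            if len(item) == 3:
                weight[(u, v)] = float(item[2])
        dag = Dag(nodes, edges, weight)
        pairs = []
        for item in doc.get("pairs", []):
            if not isinstance(item, (list, tuple)) or len(item) != 2:
                raise FormatError(f"pair entry must hold two node lists, got {item!r}")
            pairs.append((as_path(item[0]), as_path(item[1])))
        return Instance(
            dag=dag,
            required_nodes={str(v) for v in doc.get("required_nodes", [])},
            required_edges={(str(u), str(v)) for u, v in doc.get("required_edges", [])},
            subpaths=tuple(as_path(p) for p in doc.get("subpaths", [])),
            pairs=tuple(pairs),
            starts={str(v) for v in doc.get("starts", [])},
            ends={str(v) for v in doc.get("ends", [])},
        )
    except (TypeError, KeyError) as exc:
        raise FormatError(f"malformed instance file: {exc}") from exc


def instance_to_dict(instance: Instance) -> dict:
    """Canonical (sorted) JSON-ready form of an instance; round-trip stable."""
    dag = instance.dag
    edges = []
    for u, v in sorted(dag.edges):
        if (u, v) in dag.weight:
            edges.append([u, v, dag.weight[(u, v)]])
        else:
            edges.append([u, v])
    return {
        "nodes": sorted(dag.nodes),
        "edges": edges,
        "required_nodes": sorted(instance.required_nodes),
        "required_edges": [list(e) for e in sorted(instance.required_edges)],
        "subpaths": [list(p) for p in instance.subpaths],
        "pairs": [[list(p), list(q)] for p, q in instance.pairs],
        "starts": sorted(instance.starts),
        "ends": sorted(instance.ends),
    }


def write_instance(instance: Instance, stream: IO[str]) -> None:
    json.dump(instance_to_dict(instance), stream, indent=1)
    stream.write("\n")


def solution_to_dict(solution: CoverSolution) -> dict:
    return {
        "problem": solution.problem,
        "num_paths": solution.k,
        "paths": [list(p) for p in solution.paths],
        "total_weight": solution.total_weight,
        "satisfied": solution.satisfied,
    }


def write_solution(solution: CoverSolution, stream: IO[str]) -> None:
    json.dump(solution_to_dict(solution), stream, indent=1)
    stream.write("\n")


def read_solution(stream: Stream) -> CoverSolution:
    text = stream if isinstance(stream, str) else stream.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    try:
        return CoverSolution(
            paths=[as_path(p) for p in doc["paths"]],
            total_weight=float(doc.get("total_weight", 0.0)),
            problem=str(doc.get("problem", "mpc")),
            satisfied=bool(doc.get("satisfied", True)),
        )
    except (TypeError, KeyError) as exc:
        raise FormatError(f"malformed solution file: {exc}") from exc


def to_dot(dag: Dag, paths: Iterable = (), name: str = "G") -> str:
    """Graphviz DOT text for a Dag, optionally highlighting solution paths."""
    colors = ["red", "blue", "darkgreen", "orange", "purple", "brown", "cyan4"]
    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    for v in sorted(dag.nodes):
        lines.append(f'  "{v}";')
    colored = {}
    for i, path in enumerate(paths):
        col = colors[i % len(colors)]
        for a, b in zip(path, path[1:]):
            colored.setdefault((a, b), col)
    for u, v in sorted(dag.edges):
        attrs = []
        if (u, v) in dag.weight:
            attrs.append(f'label="{dag.weight[(u, v)]:g}"')
        if (u, v) in colored:
            attrs.append(f"color={colored[(u, v)]}, penwidth=2")
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f'  "{u}" -> "{v}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"
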