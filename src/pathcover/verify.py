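"""Independent satisfaction checking of covers against instance constraints.

Every public solver runs its answer through :func:`verify_cover` before
returning it, so a returned solution is always a *certified* cover.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

from .graph import Instance, NodeId, Path


def contains_contiguous(path: Sequence[NodeId], sub: Sequence[NodeId]) -> bool:
    """True iff ``sub`` occurs as a contiguous block of ``path``."""
    p, s = tuple(path), tuple(sub)
    if len(s) > len(p):
        return False
    return any(p[k : k + len(s)] == s for k in range(len(p) - len(s) + 1))


def verify_cover(
    instance: Instance,
    paths: Iterable[Sequence[NodeId]],
    require_st: bool = False,
) -> Tuple[bool, List[str]]:
    """Check a family of paths against every constraint of ``instance``.

    Returns (ok, list of human-readable violations).  S/T endpoint membership
    is enforced when ``require_st`` is set or when the instance carries
    non-empty S/T sets.
    """
    paths = [tuple(p) for p in paths]
    violations: List[str] = []
    dag = instance.dag
    for p in paths:
        if not dag.is_path(p):
            violations.append(f"{p} is not a path of the graph")
    covered = set().union(*[set(p) for p in paths]) if paths else set()
    for v in sorted(instance.required_nodes - covered):
        violations.append(f"required node {v} uncovered")
    for e in sorted(instance.required_edges):
        if not any(e in zip(p, p[1:]) for p in paths):
            violations.append(f"required edge {e} uncovered")
    for sub in instance.subpaths:
        if not any(contains_contiguous(p, sub) for p in paths):
            violations.append(f"subpath constraint {sub} unsatisfied")
    for a, b in instance.pairs:
        if not any(
            contains_contiguous(p, a) and contains_contiguous(p, b) for p in paths
        ):
            violations.append(f"paired constraint ({a}, {b}) unsatisfied")
    if require_st or instance.weighted_fields_present():
        starts = instance.starts or set(dag.sources())
        ends = instance.ends or set(dag.sinks())
        for p in paths:
            if p[0] not in starts:
                violations.append(f"path {p} does not start in S")
            if p[-1] not in ends:
                violations.append(f"path {p} does not end in T")
    return (not violations), violations
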