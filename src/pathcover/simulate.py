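"""Synthetic splicing-graph instances with ground-truth transcripts.

A splicing graph abstracts a gene locus: nodes are pseudo-exons in genomic
order, and an edge joins two pseudo-exons that are consecutive in some
transcript.  The generator draws each transcript as an increasing
subsequence of the exon list, so the union of transcripts is automatically
a DAG and every ground-truth transcript is a path of it.  Long reads are
sampled as contiguous windows of a transcript (subpath constraints);
paired-end reads as two disjoint windows of the same transcript separated
by a gap (paired subpath constraints) -- so every sampled constraint is
satisfiable by its originating transcript by construction.

Everything is deterministic under the seed in :class:`SimulationParams`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Set, Tuple

from .errors import ValidationError
from .graph import Dag, Instance, NodeId, Path


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the splicing-graph simulation.

    Defaults describe a mid-sized locus: 20 pseudo-exons, 3 expressed
    transcripts, each transcript keeping an exon with probability 0.5,
    10 long reads spanning 3 consecutive pseudo-exons, 5 read pairs with a
    1-3 exon gap between mates.
    """

    num_exons: int = 20
    num_transcripts: int = 3
    edge_density: float = 0.5
    read_length: int = 3
    num_long_reads: int = 10
    num_pairs: int = 5
    gap_range: Tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.num_exons < 1 or self.num_transcripts < 1:
            raise ValidationError("exon and transcript counts must be positive")
        if not (0 < self.edge_density <= 1):
            raise ValidationError("edge_density must be in (0, 1]")
        if self.read_length < 2:
            raise ValidationError("read_length must be >= 2 for subpath sampling")
        if self.gap_range[0] < 0 or self.gap_range[0] > self.gap_range[1]:
            raise ValidationError("gap_range must be a non-negative interval")


def _exon_label(i: int, width: int) -> str:
    return f"e{i:0{width}d}"


def random_splicing_dag(params: SimulationParams) -> Tuple[Dag, Tuple[Path, ...]]:
    """A splicing-graph DAG plus its ground-truth transcript paths.

    Each transcript keeps each exon with probability ``edge_density``
    (resampled until it has >= 2 exons); exons missed by every transcript
    are inserted into a random transcript afterwards, so every node lies on
    at least one transcript.
    """
    params.validate()
    rng = random.Random(params.seed)
    width = len(str(params.num_exons))
    exons = [_exon_label(i, width) for i in range(1, params.num_exons + 1)]
    picks: List[List[int]] = []
    for _ in range(params.num_transcripts):
        while True:
            chosen = [i for i in range(params.num_exons) if rng.random() < params.edge_density]
            if len(chosen) >= 2 or params.num_exons == 1:
                break
        picks.append(chosen)
    covered = set().union(*map(set, picks))
    for i in range(params.num_exons):
        if i not in covered:
            t = rng.randrange(params.num_transcripts)
            picks[t] = sorted(set(picks[t]) | {i})
    transcripts = tuple(tuple(exons[i] for i in chosen) for chosen in picks)
    edges = {
        (t[k], t[k + 1]) for t in transcripts for k in range(len(t) - 1)
    }
    dag = Dag(set(exons), edges)
    assert all(dag.is_path(t) for t in transcripts if len(t) > 0)
    return dag, transcripts


def sample_long_reads(
    dag: Dag, transcripts: Tuple[Path, ...], params: SimulationParams
) -> Tuple[Path, ...]:
    """Long reads: contiguous ``read_length``-node windows of transcripts.

    A read from a transcript shorter than the read length is the whole
    transcript.  Uses a dedicated RNG stream (seed + 1) so read sampling
    does not perturb graph generation.
    """
    rng = random.Random(params.seed + 1)
    reads: List[Path] = []
    for _ in range(params.num_long_reads):
        t = transcripts[rng.randrange(len(transcripts))]
        span = min(params.read_length, len(t))
        start = rng.randrange(len(t) - span + 1)
        reads.append(t[start : start + span])
    return tuple(reads)


def sample_paired_reads(
    dag: Dag, transcripts: Tuple[Path, ...], params: SimulationParams
) -> Tuple[Tuple[Path, Path], ...]:
    """Read pairs: two disjoint windows of one transcript, gap nodes apart.

    Windows are shrunk (never below one node each) when the chosen
    transcript is too short for two full windows plus the gap, so each pair
    is individually satisfiable by construction.
    """
    rng = random.Random(params.seed + 2)
    pairs: List[Tuple[Path, Path]] = []
    for _ in range(params.num_pairs):
        t = transcripts[rng.randrange(len(transcripts))]
        gap = rng.randint(*params.gap_range)
        span = params.read_length
        while len(t) < 2 * span + gap and span > 1:
            span -= 1
        gap = min(gap, max(0, len(t) - 2 * span))
        if len(t) < 2 * span + gap:  # tiny transcript: fall back to endpoints
            pairs.append(((t[0],), (t[-1],)))
            continue
        start1 = rng.randrange(len(t) - 2 * span - gap + 1)
        start2 = start1 + span + gap
        pairs.append((t[start1 : start1 + span], t[start2 : start2 + span]))
    return tuple(pairs)


def simulate_instance(params: SimulationParams) -> Tuple[Instance, Tuple[Path, ...]]:
    """A full simulated instance (all nodes required, sampled constraints)
    plus the ground-truth transcripts."""
    dag, transcripts = random_splicing_dag(params)
    reads = sample_long_reads(dag, transcripts, params)
    pairs = sample_paired_reads(dag, transcripts, params) if params.num_pairs else ()
    instance = Instance(
        dag,
        required_nodes=set(dag.nodes),
        subpaths=reads,
        pairs=pairs,
    )
    return instance, transcripts


# ---------------------------------------------------------------------------
# Generic random DAGs and constrained instances (used by tests and the
# acceptance sweeps; kept here so the study conditions live in one place).
# ---------------------------------------------------------------------------

def random_dag(n: int, p: float, seed: int) -> Dag:
    """Random DAG: nodes v1..vn in a fixed order, forward edge with
    probability p."""
    rng = random.Random(seed)
    width = len(str(n))
    names = [f"v{i:0{width}d}" for i in range(1, n + 1)]
    edges = {
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return Dag(set(names), edges)


def _random_walk(dag: Dag, rng: random.Random, max_len: int) -> Optional[Path]:
    nodes = sorted(dag.nodes)
    v = rng.choice(nodes)
    path = [v]
    while len(path) < max_len:
        nxt = dag.successors(path[-1])
        if not nxt or rng.random() < 0.3:
            break
        path.append(rng.choice(nxt))
    return tuple(path) if len(path) >= 2 else None


def random_constrained_instance(
    n: int,
    seed: int,
    p: float = 0.35,
    max_subpaths: int = 3,
    weighted: bool = False,
    max_weight: int = 10,
) -> Instance:
    """A random instance for the subpath-constrained problems.

    All nodes required, up to ``max_subpaths`` random-walk subpath
    constraints; with ``weighted``, integer edge weights in [0, max_weight]
    and S/T = sources/sinks plus one random extra node each (when any
    non-source/sink node exists).
    """
    rng = random.Random(seed)
    dag = random_dag(n, p, seed)
    subpaths = []
    for _ in range(rng.randint(0, max_subpaths)):
        walk = _random_walk(dag, rng, max_len=4)
        if walk is not None:
            subpaths.append(walk)
    starts: Set[NodeId] = set()
    ends: Set[NodeId] = set()
    if weighted:
        dag.weight = {e: float(rng.randint(0, max_weight)) for e in dag.edges}
        starts = set(dag.sources())
        ends = set(dag.sinks())
        inner = sorted(dag.nodes - starts)
        if inner:
            starts.add(rng.choice(inner))
        inner = sorted(dag.nodes - ends)
        if inner:
            ends.add(rng.choice(inner))
    return Instance(
        dag,
        required_nodes=set(dag.nodes),
        subpaths=tuple(subpaths),
        starts=starts,
        ends=ends,
    )
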