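# pathcover

Minimum path covers of directed acyclic graphs with subpath and
paired-subpath constraints — the optimization core of genome-guided
multi-assembly (RNA-Seq transcript reconstruction, viral quasi-species).

## The problem

A splicing graph is a DAG *G* whose nodes are pseudo-exons and whose edges
join pseudo-exons consecutive in some transcript. Many assemblers predict
transcripts as a **minimum path cover** (MPC): the smallest family of
directed paths touching every node, computable in polynomial time on a DAG
(by Dilworth's theorem its size equals the maximum antichain). Sequencing
evidence refines this:

* **Subpath constraints** (long reads, transfrags): each given path
  *P<sup>in</sup>* must appear *contiguously* inside some solution path
  (problem MPC-SC, and its weighted variant MW-MPC-SC with edge weights
  *w* and allowed start/end node sets *S*, *T*).
* **Paired subpath constraints** (paired-end reads): two subpaths must lie
  on the *same* solution path, not necessarily adjacent (problem MPC-PSC).

This package implements the full family, exactly:

| problem | method | complexity |
|---|---|---|
| MPC / min-weight MPC | node-split min-flow / min-cost circulation with flow lower bounds | polynomial |
| MPC-SC | normalize, merge suffix/prefix-overlapping constraints (longest first), shortcut + subdivide, transitive closure, classical MPC, lift back | polynomial |
| MW-MPC-SC | same preprocessing through the subdivision stage; coverage as flow lower bounds in a min-cost circulation; return-arc cost > any path weight enforces (count, weight) lexicographic optimality | polynomial |
| MPC-PSC | NP-hard (reduction from graph 3-coloring, included as a generator); solved exactly as the chromatic number of the constraint *incompatibility graph*, FPT in the constraint count; OPT = 2 decided in polynomial time via bipartiteness | FPT |

The merge stage of MPC-SC is the delicate part: when a suffix of one read
is a prefix of another (and a different-length suffix prefixes a third),
reductions that skip the merge return provably too many paths. The
`overlap_chain_fixture` family reproduces this regression and the test
suite checks it against an exhaustive oracle.

## Worked example

Weighted diamond 1 → {2, 3} → 4, cheap upper branch
(w(1,2) = w(2,4) = 1), expensive lower branch (w(1,3) = w(3,4) = 10),
every node required, transcripts must end at 4:

```python
from pathcover import Dag, Instance, solve_mw_mpc_sc

dag = Dag({"1","2","3","4"},
          {("1","2"),("1","3"),("2","4"),("3","4")},
          {("1","2"):1, ("2","4"):1, ("1","3"):10, ("3","4"):10})
for starts in ({"1"}, {"1","3"}):
    sol = solve_mw_mpc_sc(Instance(dag.copy(), required_nodes=set(dag.nodes),
                                   starts=starts, ends={"4"}))
    print(sorted(starts), sol.k, sol.total_weight, sol.paths)
```

prints

```
['1'] 2 22.0 [('1', '2', '4'), ('1', '3', '4')]
['1', '3'] 2 12.0 [('1', '2', '4'), ('3', '4')]
```

Both covers use the minimum two paths, but letting a transcript start at
node 3 (e.g. a coverage jump inside an exon) avoids the expensive edge
(1,3): total weight drops from 22 to 12. Start/end sets must therefore be
part of the optimization — extending paths to sources/sinks after the fact
is not correct.

The `examples/` directory holds one short narrative script per capability
(classical MPC, long-read constraints, weighted covers, paired-end
constraints, the hardness gadget, splicing-graph simulation); each prints
the numbers it computes and what they mean. A thin CLI mirrors the
library:

```bash
pathcover gadget --graph k3 -o k3.json
pathcover mpc-psc k3.json --fpt-budget 30   # num_paths: 3
pathcover simulate --num-exons 20 -o sim.json
pathcover mpc-sc sim.json -o sol.json
pathcover verify sim.json sol.json
```

## Scope

Nodes are abstract pseudo-exons: the package does not parse alignments or
annotation formats (GTF/BAM/GFA) and does not estimate expression levels.
Instances are plain JSON (see `pathcover.io`); the synthetic generator in
`pathcover.simulate` provides splicing-graph-like inputs with ground
truth.
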