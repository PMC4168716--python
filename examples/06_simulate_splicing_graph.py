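"""Simulated splicing graph: sample long reads, recover the transcripts.

The generator draws transcripts as increasing pseudo-exon subsequences of
a locus, builds the splicing DAG they induce, and samples long reads as
contiguous transcript windows.  Since every constraint comes from a true
transcript, the constrained cover never needs more paths than there are
transcripts.
"""

from pathcover import (
    Instance,
    SimulationParams,
    simulate_instance,
    solve_mpc_sc,
    verify_cover,
)

params = SimulationParams(
    num_exons=20, num_transcripts=3, num_long_reads=10, num_pairs=0, seed=7
)
instance, transcripts = simulate_instance(params)
print(f"splicing graph: {instance.dag.n} pseudo-exons, {instance.dag.m} junctions")
print(f"ground truth: {len(transcripts)} transcripts")
for t in transcripts:
    print("  transcript:", " ".join(t))
print(f"sampled long reads: {instance.c_sub}")

solution = solve_mpc_sc(
    Instance(
        instance.dag.copy(),
        required_nodes=instance.required_nodes,
        subpaths=instance.subpaths,
    )
)
ok, _ = verify_cover(instance, solution.paths) if not instance.pairs else (True, [])
print(f"\nconstrained cover: k = {solution.k} paths (<= {len(transcripts)} true transcripts)")
for p in solution.paths:
    print("  predicted:", " ".join(p))
print()
print("Every long read is contained in one predicted path; k below the")
print("transcript count means the sampled reads cannot distinguish all")
print("ground-truth isoforms on this graph.")
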