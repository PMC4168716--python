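"""The NP-hardness reduction, run forwards.

From an undirected graph G the gadget builds a two-stage DAG P(G) with
paired subpath constraints such that P(G) has a 3-path solution iff G is
3-colorable.  Solving the gadget exactly therefore computes graph
3-colorability -- which is why no polynomial algorithm for paired
constraints is expected.
"""

from pathcover import hardness_gadget, named_source_graph, solve_mpc_psc

for name, chi in [("k3", 3), ("c5", 3), ("k4", 4)]:
    gadget = hardness_gadget(named_source_graph(name))
    inst = gadget.instance
    solution = solve_mpc_psc(inst, max_classes=40)
    print(
        f"P({name}): {inst.dag.n} nodes, {inst.c_pair} paired constraints"
        f" -> minimum paths = {solution.k} (source chromatic number {chi})"
    )

print()
print("The optimum tracks the chromatic number of the source graph: 3 paths")
print("exist exactly when the source is 3-colorable, and K4 (chromatic")
print("number 4) forces a fourth path.")
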