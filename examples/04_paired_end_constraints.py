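"""Path cover with paired-end constraints (the NP-hard variant).

A read pair pins two subpaths to the SAME solution path without making
them adjacent.  Two constraints are compatible when one directed path
contains both; the optimum equals the chromatic number of the
incompatibility graph, and OPT = 2 is decidable in polynomial time
(bipartiteness).
"""

from pathcover import (
    Dag,
    Instance,
    build_incompatibility_graph,
    solve_mpc_psc,
    solve_opt2,
)

chain = Dag(
    {str(i) for i in range(1, 6)},
    {(str(i), str(i + 1)) for i in range(1, 5)},
)

# A pair whose mates sit 2 exons apart on the chain.
paired = Instance(chain, pairs=(((("1", "2")), ("4", "5")),))
solution = solve_mpc_psc(paired)
print(f"chain with one read pair: k = {solution.k}")
print("  path:", " -> ".join(solution.paths[0]))
print("  (the gap 3 is filled by the connecting path)")

# Incomparable required nodes on a diamond: incompatible constraints.
diamond = Dag(
    {"1", "2", "3", "4"},
    {("1", "2"), ("1", "3"), ("2", "4"), ("3", "4")},
)
branches = Instance(diamond, required_nodes={"2", "3"})
inc = build_incompatibility_graph(branches)
print()
print(f"diamond branch nodes: {inc.graph.number_of_edges()} incompatibility")
two = solve_opt2(branches)
print(f"OPT = 2 decision: {'yes' if two is not None and two.k == 2 else 'no'}")
print(f"exact solver: k = {solve_mpc_psc(branches).k}")
print()
print("Three pairwise-incompatible constraints would make the graph an odd")
print("cycle: not bipartite, so OPT >= 3 and the FPT coloring takes over.")
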