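"""Path cover with long-read (subpath) constraints.

A long read pins a run of pseudo-exons that must appear consecutively in a
single predicted transcript.  The solver normalizes the constraints, merges
reads whose suffix is another's prefix (longest overlap first), reduces to
classical MPC, and lifts the answer back -- so overlapping reads chain into
one transcript instead of inflating the path count.
"""

from pathcover import Dag, Instance, solve_mpc_sc

chain = Dag(
    {str(i) for i in range(1, 6)},
    {(str(i), str(i + 1)) for i in range(1, 5)},
)

# Three staggered long reads tiling the chain with 2-node overlaps.
instance = Instance(
    chain,
    required_nodes=set(chain.nodes),
    subpaths=(("1", "2", "3"), ("2", "3", "4"), ("3", "4", "5")),
)

solution = solve_mpc_sc(instance)
print(f"cover size with 3 overlapping reads: k = {solution.k}")
for path in solution.paths:
    print("  path:", " -> ".join(path))
print()
print("The reads merge into one constraint spanning the whole chain, so a")
print("single path satisfies all of them; skipping the merge step would")
print("treat the reads as incomparable and report extra paths.")

# Contrast: a diamond where one read fixes the upper branch.
diamond = Dag(
    {"1", "2", "3", "4"},
    {("1", "2"), ("1", "3"), ("2", "4"), ("3", "4")},
)
constrained = Instance(
    diamond, required_nodes=set(diamond.nodes), subpaths=(("1", "2", "4"),)
)
solution = solve_mpc_sc(constrained)
print()
print(f"diamond with read 1-2-4: k = {solution.k}, paths = {solution.paths}")
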