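"""Neighbor-joining tree and non-metric MDS from an R_ST matrix.

Population relationships estimated from the R_ST matrix are visualized two
ways: a Saitou-Nei neighbor-joining tree (with the sum of branch lengths as
an overall divergence summary) and a Kruskal non-metric MDS embedding
(with stress-1 as the goodness-of-fit).
"""

from ystrkit import (
    RstConfig,
    SimConfig,
    distance_from_rst,
    neighbor_joining,
    nmds,
    rst_matrix,
    simulate_populations,
    sum_branch_lengths,
    to_newick,
)

dataset = simulate_populations(
    SimConfig(n_pops=6, pop_sizes=(30,) * 6, generations=30,
              within_generations=200, seed=19)
)
rst = rst_matrix(dataset, RstConfig(n_permutations=199, seed=2))
dm = distance_from_rst(rst)  # negatives clamped to 0 before tree/MDS

tree = neighbor_joining(dm)
print("Newick:", to_newick(tree))
print(f"sum of branch lengths (SBL) = {sum_branch_lengths(tree):.8f}")
print(f"negative R_ST entries clamped: {dm.n_clamped}")

embedding = nmds(dm, seed=4)
print(f"NMDS stress-1 = {embedding.stress:.5g} after "
      f"{embedding.n_iterations} iterations (initializer stress "
      f"{embedding.stress_initial:.5g})")
for label, (x, y) in zip(embedding.labels, embedding.coordinates):
    print(f"  {label}: ({x: .4f}, {y: .4f})")
print()
print("SBL grows with overall divergence among the populations; stress")
print("below ~0.05 means the 2-D map faithfully reproduces the rank order")
print("of the genetic distances.")
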