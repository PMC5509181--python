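"""Pairwise linkage-disequilibrium scan across the Y23 panel.

The male-specific region of the Y chromosome does not recombine, so panel
loci are inherited as one block and most pairs of polymorphic loci show
association.  Each pair is tested with a permutation G-test (likelihood
ratio on the two-locus contingency table).
"""

from ystrkit import SimConfig, ld_matrix, simulate_populations

# two diverged populations: the shared bipartition couples the loci
dataset = simulate_populations(
    SimConfig(n_pops=2, pop_sizes=(40, 40), generations=150,
              within_generations=40, mu=0.01, seed=11)
)
result = ld_matrix(dataset, n_permutations=199, seed=5)

print(f"locus pairs tested: {result.n_pairs}")
print(f"significant at alpha=0.05: {result.n_significant} "
      f"({result.percent_significant}%)")
top = sorted(result.pairs, key=lambda p: p.g, reverse=True)[:5]
print("strongest associations (G statistic, permutation p):")
for pair in top:
    print(f"  {pair.locus_a} - {pair.locus_b}: G = {pair.g:.2f}, p = {pair.p:.4f}")
print()
print("A high significant fraction is the expected signature of a")
print("non-recombining haplotype block: it is why Y-STR loci are reported")
print("as joint haplotypes rather than as independent markers.")
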