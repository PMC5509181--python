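# Methods

## Data model and panel conventions

A Y-STR allele is a non-negative integer repeat count, optionally carrying
a microvariant step in tenths of a repeat (`16.2` = 16 repeats + 2 bases;
steps are restricted to .1/.2/.3, the partial repeats that occur in
tetranucleotide STRs), or a null marker `0` recording locus dropout. Null
alleles compare equal to one another and carry no repeat information.

The PowerPlex Y23 registry holds 21 single-copy loci plus the duplicated
DYS385a/b (copy number 2), i.e. 23 allele columns. Two conventions are
applied at load time:

- **DYS385 as an unordered pair.** The two copies cannot be assigned to a
  chromosome arm by capillary electrophoresis, so the pair is sorted
  ascending and treated as one combined state wherever a categorical
  genotype is needed. Cells with three alleles are loaded and flagged as
  copy-number variants (they are needed downstream by the QC filter), not
  rejected.
- **DYS389II subtraction.** The DYS389II amplicon physically contains the
  DYS389I repeat block, so the reported DYS389II allele is the sum of both.
  The stored value is DYS389II − DYS389I, applied at load behind a flag
  that defaults to on and is recorded in dataset provenance (idempotent;
  null at either locus leaves the record unadjusted and flagged; a reported
  II < I is an error; a zero difference is kept with a warning flag).
  Tables are always *written* back in the reported convention so files
  round-trip.

## Diversity statistics

Per-locus gene diversity uses Nei's unbiased estimator
GD = (n/(n−1))(1 − Σpᵢ²) with frequencies by direct count. Null alleles
are excluded from GD by default (a deletion is not a repeat-count allele)
and reported separately as a dropout count; a flag includes them as a
category. DYS385 GD is computed on combined sorted pairs, one observation
per sample, so microvariant-bearing and CNV pairs form their own
categories.

Whole-haplotype parameters treat the full 23-column profile (DYS385
sorted; nulls and microvariants are legitimate distinguishing states) as
one category: MP = Σ(cᵢ/n)², HD = (n/(n−1))(1 − MP), DC = k/n. The
identity HD ≡ (n/(n−1))(1 − MP) holds to machine precision by
construction and is asserted in tests. Report rounding follows forensic
convention: GD/MP/DC to 4 decimals, HD to 5.

## AMOVA R_ST

The molecular distance between two clean haplotypes is
d = Σ_loci Σ_copies (a − b)², with DYS385's sorted copies matched
positionally (deterministic and order-free; with both pairs sorted this is
also the assignment minimizing the contribution). A one-level AMOVA
converts sums of squared distances to variance components:

- SSD_total = (1/N) Σ_{i<j} d_ij over the pooled sample,
- SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij,
- σ²𝓌 = SSD_within/(N − G), n_c = (N − Σn_g²/N)/(G − 1),
- σ²ₐ = (SSD_among/(G − 1) − σ²𝓌)/n_c, R_ST = σ²ₐ/(σ²ₐ + σ²𝓌).

R_ST may be slightly negative for undifferentiated pairs and is reported
as computed; it is clamped at zero only when a matrix is handed to the
tree/MDS stages (clamp count logged). A pooled sample with zero total
variance returns R_ST = 0 with a warning flag.

Before any R_ST computation, every sample with a null allele, an
intermediate allele, or a copy-number variant is removed (the sample, not
the locus, is the filter unit), with a per-sample reason log; a population
reduced below 2 samples is an error. An `excluded_loci` option additionally
supports DYS385-free runs.

Significance: population labels are permuted over the pooled pair
preserving group sizes, and p = (k+1)/(N+1) with k the number of
permutations whose R_ST is ≥ the observed value (ties counted, making the
test conservative rather than anti-conservative). The library default is
10 000 permutations; the bundled tests and examples use 99–999, which this
package treats as its default desk-scale problem sizes. Family-wise
correction uses α/m with m = C(L,2) computed from the data; an explicit
`bonferroni_m` override exists for reproducing reports that used another
divisor.

## Linkage disequilibrium

Y-STR panels sit on the non-recombining male-specific region, so loci are
expected to associate. Each locus pair is summarized by the likelihood-
ratio statistic G = 2 Σ O ln(O/E) on the two-locus allele-state
contingency table, with the null distribution obtained by permuting one
locus's allele column across samples (p = (k+1)/(N+1)). The permutation
null makes the test exact in distribution regardless of table sparsity, so
rare categories are not pooled. A monomorphic locus carries no
information: G = 0, p = 1 by convention, flagged. Argument order is
canonicalized so (A,B) and (B,A) give identical results for a fixed seed.

The full scan defaults to entering DYS385a and DYS385b as two separate
column loci (the smaller allele of the sorted pair is "a"), giving
C(23,2) = 253 comparisons on this panel — the layout a 23-locus report
uses; a combined mode (22 loci, 231 pairs, the pair as one categorical
state) is available. Significance is uncorrected α = 0.05, matching how
such scans are usually summarized ("x of 253 pairs significant").

## Neighbor joining

Saitou–Nei NJ on the clamped distance matrix: repeatedly join the pair
minimizing Q_ij = (m−2)d_ij − r_i − r_j, assign branch lengths by the
three-point formulas, reduce, and finish at an unrooted trifurcation.
Q-ties break to the lowest-index pair, making the topology deterministic.
Negative branch lengths are kept by default — they are exactly what makes
NJ recover additive matrices to machine precision — with an optional
MEGA-style clamp that zeroes a negative branch and transfers the deficit
to its sibling. The sum of branch lengths (SBL) is the arithmetic sum over
all branches, internal ones included. Newick export quotes labels
containing spaces and writes lengths at full precision.

## Non-metric MDS

Kruskal NMDS in 2 dimensions (the standard choice for population plots)
minimizing stress-1 = sqrt(Σ(d − d̂)²/Σd²), where d are configuration
distances and d̂ the disparities from isotonic regression of d on the rank
order of the input dissimilarities (primary approach to ties). The
configuration is initialized from classical (Torgerson) scaling — a tiny
seeded jitter is added only if that configuration is degenerate — and
updated by Guttman transforms. Because the stress-1 denominator moves with
the configuration, a raw Guttman step can occasionally increase stress-1;
each step therefore carries a backtracking line search (step halving, up
to 12 times) and iteration stops when no improving step exists or the
improvement falls below `tol` (default 1e-6, max 500 iterations). The
recorded stress trace is consequently non-increasing on every run. Both
the final stress and the initializer's stress are reported, since "the
stress" of a configuration is otherwise ambiguous.

## Synthetic-data generator

The simulator emulates a multi-population Y-STR survey under a strict
single-step stepwise mutation model: each allele copy mutates with
per-generation probability `mu` (default 2×10⁻³, the order of measured
Y-STR rates) and moves ±1 repeat with equal probability, reflecting at 1
repeat. DYS385's two copies mutate independently. Divergence is produced
by independent drift from shared founders in two phases: each population's
founder drifts `generations` rounds from a common ancestral haplotype
(drawn uniformly per locus from 10–16 repeats unless explicit founders are
given), then each sampled lineage drifts `within_generations` rounds
(default 200) below its population founder. Expected squared repeat
differences are then 2·mu·g_within per locus within populations and
2·mu·(g_between + g_within) between, so the expected R_ST is approximately
g_between/(g_between + g_within) — a direct, mutation-rate-free dial for
the divergence level, which the defaults (20/200) place at the weak
structure (≈0.1) end typical of intra-regional comparisons. Per-locus `mu`
overrides allow low-diversity loci with one dominant allele (the skewed
frequency spectra real panels show at loci like DYS438).

Artifacts are injected after simulation, so a pristine truth dataset
always exists: per sample-locus cell, a null (all copies dropped) or an
intermediate (+0.2 on one copy) with the configured rates; per sample, a
DYS385 third-allele duplication. These are exactly the three classes the
R_ST QC filter removes.

What the generator does *not* emulate: coalescent genealogy within
populations (lineages are independent below the founder, so haplotype
sharing is rarer than in real samples), locus-specific calibrated mutation
rates, multi-step mutations, migration, and uneven real-world sampling.
Passing tests therefore demonstrate correctness of the estimators and
machinery under a known model, not distributional realism of any
particular population.

## Pipeline and reproducibility

`run_full_analysis` chains load/simulate → QC → diversity → LD → R_ST →
tree + MDS. All randomness derives from one master seed through fixed
per-stage offsets; derived seeds are recorded in the report's provenance
block, and a re-run with the same config is byte-identical. Stages whose
preconditions fail (one population; a population depleted by QC) are
skipped with an explanatory log entry while earlier outputs are kept.

## Numerical and testing choices

- Permutation counts in tests (99–999) and replicate counts (20–400) are
  the package's desk-scale defaults; the permutation estimator
  p = (k+1)/(N+1) is exact at any N ≥ 99.
- Oracles: R_ST is checked against a from-scratch pairwise-SSD enumeration;
  the G statistic against scipy's log-likelihood-ratio contingency test;
  NJ against randomly generated additive trees (path-length oracle) and
  scikit-bio's implementation; Newick round-trips through dendropy; NMDS
  against its own classical-scaling initializer (final stress must
  dominate it).
- Known limitations: the simulator's reflecting boundary at 1 repeat
  slightly biases drift for very low repeat counts (founders start at
  10–16, where it is essentially never hit); DYS385 positional pairing of
  sorted copies is one of several defensible distance conventions; the LD
  significant-fraction on simulated data depends strongly on the
  divergence scenario and is a qualitative, not quantitative, reproduction
  of real panel scans.
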