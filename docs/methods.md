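# Methods

## Networks

A PPI network is a simple undirected graph over protein accession strings:
no self-interactions, no parallel edges, case-sensitive identity, no
direction or weight. Source files may carry directions, scores or metadata;
all of it is discarded except a per-edge set of source labels, which survives
union-merging so a unified network built from several interaction databases
retains provenance. A protein belongs to a network only by having an
interaction: nodes whose only record was a self-loop are dropped by default
(`keep_isolated=True` retains them). Induced subnetworks keep exactly the
input proteins found in the network and the interactions among them, and
report mapping coverage as an integer percent, `round(100·|mapped|/|input|)`.

## Short loops

A short loop of length k is a simple cycle of k distinct proteins. Length 3
is the default throughout; longer loops add computational cost without, in
our hands, changing the topological or functional picture, so length 4 is
provided for sensitivity checks only. Triangles are enumerated by
neighbour-set intersection anchored at each edge's lexicographically smallest
endpoint, so each 3-clique is produced exactly once in a deterministic
canonical order (sorted member tuple). 4-cycles are found by scanning
diagonal pairs and their common neighbours, canonicalised to the
lexicographically smallest rotation/reflection. A 4-cycle with a chord still
counts by default — a short loop is a cycle, not an induced cycle — and
`chordless=True` gives the stricter alternative. Both enumerators are
verified against exhaustive subset scans in the test suite.

The loop ratio `n_loops / n_edges` normalises away the strong dependence of
loop counts on network size; it is computed at full precision and reported to
2 decimals.

## Functional consensus

A loop has consensus when the intersection of its members' annotation term
sets is non-empty; the graded variant reports `100·|∩|/|∪|`. Matching is by
exact term identifier: the statistic is meant to be independent of where the
shared term sits in an ontology hierarchy, so no ancestor propagation is
performed (pre-close the annotation table if hierarchy-aware sharing is
wanted). A loop containing an unannotated protein cannot have consensus and
by default stays in the denominator (`count-as-no-consensus`); the `exclude`
policy removes such loops from both numerator and denominator, and the
network statistic is reported as absent when nothing remains. The
network-level consensus ratio is the percentage of loops with consensus.

## Short loop commonality

From the triangle set, each protein X accumulates partner pairs: {A, B} for
every triangle {X, A, B}. Proteins X and Y are a commonality pair when (i)
there is no X–Y edge, (ii) they share at least `min_shared = 3` partner
pairs, and (iii) the shared count is at least `min_frac = 0.95` of *each*
protein's pair set. The fraction criterion is applied symmetrically because
the motif being modelled has identical loop sets on both sides and the
symmetric reading is the strictest consistent one; `frac_mode="either"`
relaxes it to one side. Proteins with no partner pairs are never candidates
(their fraction is undefined). Detection inverts the pair→owner map so only
proteins sharing at least one partner pair are compared; output order is
lexicographic, and an exhaustive pair-scan oracle checks equivalence on small
graphs.

Commonality pairs form their own network (pairs as edges); its summary
reports the mean neighbour count `2·n_pairs/n_nodes` to 2 decimals and
connected-component sizes. A *control set* matched to a disease-derived pair
set consists of commonality pairs (A, B) of the unfiltered network, under the
same thresholds, where A appears in some disease pair, B carries no disease
mutation, and (A, B) is not itself a disease pair.

## Null models

The null for a subnetwork statistic draws protein subsets of the observed
subnetwork's size uniformly at random without replacement from the reference
network, induces each subset's interactions, and recomputes the statistic
(`loop3_ratio` or the commonality network's mean neighbour count). Sampling
is uniform over proteins, not degree-matched: the null asks "what does a
random protein set of this size look like", not "a random set with this
degree sequence"; degree-preserving rewiring is out of scope. A draw on which
the statistic is undefined (no edges, or no commonality pairs) scores 0 and
is counted in `n_degenerate` rather than redrawn — redrawing would condition
on non-degeneracy and bias the null upward. The sample standard deviation
uses the n−1 denominator; a constant sample list is treated as exactly
degenerate (sd = 0) rather than float-epsilon noise. z-scores are
`(observed − mean)/sd`, with signed infinity flagged when sd = 0. All
sampling flows through `numpy.random.default_rng(seed)` and is bit-stable
under a fixed seed.

Reference run sizes are 2000 samples for loop-ratio nulls and 10 000 for
commonality nulls; tests use a few hundred samples on networks of 40–200
proteins, which is ample to pin the moments at the 3-standard-error
tolerances asserted.

## Mutations, hotspots, MHRD

Mutation tables carry one record per observed mutation: protein, patient
sample id, 1-based residue position (insertions/deletions use their start
position) and a type label. The default allowed set is the non-synonymous
types (nonsense/missense substitutions, in-frame/frameshift
insertions/deletions, complex); rows outside it are dropped, and proteins
observed in fewer than 2 distinct patients are removed entirely, so
single-case observations never drive downstream statistics. The per-residue
variant frequency `n_variants / length` assumes mutability scales with
sequence length.

A hotspot is a position holding at least `min_fraction = 5 %` of the
protein's mutations, in at least `min_samples = 2` distinct samples; both are
configurable since hotspot conventions vary. MHRD is the fraction of a
protein's mutations that fall on its hotspot positions. Its significance is
assessed against a uniform null: `n_sims` simulations each scatter the
observed number of mutations independently and uniformly over positions
1..L and record the mass landing on the *fixed* observed hotspot positions.
Keeping the positions fixed (rather than re-detecting hotspots per
simulation) makes the null statistic exactly Binomial(N, |H|/L)/N, which the
tests exploit as a closed-form oracle, and matches the question actually
asked — is this much mass on these positions surprising under uniformity?
The p-value is the add-one-smoothed upper tail `(r+1)/(n_sims+1)`, so it is
never 0 and is valid conservatively; the z-score standardises the observed
MHRD by the simulated null moments. When every position is a hotspot the
null is degenerate: z is reported as 0 (observed equals the null mean) and
p as 1.

## Gene dependency

Dependency matrices are consumed as given (cell line × gene scores normalised
so non-essential ≈ 0 and median essential ≈ −1); a line is dependent on a
gene iff its score is strictly below −1. For a gene pair the binary profiles
are crossed over lines with non-missing scores for both genes
(pairwise-complete). Classification is by counts, not p-values: dependency
profiles are sparse and near-binary, which makes Fisher p-values a poor
primary filter, so both one-sided Fisher exact p-values (scipy
implementation, cross-checked against full hypergeometric enumeration in the
tests) are attached for ranking only. Mutual exclusivity requires zero
co-dependent lines (the strictest reading of "either X or Y"; `max_overlap`
relaxes it), at least 2 lines dependent on each gene alone, and each gene
dependent in strictly less than 50 % of lines — the essentiality cap that
removes housekeeping genes every line depends on. Co-occurrence requires at
least 2 co-dependent lines under the same cap. The two classes cannot both
hold, and both rules are symmetric in gene order.

## Synthetic data

The generators produce every input format the readers consume, each with a
recorded ground truth:

- `gen_er_network` — Erdős–Rényi G(n, p) backgrounds.
- `gen_planted_commonality` — the commonality motif itself: a hub pair (X, Y)
  with no X–Y edge and a *chained* fan of partner pairs (AB, BC, CD share
  members), every chain node connected to both hubs. Chaining reproduces the
  motif being modelled exactly; motif node labels are disjoint from the
  background so at zero background density detection is provably exact.
- `gen_planted_control` — a two-layer variant: an unmutated third hub wired to
  the same chain yields known control pairs in the general network while the
  disease subnetwork keeps only the (X, Y) pairs.
- `gen_annotations` — each triangle independently consensual with probability
  `p_consensus` via a triangle-unique shared term; private per-protein terms
  otherwise, so on node-disjoint triangles the consensual count is exactly
  binomial.
- `gen_mutations` — exact hotspot-mass allocation (`round(mass·n)` records on
  the planted positions, the rest uniform elsewhere), so planted MHRD is
  recovered identically.
- `gen_dependency` — disjoint 3-line dependent blocks for mutually exclusive
  pairs, one shared block for co-occurring pairs, ≤ 1 dependent line per
  decoy; dependent scores drawn in (−2.5, −1.5), others in (−0.4, 0.4), so
  binarisation at −1 recovers the blocks exactly at zero noise.

What the generators do *not* emulate: scale-free degree distributions, the
correlated multi-database error structure of real interactomes, ontology
hierarchy in annotations, sequencing artefacts in mutation calls, or
screen-level batch effects in dependency scores. Passing the planted-recovery
tests therefore demonstrates correctness of the detectors' logic at their
stated criteria, not robustness to real-data noise.

## Numerical and design choices

- Ratios and percentages are computed at full precision and rounded only at
  the reporting layer (2 decimals; coverage to integer percent).
- All thresholds default to the reference analysis values: k = 3,
  min_shared = 3, min_frac = 0.95, dependency threshold −1 (strict),
  min_patients = 2, hotspot fraction 5 % / 2 samples, 2000 / 10 000 null
  samples.
- Binarisation and the essentiality cap use strict inequalities as stated
  ("< −1", "< 50 %", "> 1 line" ⇒ ≥ 2).
- Degenerate inputs are explicit: loop ratio on an edgeless network, MHRD on
  an empty record list and mean neighbours of an empty pair set are errors or
  reported-absent, never silent zeros; zero-margin Fisher tables give p = 1.
- Test problem sizes (graphs ≤ 60 nodes, a few hundred null samples, 20 000
  hotspot simulations) were chosen as the smallest sizes at which the
  closed-form and brute-force oracles pin every statistic at 3-standard-error
  tolerances.

## Known limitations

- Commonality is defined for length-3 loops only; partner-pair sets have no
  length-4 analogue here.
- Uniform (not degree-matched) null sampling overstates significance for
  statistics strongly driven by hubs.
- The hotspot null is uniform over the full sequence; domain-restricted or
  mutability-weighted nulls are not implemented.
- Exact reproduction of full-scale published network statistics requires the
  original deposited interaction, mutation and screen datasets; this package
  reproduces the derived statistics those publications print and verifies all
  algorithms on synthetic data with known truth.
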