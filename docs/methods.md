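# Methods

This note documents the models and algorithms implemented in `paleokaryo`,
the parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Homology filtering (CIP/CALP)

A gene pair's HSPs are first trimmed on the query axis (within an overlap the
HSP with the higher identity fraction owns the positions), then summarized as

- CIP = 100 × Σ identities / Σ aligned length (cumulative identity %),
- CALP = 100 × Σ aligned length / query length (cumulative aligned-length %).

Trimming guarantees CALP ≤ 100 and makes the statistic idempotent under
duplicated HSPs and invariant to HSP order. The retention rule is inclusive:
CIP ≥ 60 **and** CALP ≥ 70 by default, the parameterization classically used
to call orthologs/paralogs for synteny work. The denominators are
conventions, not laws: the module is unit-agnostic (amino acids or codons)
and the thresholds are plain arguments. A pair passing in at least one query
direction is kept (a "both directions" mode exists).

Event labels (ρ, α, β, γ, speciation nodes) come from the posterior of a
fitted Ks mixture; exact posterior ties go to the component with the lower
log-Ks mean, which biases ties toward younger events — ties occur only at
component boundaries and are logged.

## Synteny blocks

The block detector is a transparent chaining algorithm honouring the three
classic Closeup parameters: anchors chain while both rank gaps are ≤ CL
(cluster length, 20 gene ranks) with a monotone partner direction; chains
need ≥ MN (match number, 5) anchors; and a chain is kept when its anchor
density is at least DR (density ratio, 2) times the *local background* — the
anchor density of the same chromosome pair outside the candidate. Comparing
against the outside-density rather than the whole-pair density matters: on a
fully syntenic chromosome pair the whole-pair density equals the block's own
density and a global ratio test would reject everything. Whether CL counts
gene ranks or anchors is a free choice; gene ranks are used. Overlapping
candidates are resolved greedily (more anchors, then denser, then
lexicographic), so retained blocks partition their anchors. Tandem arrays
are collapsed to their first member before anchoring.

## Ancestral gene order: sandwich matrix and PQ-tree

Markers are informative gene families: present with exactly the expected
copy number (default 1) in each genome where they occur, linked by a
retained ortholog pair across a genome pair whose most recent common
ancestor is the target node. Restricting to such *informative pairs*
prevents within-clade adjacencies from contaminating an older ancestor.

Contiguity is always evaluated in marker rank space — intervening non-marker
genes are invisible. An adjacency is a marker pair contiguous in ≥ 2
informative genomes; a common interval is a marker set contiguous, in any
internal order, in both genomes of a pair (only maximal intervals are kept,
computed by an O(n²) window scan per chromosome). Both become rows of the
sandwich matrix: 1 for markers inside the constraint, 0 for markers present
in both genomes of the supporting pair but outside it, X otherwise.

Ordering the columns so that no 0 lies between two 1s in any row is NP-hard
with X entries, so the solver is staged:

1. rows without X are exact consecutive-ones constraints and are reduced on
   a PQ-tree (the tree represents *exactly* the permutations satisfying the
   constraints so far; this is fuzz-verified against exhaustive permutation
   filtering, including the admissible-arrangement count);
2. X-bearing rows are inserted greedily in decreasing support order using
   the stronger all-columns-consecutive reduction; rows that fail are
   discarded and logged;
3. a component that still has unsatisfied rows and ≤ 9 markers is re-solved
   by an exact depth-first search over orders with prefix pruning.

Connected components of the row hypergraph become CARs; markers in no row
are reported unplaced. Each CAR is oriented to maximize Spearman rank
correlation with a declared reference genome. A CAR whose PQ-tree admits
more than one order besides full reversal (or a two-marker CAR, whose
internal order is arbitrary) carries an `order_ambiguous` flag. The greedy
stage may discard rows a perfect sandwich solver could satisfy; the exact
small-component fallback removes this slack where it is affordable.

## Pre-WGD reconstruction by double conserved synteny

An ancestral gene is a base gene with exactly two orthologs on two distinct
chromosomes of the duplicated genome (duplication mode), or a gene family
whose surviving paralogous copies occupy 2–3 distinct chromosomes
(triplication mode, for the hexaploidy). Segments are maximal runs of
ancestral genes, strictly contiguous in ancestral-gene space on the base
and on every copy chromosome — zero flexibility, so a gene without the
clean copy pattern breaks the run, as does a change of companion
chromosomes. In triplication mode an ancestral gene may be witnessed by a
single surviving paralog pair (fractionation usually destroys one partner of
the third copy); a strict three-copy mode exists. The same triplet is found
from each of its three chromosomes, so candidates are deduplicated greedily
by size over disjoint family sets.

Significance: the original DCS significance statistic is not reconstructable
from its published description, so the package uses a permutation null —
gene labels are shuffled within chromosomes, the scan is re-run, and the
null distribution of the *maximal* segment size over the whole comparison is
recorded (default 200 permutations; `p = (1 + #{max ≥ n}) / (B + 1)`).
Using the maximum makes the p-values conservative (super-uniform) by
construction, which the tests verify. Benjamini–Hochberg control at
FDR 0.05 follows; segments below 2 genes are never called significant.

Significant segments then act as markers: adjacencies and common intervals
over their projections onto every chromosome feed the same consecutive-ones
solver, this time on a 0/1 matrix with no X entries (every marker is present
in the genomes compared). Expanding segment CARs gene-wise follows base-run
order, reversing a segment when that chains with its predecessor's span.

## Subgenome dominance and the two-step model

Retention counts are tallied per triplicated block and modern genome from a
block painting. Within each homoeologous triplet, the three pairwise
comparisons use the exact binomial test B(n₁+n₂, ½), two-sided by the
minimum-likelihood convention (outcomes whose pmf does not exceed the
observed one are summed); significance is strict, p < 0.005, with **no**
multiple-testing correction across the pairwise tests — that is the
published protocol, and a BH option exists but is off by default. A block is
sensitive (S) if significantly below any triplet partner, dominant (D)
otherwise; triplets without any significant pair are all-D with a `no_bias`
flag, all-zero triplets are NA. Counts are pooled across genomes by default;
a per-genome mode calls a pair significant on a majority of genomes and
Fisher-combines the per-genome p-values for reporting. A chi-square
goodness-of-fit cross-check is provided.

The two-step allohexaploidy model assigns each triplet one block to each of
subgenomes A, B, C with expectation A, C → D and B → S. The search scores
all six assignments per triplet; because the objective is separable this
equals the full 6⁷ enumeration (verified against explicit enumeration in the
tests). D/S labels cannot distinguish A from C within a triplet (both expect
D), so such ties are broken toward a supplied reference assignment when
given, otherwise toward the triplet's stated (A, B, C) member order, with
the number of tied optima reported. The published C list contains a
typographical duplicate (A16, which belongs to A) and omits A18; the
package's built-in rosid configuration assigns A18 to C — the unique
completion giving 21 disjoint blocks — and reproduces the published 20/21
consistency with A14 the sole exception.

## Ks dating

T = Ks/(2r) with r = 6.5×10⁻⁹ substitutions per synonymous site per year by
default. Mixtures of log-normal components are fitted by expectation-
maximisation on log Ks (10 restarts, tolerance 10⁻⁸, seeded and
deterministic; the log-likelihood is asserted non-decreasing on every fit),
and k is chosen by plain BIC over the requested range. Ks > 3 is treated as
saturated and excluded by default. The "central Ks" used for dating is
exp(μ) — the log-normal median — with the true mode exp(μ − σ²) available;
at the fitted σ ≈ 0.1 the two differ by ≈ 1%. The optional exponential
component for very recent tandem duplicates is off by default. An
independent cross-check against scikit-learn's Gaussian mixture on the same
log-Ks data is part of the test suite.

## Karyotype events

`paint_genome` labels each modern gene with the protochromosome of its
family and keeps maximal same-label runs; runs shorter than 5 genes
(configurable) are absorbed into their larger flanking segment, suppressing
single-gene transposition noise. Two fused post-WGD copies of the *same*
protochromosome are separated by a rank-revisit rule: within one copy the
ancestral ranks run strictly monotone, so a rank falling inside the span
already covered signals a second copy; adjacent same-label segments are
re-merged only when their ancestral spans are disjoint. `count_events` reads

- Cfus = Σ over modern chromosomes (segments − 1),
- Cfis = Σ over ancestral chromosomes (segments of it − WGD factor),

treating post-WGD copies separately — the reading under which the published
per-lineage equations balance — and checks the conservation identity
n_modern = n_anc × WGD + Cfis − Cfus. Inversions change no segment counts
and are invisible here by design; with inversions *and* same-protochromosome
fusions in one genome the revisit rule can over-split, which is the main
known approximation of this module.

## The synthetic-data generator

The simulator emulates the inferred rosid history: an n = 7 ancestor
(default 200 genes per chromosome), a two-step hexaploidy with
subgenome-specific retention probabilities pA = 0.9, pB = 0.4, pC = 0.95 —
the dominant/sensitive/dominant pattern of the A + B tetraploidization
followed by C hybridization — and descendant lineages with optional WGDs,
fissions (uniform internal split), telomeric fusions (end-to-end join of two
uniformly chosen chromosomes, second copy possibly reversed), inversions,
and uniform gene loss. A family losing all three hexaploid copies keeps one
on the most retentive subgenome, so the ancestral repertoire survives
(complete gene extinction would merely shrink the reconstructable ancestor).
Event ages default to 125 My for the hexaploidy, 60 My for shared lineage
WGDs and 11 My for recent ones, inside the published ranges for γ, α/β and
ρ; with r = 6.5×10⁻⁹ these give Ks centres 1.625 / 0.78 / 0.143. Ks values
are 2rT times exp(N(0, 0.1)) noise. All randomness flows through one seeded
generator; every event is logged in enough detail for exact replay, which
the tests assert.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: gene-family birth/death and tandem
expansion, translocations, annotation error, rate heterogeneity across
families (Ks noise is homoskedastic), missing or fragmented assemblies, and
partial synteny decay by small-scale rearrangement. Recovery metrics are
computed on the truth *projected to the reconstructed marker set*, so they
measure ordering quality of what was reconstructed, not repertoire
completeness (which losses necessarily shrink).

## Numerical and design notes

- Tie-breaks are lexicographic and logged throughout (rank ties in gene
  tables, block overlap resolution, CAR orientation, posterior ties).
- The permutation p-value uses the +1 correction, so it is never 0 and never
  anti-conservative at small B.
- `order_c1p` is deterministic: rows are sorted by (support, size, ids) and
  PQ-tree frontiers are canonical.
- Problem sizes in the test and acceptance suites (7 × 200-gene
  chromosomes, 200–1000 permutations, 50-replicate BIC studies) were chosen
  as the smallest scales at which the statistical assertions are stable;
  all complete in a few minutes on one CPU.

## Limitations

- The sandwich solver is exact only for X-free rows and small conflicted
  components; large components with many X-bearing conflicts may discard
  more rows than a perfect solver.
- Chained reconstructions through two stacked WGDs are done one WGD at a
  time; there is no joint two-WGD mode.
- Block significance is the DR density criterion only; no analytic block
  p-value is computed.
- The painting-based event counter assumes fusions/fissions dominate; heavy
  translocation would be misread as extra fusion/fission pairs.
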