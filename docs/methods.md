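# Methods

`phylorec` implements the computational core of a multilocus clonality study
for haploid organisms (its motivating use case is fungal species complexes
typed at three unlinked loci): recombination detection, genealogical
concordance species recognition, a border scan for recombining populations,
and population divergence statistics, together with a coalescent-based
generator of synthetic datasets with known truth.

## Data model

A dataset is a strain manifest (one record per haploid isolate, with
collection numbers, origin, subclade label, teleomorph/ex-type flags and one
GenBank accession per locus) plus one aligned FASTA per locus whose headers
are the manifest's strain ids.  All coordinates are 0-based, half-open.
Sequences are upper-cased with `U` normalised to `T`; the alphabet is the
IUPAC nucleotide codes plus `-`.  For every statistic, gap and ambiguity
characters count as missing; "complete deletion" drops columns containing any
missing character, "pairwise deletion" drops them per sequence pair.

Clone correction collapses strains whose concatenated aligned rows are
exactly identical (string equality, gaps and ambiguity codes compared
literally) to the first strain in manifest order.  This is deliberately
strict: the alternative — comparing under ambiguity expansion — would make
haplotype identity non-transitive.

The column filter is a minimal stand-in for alignment-trimming tools: a
column is dropped when the fraction of rows carrying `-` or an ambiguity code
exceeds `max_gap_fraction`.  It does not attempt conservation-based trimming.

## Recombination tests

### Pairwise homoplasy index (Phi)

For two aligned columns restricted to their mutually called rows, with `V`
distinct joint states, `C` connected components of the graph linking joint
states that share a state at either site, and `k_a`, `k_b` per-site state
counts, the refined incompatibility score is

    l(a, b) = (V - 1) + (C - 1) - (k_a - 1) - (k_b - 1).

`V + C - 2` is the minimum summed parsimony length of the two sites on their
best common tree (moving between joint states inside a component costs one
change, bridging components costs two), so `l` is the number of extra,
homoplasious changes the pair forces; `l = 0` iff the sites are compatible,
and the classic four-gamete conflict of two biallelic sites scores 1.  The
closed form is validated in the test suite against an exhaustive-topology
Fitch oracle; biallelic complete-data pairs are scored wholesale by a
vectorised four-gamete rule, which is the special case of the same formula.

Phi is the mean of `l` over all pairs of parsimony-informative sites (at
least two states each carried by at least two sequences) whose alignment
positions differ by at most `window_w` (default 100 nt, the published default
of the test).  The null permutes the informative sites among their positions.
Under clonality, homoplasy from recurrent mutation is position-independent
and the permutation test is exact; under recombination, genealogical
correlation decays with distance, so nearby pairs are more compatible than a
random re-arrangement makes them and the observed windowed mean falls in the
*left* tail: `p = (1 + #{perm Phi <= obs}) / (n_perm + 1)`.  An optional
analytic p-value applies a normal approximation with the permutation null's
mean and standard deviation; it is useful because the permutation
distribution is discrete (the incompatibility matrix is sparse on
desk-scale data), which makes the raw permutation p conservative.

When applied to a concatenation of unlinked loci, informative-site ordering
follows concatenated coordinates, so inter-locus pairs are mostly
out-of-window; Phi then mainly tests intra-locus recombination, which is the
documented behaviour.

### Index of association (IA)

Per-locus alleles are the distinct sequence strings at that locus.  The
distance between two haplotypes is the number of loci at which their alleles
differ; `V_obs` is the variance of this distance over all pairs and `V_exp`
the sum of per-locus mismatch-indicator variances (the linkage-equilibrium
expectation).  `IA = V_obs / V_exp - 1` is 0 under panmixia and positive
under association (clonality).  Population-variance convention is used; the
ratio is invariant to the divisor choice.  Clone correction is applied first
(it can be disabled for worked examples); monomorphic loci are dropped with a
warning.  The null permutes allele assignments independently per locus;
`p = (1 + #{perm IA >= obs}) / (n + 1)`.  The informal reading used in
clonality studies (IA below ~1 read as recombination, above as clonality) is
reported as a labelled secondary field; the permutation p is the formal
result.

### Partition homogeneity test (PHT / ILD)

`T_obs` is the sum over partitions (loci) of the maximum-parsimony tree
length on that partition's columns; replicates reassign columns to partitions
at random, preserving sizes.  Congruent (clonal) data leave `T` essentially
unchanged; loci that evolved on conflicting trees fit shorter trees alone
than random mixtures do, so recombination shows up as
`p = (1 + #{T_rep <= T_obs}) / (R + 1)` being small.  Tree lengths come from
the package's parsimony engine: random-order stepwise addition followed by
first-improvement NNI hill climbing (best of `n_starts`), or exhaustive
enumeration up to 11 taxa.  The Fitch kernel operates on IUPAC bitmask
patterns with multiplicity weights and is JIT-compiled with numba when
available (a semantically identical numpy fallback is included).  PHT
replicates default to 1000 (10 000 by flag); the statistical experiments in
the test suite use 200 to keep runtimes reasonable.

The ILD statistic is known to be blunt on low-homoplasy data: when every
column fits one tree, `T` is invariant to repartitioning and the p-value is
1 by construction.  The calibration experiment therefore runs at high
per-site mutation rates (theta = 30 per 150-nt locus, finite-site model),
where recurrent mutation supplies the conflict the statistic needs; even
there the test is somewhat conservative because the integer-valued replicate
distribution places appreciable mass exactly at `T_obs`.

## GCPSR

Gene trees (supplied as newick with supports, or built as NJ trees with
bootstrap supports) are reduced to clade tables: non-trivial bipartitions
with support at or above the threshold (default 0.95, the conventional
posterior-probability cutoff; bootstrap proportions are the desk-scale
surrogate here).  A candidate clade is *supported* in a locus iff its
restriction to that locus's taxa exactly equals a supported split side —
mere compatibility is not support — and *contradicted* iff some supported
split is incompatible with it (restricted four-point test; fewer than four
shared taxa is vacuously compatible).  A candidate is recognized as a
phylogenetic species when supported in at least one locus and contradicted in
none.  Candidates default to the union of every locus's supported clades;
the combined-concatenation tree is intentionally *not* counted as an
independent gene tree.

## Border scan

The scan formalises a trial-and-error procedure for finding the borders of a
recombining population.  The baseline is a focal clade plus distant control
strains and must itself pass the Phi test (`p >= alpha`), otherwise a
baseline error is raised.  Candidates are ranked by mean patristic distance
to the focal clade on a supplied tree (ties break lexicographically) and
tested in ascending order.  In the default fixed-baseline mode each candidate
is tested as `baseline + {candidate}` and triggering candidates stay out of
later samples — this follows the procedure's rule of excluding the first
strain that indicates recombination, and makes step outcomes independent of
one another; cumulative mode (non-triggering candidates accumulate) is
provided for sensitivity analysis.  The scan continues past the first
trigger: the first triggering strain is the inner border, the most distant
one the outer border, and the recombining population is the focal clade plus
all triggering strains.  Per-step permutation seeds derive from the master
seed and the candidate id, so results are reproducible and per-step outcomes
do not depend on which other candidates were scanned.  No multiple-testing
correction is applied by default, matching how such scans are run in
practice; steps where Phi is not computable are recorded and skipped.

## Population statistics

Standard formulas: segregating sites `S` and Watterson `theta_w = S / a1`
(complete deletion); mean pairwise differences `pi` (pairwise deletion;
the complete-deletion variant is used inside Tajima's D so numerator and
variance share a site set); Tajima's D with the textbook `a1..e2` constants,
flagged undefined when `S = 0`.  FST is Hudson's `1 - Hw/Hb` with `Hw` the
pair-weighted mean within-population difference count and `Hb` the mean
between-population count; negative estimates are reported as computed.  The
Hudson-Kaplan `Rm` lower bound runs the four-gamete test over biallelic site
pairs and counts a maximal set of non-overlapping incompatible open
intervals by the standard left-to-right sweep.

## Synthetic data generator

Genealogies are Kingman coalescents (pairwise merging, waiting times
`Exp(k(k-1)/2)`, coalescent time units).  Mutation models: infinite sites
(`Poisson(theta/2 x tree length)` mutations, each at a distinct uniformly
drawn column — guarantees zero homoplasy, so Phi is identically 0 on clonal
output) and Jukes-Cantor (per-site rate `theta/(2 x length)` along each
branch, recurrent mutation possible).  Scenarios:

- **clonal** — one genealogy shared by all loci;
- **free_recomb** — an independent genealogy per locus;
- **intralocus** — each locus split into `n_blocks` contiguous blocks with
  independent genealogies (default 4 blocks);
- **structured** — two demes coalescing internally until the divergence time
  `tau`, then jointly (default `tau = 6`, deep enough that both demes are
  almost always reciprocally monophyletic at every locus);
- **border_scenario** — a clonal backbone (a tight core crown of 8 strains
  plus 5 controls on a ladder of long branches above it) and a halo of 10
  recombining strains.  Each halo strain has a "home" attachment point inside
  the core crown and re-draws it per block with probability
  `halo_intensity` (default 1.0), making its sequence a block mosaic of
  different core positions; intensity 0 collapses to full clonality.

Defaults describe a desk-scale study: 20 strains, three 300-nt loci,
theta = 10 per locus.  The border scenario uses 600-nt loci with theta = 16
and a control spacing of 0.4 coalescent units so that, per block, enough
mutations land inside the core crown to discriminate attachment points —
per-site diversity is then comparable to the fast-evolving intron-bearing
typing loci such scans are applied to.  All randomness flows from the single
config seed; identical configs reproduce datasets byte for byte.

### What the generator does not emulate

Real multilocus data have alignment gaps, rate heterogeneity across sites,
selection, and base-compositional bias; the generator has none of these.
Halo recombination is modelled by re-attachment of whole blocks rather than
an ancestral recombination graph — sufficient to create the
homoplasy/incongruence signal the tests detect, but not a model of
recombination breakpoint distributions.  Passing tests therefore demonstrate
correctness and statistical behaviour of the methods under clean coalescent
conditions, not performance on noisy real alignments.

## Statistical experiment conditions

The calibration and power experiments in the acceptance suite run under the
following conditions, chosen once as the study conditions of each test:

- **Phi calibration/power**: n = 20, three 150-nt loci, theta = 10 per
  locus, JC mutation, 300 permutations, analytic p at alpha = 0.05.  The
  finite-site model is essential: under infinite sites a clonal sample has
  Phi = 0 and p = 1 identically, so there is no null distribution to
  calibrate.  The 150-nt loci put per-site theta at 0.067, high enough that
  recurrent mutation gives the null appreciable homoplasy; the analytic p is
  used because the discrete permutation p is conservative on sparse
  incompatibility matrices (its rejection rate at nominal 5% is roughly 2-3%).
- **PHT calibration/power**: n = 16, two 150-nt loci, theta = 30 per locus,
  JC, 200 replicates (see the ILD bluntness note above).
- **GCPSR recovery**: the structured scenario above, NJ with 60 bootstrap
  replicates, threshold 0.95.
- **Border scan**: the border scenario defaults, Phi with 200 permutations,
  alpha = 0.05; accuracy counts core strains as correct when not flagged and
  halo strains as correct when flagged (controls are excluded from scoring).

## Numerical choices and degenerate inputs

Permutation p-values always use `(1 + b)/(n + 1)` and never return 0.  NJ
ties resolve to the first row-major minimum of the Q matrix; negative branch
lengths are clamped to 0 with the deficit logged.  NNI uses the first
improving move in a deterministic edge ordering; the stepwise-addition order
comes from the search seed.  Fitch treats `-` as the full state set and
ambiguity codes as their IUPAC sets; polytomies are folded as sequential
cherries (exact for binary trees, a documented convention otherwise).  K3ST
distances raise a saturation error naming the pair when a log argument is
non-positive.  Phi raises a not-computable error with fewer than two
informative sites or no in-window pair; IA requires at least three
haplotypes after clone correction and two polymorphic loci.

## Known limitations

Bayesian tree inference, substitution-model selection, coalescent-MCMC
growth/theta estimation and split-network drawing are out of scope; gene
trees are inputs (or NJ surrogates), and supports are bootstrap proportions
rather than posterior probabilities — whether 0.95 bootstrap is as stringent
as 0.95 posterior probability is a user-level calibration question.  The
pairwise-deletion pi and the complete-deletion S can disagree on gappy
alignments.  Reproducing the original study's printed statistics requires
its GenBank sequences and alignment pipeline, which are outside the package.
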