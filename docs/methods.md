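# Methods

This note documents the models implemented in `phylophen`, their
assumptions, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that affect
results. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genome statistics

N50 is the length of the scaffold at which the descending cumulative sum
first reaches at least half the total (the `>=` convention); L50 is its
1-based rank. GC% is computed over unambiguous bases only — N and IUPAC
ambiguity codes are excluded from numerator and denominator, matching
assembly-report convention; a record with no A/C/G/T raises rather than
silently reporting 0.

Organelle detection is a size heuristic, not homology: the shortest
scaffold is reported when it is at most 100 kb (fungal mitogenomes are
tens of kb; nuclear chromosomes Mb-scale). Telomere scanning flags a
scaffold end when the repeat motif (default `TTAGGG`) or its reverse
complement occurs at least 3 times (overlapping, case-insensitive) in the
terminal 500 bp. Window and copy number are defaults of this package —
motif literature fixes the repeat but not scan parameters — and both are
arguments. Because published genome-size figures do not always state
whether the organelle is included, the stats report carries totals both
with and without it.

## MinHash sketches and Mash distance

Canonical k-mers (lexicographic min of k-mer and reverse complement,
windows with non-ACGT skipped) are hashed with a murmur3-family 64-bit
finalizer (`fmix64`) seeded by mixing the user seed with a splitmix
constant. A sketch keeps the s smallest distinct hashes (defaults k = 21,
s = 1000, seed = 42 — the defaults of the widely used sketching tool,
which the source study also ran with defaults). Bit-compatibility with
that tool's output files is not claimed.

Jaccard is estimated on the merged union bottom: with X the s smallest
distinct hashes of A ∪ B, Ĵ = |X ∩ A ∩ B| / |X| — the fixed-size
estimator that is unbiased for bottom sketches. The distance is
D = −(1/k)·ln(2Ĵ/(1+Ĵ)), the Poisson-approximation inversion of k-mer
survival under independent substitutions; at Ĵ = 0 the form diverges and D
is capped at 1.0. Assumptions: substitution-dominated divergence, roughly
uniform rates; indels and repeats bias D upward relative to per-base
divergence. The acceptance suite verifies Ĵ stays within the 3-sigma
binomial band of the exact k-mer Jaccard and that D recovers simulated
substitution divergence within ±0.01 for d ≤ 0.10.

## Coherence metrics

**ANI** follows the orthologous-fragment scheme: both genomes are cut into
non-overlapping 1,020 bp fragments (the granularity of the standard
OrthoANI-style implementations); fragments are matched by shared 15-mer
seeds and scored by edit-distance alignment (edlib), both orientations
tried; only reciprocal best-hit pairs with identity ≥ 0.3 contribute; ANI
is their mean percent identity. Self-ANI is exactly 100; the estimator is
symmetric because the RBH set is. When no pair passes the floor the result
is an explicit undefined-ANI error, never a silent 0. Known bias: with
identity defined against the full fragment length, ANI ≈ 100·(1−d) with a
small upward correction ~d²/3 from coincident mutations — well inside the
±0.5 pp recovery tolerance the acceptance suite checks at d ≤ 0.08.

**AAI** is the mean identity over reciprocal best-hit protein pairs under
local BLOSUM62 alignment (gap open −11, extend −1), keeping hits with
identity > 30% and an aligned region > 70% of the shorter protein — the
default filters of the common AAI tools. **POCP** counts a protein as
conserved when some hit has E-value < 1e-5 (Karlin–Altschul with gapped
BLOSUM62 parameters λ = 0.267, K = 0.041), identity > 40% and an alignable
region > 50% of the query, then POCP = 100·(C1+C2)/(T1+T2). Proteomes are
explicit inputs; a deliberately trivial six-frame longest-ORF extractor is
provided as a convenience and is not a gene predictor.

**Verdict.** ANI is the primary criterion: distinct below 95% (the
conventional species boundary), conspecific at ≥ 98% (distinct fungal
species have been reported up to ~98% ANI, so the band between is
"borderline"). A Mash D ≤ 0.05 flag is attached as "high genomic
coherence" context only — close neighbors from different species routinely
fall inside it, so it never classifies on its own. Both thresholds are
arguments.

## Hexamer profiles

Profiles are canonical 6-mer frequency vectors (2,080 dimensions; counts
normalized to sum 1 so genomes of different sizes are comparable).
Similarity indices: weighted Jaccard Σmin/Σmax, containment Σmin/Σx
(asymmetric), Euclidean distance, Pearson correlation, plus a binary
Jaccard on the supports. Published "shared hexamer" percentages are
sometimes presence/absence-based, so the panel's reported hexamer
similarity is configurable; the default is binary Jaccard × 100
("considering all unique hexamers"), while the dendrogram distance is
1 − weighted Jaccard, which uses the full frequency information.

## Clustering and trees

Ward clustering runs the Lance–Williams recurrence on squared distances
with deterministic tie-breaking (lexicographically smallest label pair,
clusters keyed by their smallest member); Ward is reducible, so merge
heights are non-decreasing. The dendrogram is returned as an ultrametric
tree in which the tip-to-tip path through a node equals its merge height.

NJ/BIONJ implement the standard Q-criterion with BIONJ's variance-weighted
reduction as the default (mirroring the distance-tree builder used for
genome screening); ties on Q break by smallest label pair. Negative branch
estimates are clamped to zero with the deficit moved to the sister branch,
preserving the joined path length — on additive matrices nothing is
clamped and the generating tree is recovered exactly (verified against an
independent path-length oracle and a library NJ implementation). Trees are
built directly on Mash D, so branch lengths stay on the D scale; no
internal distance transformation is applied.

Bootstrap supports resample each genome's sketch hashes with replacement,
rebuild the tree per replicate and report bipartition frequencies. These
quantify MinHash sampling noise, not site-level phylogenetic conflict, and
are labelled as such in the output.

## PTP and Bayesian PTP

A species partition is a set of "species root" nodes covering all tips;
edges at or above species roots form the speciation class, edges strictly
below form a single pooled coalescent class. Each class is exponential
with its own rate, estimated at its MLE (rate = class count / class length
sum), giving the profile log-likelihood n·(ln(n/S) − 1) per class. Pooling
the coalescent class (rather than one rate per species) keeps the
enumeration oracle exact and matches dominant usage.

The ML search enumerates all valid partitions when their number is at most
20,000 — which covers every tree in the test and acceptance suites, making
the reported optimum exact — and otherwise hill-climbs with split/merge
moves from both the one-species and all-singletons extremes. A
likelihood-ratio test against the one-class null (χ², 1 df) guards against
over-splitting; when the null is not rejected the one-species partition is
returned, flagged. The LRT is anticonservative in principle (the partition
is optimized), which is acceptable for its guard role.

bPTP samples partitions by Metropolis–Hastings: a move splits a species
into its daughter clades or merges sibling species; proposals are uniform
over available moves with the exact Hastings correction; the prior over
partitions is uniform and the likelihood is the same profile likelihood
(no rate hyperpriors — the sampler stays consistent with the ML
objective). Defaults: 10⁶ iterations, 10% burn-in, thinning 100, four
seeds run independently; the convergence report is the maximum per-group
support difference across seeds. Per-group support is the fraction of
post-burn-in samples containing exactly that tip group; the returned
assignment is the maximum-posterior sampled partition. Support is emitted
both per group and as a posterior over species counts, since published
"delimitation support" figures are sometimes one and sometimes the other.

On a rate-homogeneous tree the posterior is intentionally diffuse: within
any species-count class some split of an exponential sample fits two rates
better than one, and count multiplicity dominates a uniform prior. The
test suite asserts exactly this null behavior (no confidently supported
multi-tip group) rather than concentration on one species, which no
uniform-prior sampler would produce.

## GMYC (single threshold)

The tree is made ultrametric, if it is not already, by mean-path-length
smoothing: each internal node's age is the mean path length to its
descendant tips, clamped so children never exceed parents (idempotent on
ultrametric input). This is a deliberately simple ultrametricization — the
commonly cited delimitation scripts accept non-ultrametric trees without
documenting their internal handling, so the choice is made explicit here.

Given a threshold T, nodes older than T are Yule events (forward birth
rate λ·lineages) and each subtree crossing T is an independent coalescent
(backward rate μ·m(m−1)/2 while m lineages remain); λ and μ take their
MLEs. T is optimized over midpoints between consecutive observed node
ages, plus the two extremes (all-Yule, all-coalescent). The null model is
the better-fitting single-process extreme; the LRT uses χ² with 2 df.
When the LRT is not significant the result is one entity per tip, flagged
"no significant clustering" (the GMYC null convention). Per-cluster
support is the likelihood weight of the cluster summed over all candidate
thresholds — an AIC-weight analogue (the parameter count is constant
across thresholds, so likelihood weights and AIC weights coincide).

## Population genetics

Under the default complete-columns policy, any column containing a gap or
IUPAC ambiguity is excluded from the analyzed length L (the convention of
the common haplotype-network tools); pairwise deletion is available for π.
S counts analyzed columns with ≥ 2 states; parsimony-informative columns
have ≥ 2 states each in ≥ 2 sequences. π is reported per analyzed site;
Tajima's D uses the mean pairwise difference count π̂ with the 1989
constants (a1, a2, b1, b2, c1, c2, e1, e2) and is explicitly undefined
(None, not 0) when S = 0 or n < 4. Haplotypes are distinct row strings
over analyzed columns; Hd = n/(n−1)·(1 − Σp²) with the small-sample
correction, clipped to [0, 1] against floating-point overshoot. The
acceptance suite pins a hand-evaluated n = 4 example (S = 3, π̂ = 1.5,
D ≈ −0.754) and checks the neutral-simulation mean of D stays within
±0.15 of zero at n = 20, θ = 5.

## Mantel test

Geographic origin is encoded as a binary categorical distance (0 same
country, 1 different) — "categorical" admits several encodings and this is
the simplest defensible one. The statistic is the rank correlation
(Spearman or Kendall tau-b) of upper-triangle entries; the null comes from
simultaneous row/column permutations of the geographic matrix with
p = (count + 1)/(N + 1), one-sided greater by default (the working
hypothesis is positive correlation of separation and divergence). With n
small enough that all permutations fit in the budget, the test switches to
exact enumeration automatically. A coherence-subset helper keeps only
genomes within D ≤ 0.1 of a focal genome before testing, reducing noise
from distant relatives. The permutation count default is 9,999 and the
seed is mandatory in the CLI, because stochastic p-values must be
reproducible.

## Variant screen and phenotype statistics

Variant classes follow the VCF REF/ALT convention: SNV (single differing
base), insertion (ALT longer, REF a case-insensitive prefix), deletion
(symmetric), complex (anything else). The insertion screen keeps
insertions whose ALT string reaches the assembly/variant-calling k-mer
size, k = 31 by default. "Larger than k" is ambiguous between the full
printed ALT (REF anchor base included) and the net inserted length; the
ALT-length reading reproduces published screens of this kind (an ALT of
31 letters has net length 30 and passes only under ALT-length) and is the
default, with `net_length` available. The bundled table of 14 published
insertion rows (BMH-0061 vs its closest *T. harzianum* reference genome)
ships as package data so the screen runs offline.

Growth rate is the OLS slope of colony diameter against time (cm/h), equal
to the difference quotient for two points. PIRG = (R1 − R2)/R1 × 100;
negative values (pathogen grew more with the antagonist) are legal and
flagged, never clipped. Group comparisons use one-way ANOVA plus Tukey HSD
at α = 0.05.

## Synthetic data: what it emulates, what it does not

`evolve_pair` draws a random ancestor at a set GC (defaults 200 kb, GC
0.485 — a fungal-like composition), then gives each descendant Poisson
substitutions at rate d/2 and indels at rate/2 with geometric lengths.
The truth record carries the realized identity measured at the
substitution stage, where coordinates still correspond. This matches the
assumptions of Mash and fragment-ANI (substitution-dominated divergence)
and is exactly the regime the recovery tolerances refer to.

`simulate_species_markers` builds a sequential (caterpillar) species
history with exponential split increments of mean `between_depth`
(substitutions/site), simulates within-species genealogies under the
standard neutral coalescent (msprime, haploid samples; θ = 2Nμ per site
with θ spread over the concatenated marker length), and evolves finite
sites under Jukes–Cantor. The recovery studies use 3 species × 4 tips,
between_depth 0.5 and θ = 1.0 per 3 kb locus — a separation of roughly
1500× between split depth and within-species diversity, i.e. the
"well-separated" regime where delimitation methods are expected to work.
Even there, deep within-species coalescences occasionally make PTP
oversplit; that is a property of the model class, not a bug, and the
recovery criterion is a rate (≥ 90%), not perfection.

What the generators do not emulate: sequencing error, assembly artifacts,
repeats and mobile elements, recombination within loci, gene flow between
species, selection, and rate variation across sites or lineages. Passing
tests therefore demonstrate correctness of the implementations under
their stated models, not robustness of the methods to real-data
violations of those models.

## Numerical choices and degenerate inputs

- All RNG is `numpy.random.default_rng` from explicit seeds; msprime seeds
  are drawn from the same stream and kept below 2³¹.
- Exponential-class log-likelihoods return −∞ for a non-empty class with
  zero total length; an entirely zero-length tree is a degenerate-model
  error.
- Ward/NJ tie-breaks are lexicographic on labels so outputs are
  byte-reproducible across runs and platforms.
- Distance matrices are validated (symmetry within 1e-12, exact zero
  diagonal, non-negativity) at construction, not at use.
- Mash D is capped at 1.0 when the estimated Jaccard is 0; the cap is the
  reported value, not an exception.
- Undefined statistics (GC of an all-N record, ANI with no qualifying
  fragment pairs, Tajima's D at S = 0) are explicit errors or None, never
  silent zeros.

## Problem sizes

The test and acceptance workloads use 20 kb genomes for exact-Jaccard
cross-checks, 200 kb for ANI recovery, 1–3 kb loci with n ≤ 20 samples
for popgen calibration (200 replicates), 12-tip trees for delimitation
recovery (20 trees, 10⁵ MCMC iterations per chain), and 500 datasets of
n = 10 for Mantel null calibration. These sizes were chosen so each
property is measured with useful precision while the whole suite stays
comfortably interactive on a single CPU.

## Known limitations

- ANI fragment matching is seed-based; genomes below ~35% identity or
  dominated by indels return undefined ANI rather than a low value.
- POCP E-values use analytic Karlin–Altschul parameters, not empirical
  fitting; absolute E-values differ slightly from BLAST's but the < 1e-5
  gate is insensitive to this at the identity levels POCP cares about.
- GMYC here is single-threshold only; bPTP uses profile likelihood rather
  than sampling rates, so its supports are conditional on the MLE rates.
- The six-frame ORF extractor is a stand-in for real gene prediction and
  under-samples proteomes; AAI/POCP on its output are rough.
- `select_neighbors` and the pipeline hold all sketches in memory; the
  design targets hundreds of genomes, not databases of millions.
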