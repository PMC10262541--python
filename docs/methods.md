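# Methods

## The analysis in one paragraph

Samples are ASV count vectors from four body sites (oral, nasal, vaginal,
milk) of the same animals at up to four occasions, plus negative extraction
controls.  The pipeline (i) removes rare ASVs and kit contaminants and
discards under-sequenced samples, (ii) rarefies and computes alpha/beta
diversity with permutation statistics on the rarefied table, and (iii)
computes the herd core microbiota and within-animal cross-site sharing on
the filtered, **un**rarefied table — presence/absence questions should not
depend on a random subsample, whereas diversity comparisons require a
common depth.

## Filtering and decontamination

An ASV is removed when **either** abundance clause or **either** prevalence
clause fires (strict inequalities throughout):

* pooled relative abundance `< 1e-5` in every (site × time) stratum, or
  `< 5e-5` over all samples pooled;
* prevalence `< 5%` within every site, or presence in fewer than 3 samples.

"Pooled" relative abundance of ASV *a* in stratum *s* is
`reads(a, s) / reads(s)` — stratum-summed reads, not the mean of per-sample
fractions.  This is the simpler reading of computing "the relative
abundance in each site" after splitting samples by site; a
`mean_per_sample` switch provides the other reading for sensitivity
analysis.  Control samples are excluded from these denominators; they enter
only the kitome rule.

**Kitome rule.** With controls as an extra stratum, an ASV is flagged iff
its prevalence among control samples is strictly above 50% **and** its
pooled relative abundance in controls exceeds that over all body-site
samples combined ("combined" = one pooled stratum).  Flagged ASVs are
removed everywhere; afterwards samples with fewer than 1000 reads are
discarded.  The chain runs exactly once, in this order; only the min-reads
step is idempotent (abundance filters could cascade if re-applied, which is
deliberately not done).

Every removal is logged as (entity, rule, measured values); replaying the
log against the input table reproduces the filtered table bit-exactly, and
the test suite asserts each rule against an independent brute-force
re-evaluation of the printed clauses.

**Rarefaction** subsamples each retained sample to a common depth without
replacement (multivariate hypergeometric draw), deterministic given a seed.
The default depth is the minimum retained sample total.

## Diversity

* Shannon uses the natural log.  Jaccard is binary presence/absence
  (`1 − |A∩B|/|A∪B|`); the quantitative variant `2B/(1+B)` of Bray–Curtis
  *B* is available but not the default.  Bray–Curtis is `Σ|x−y| / Σ(x+y)`
  on rarefied counts, which at equal depths equals the relative-abundance
  form.
* UniFrac propagates per-sample presence (unweighted) or relative-abundance
  mass (weighted) from the tips to the root once; branch contributions are
  then combined per sample pair.  Weighted UniFrac is normalized by
  `Σ_b L_b (p_A + p_B)` by default (the common "wUniFrac"); the raw form is
  a flag away.  On a star tree with unit branches, unweighted UniFrac
  reduces to Jaccard and weighted UniFrac to Bray–Curtis — both identities
  are asserted in the tests, alongside exhaustive branch-enumeration
  oracles at `1e-12`.
* PCoA is classical scaling: eigendecomposition of `−½ C D² C`.  Negative
  eigenvalues are reported but their axes excluded; no Cailliez/Lingoes
  correction is applied so the ordination stays faithful to the raw
  dissimilarity.  Signs follow a deterministic convention (the largest
  loading of each axis is positive).  A pair of samples covering no branch
  length (or with empty union) gets distance 0 with a warning rather than
  NaN.

## Permutation statistics

**PERMANOVA.**  Gower-center the squared distances, `G = −½ C D² C`; for
ordered terms build nested design matrices (factors dummy-coded against an
intercept, covariates centered) with orthonormal bases `Q_k`; sequential
`SS_k = tr(Q_k Q_kᵀ G) − tr(Q_{k−1} Q_{k−1}ᵀ G)`; pseudo-F against the
residual mean square; p-values by jointly permuting rows/columns of `D`,
with `p = (1 + #{F* ≥ F}) / (1 + n_perm)`.  Permuted F values are compared
with a `1e-9` relative slack so permutations that reproduce the observed
partition count as ties despite floating-point noise.  A marginal-SS mode
(each term adjusted for all others) exists because with several covariates
in one model the term order is a modelling choice; rank-deficient terms get
0 df and no test.  Permutations are free (no strata): the animal term is an
ordinary factor.  The default `n_perm` for standalone analyses is 9999;
the pipeline default is 999 to keep full runs fast.  For n ≤ 8 samples an
exhaustive mode enumerates every ordering, giving exact p-values.  On
Euclidean distances a single-factor PERMANOVA reproduces the classical
between-group SS and F to `1e-9` (asserted), and null p-values are
uniform (KS-checked over 500 simulations).

**Dispersion.**  Samples are embedded by PCoA keeping positive and
negative eigen-axes separately; distance to the group centroid is
`sqrt(max(0, ||x−c||²_pos − ||x−c||²_neg))`.  The observed one-way F on
these distances is tested by permuting group labels over the fixed
distances, followed by Tukey HSD pairwise comparisons.  Centroids (not
spatial medians) are used.  Size-1 groups are excluded with a warning.
Type-I error is calibration-tested over 400 null simulations.

**ANOVA + Tukey.**  Classical one-way ANOVA; Tukey HSD adjusted p-values
from the studentized-range distribution with the Tukey–Kramer standard
error for unequal group sizes (for two groups this reduces exactly to the
pooled t-test via `q = √2·|t|`, asserted).  All-zero within-group variance
is flagged and reported as p = 0.

**Ward clustering** follows the ward.D2 convention: Lance–Williams
recurrence on squared dissimilarities, heights in original units, cut to
exactly k clusters.  Ties are broken by the lexicographically smallest pair
of cluster representative IDs (a cluster is represented by its smallest
member), so labels are platform-independent.  The merge sequence is tested
against a brute-force minimiser of the within-cluster sum-of-squares
increase, and against scipy on Euclidean fixtures.

**ARI** is the Hubert–Arabie chance-corrected index; degenerate identical
partitions score 1.  **Cluster stability**: per site, animals are clustered
(Ward, k = 5 by default, on Bray–Curtis of per-animal profiles) at each
time point independently; consecutive time points are compared by ARI
restricted to the animals present at both, skipping pairs with fewer than
k common animals.

## Core microbiota and sharing

The unit is the *animal-site community*: presence = count > 0 in the
filtered, unrarefied table, with milk quarters summed per animal/time
before anything is computed (union semantics — sharing is an animal-level
question).  An ASV is core for (site, time) iff its relative abundance
exceeds `1e-4` in at least 50% of the animals having a community there;
the prevalence comparison is `≥` by default (a strict `>` option exists,
as both conventions circulate).  The abundance clause is evaluated on each
animal's own community, consistent with counting animals.

Sharing denominators are each animal's own community sizes
(`|A∩B|/|A|` and `|A∩B|/|B|`), not herd-level ASV counts.  A multi-way
"occurrence" is an (ASV, animal, time, site-combination) tuple with the ASV
present in every site of the combination; an ASV in all four sites of one
animal therefore contributes C(4,3) = 4 three-way occurrences and 1
four-way occurrence.  Tallies are tested against an exhaustive
tuple-enumeration oracle.

## The synthetic herd generator

The generator emulates the survey design the analysis assumes, with one
seeded PRNG stream in a documented order so identical (config, seed) pairs
are bit-identical:

1. A pool of P = 400 template ASVs; each site draws S = 120 of them with
   log-normal(0, 1.25) template abundances.  The `⌈f_core·S⌉` most
   abundant template ASVs per site are the planted core (cores in real
   herds are drawn from the abundant tail, which is also what makes them
   detectable); `f_core = 0.1`.
2. Each animal-site community keeps all core ASVs, each non-core template
   ASV with probability π = 0.25, and adds 10 animal-private ASVs; all
   abundances get an animal-specific log-normal(0, 0.5) jitter.
3. Within each animal, every ASV of each source community transfers to
   each other site with probability `f_share` (default 0.1) at 0.25× its
   abundance — the planted within-animal sharing signal.  Transfers apply
   to the first-occasion communities and then persist or churn through
   turnover.
4. Between consecutive occasions a fraction τ = 0.1 of each community is
   replaced, lowest-abundance first (detection-limit churn, deterministic
   given abundances), by fresh private ASVs; abundances are re-jittered.
5. K = 25 kit-contaminant ASVs with a log-normal profile: negative
   controls contain *only* contaminants; body-site samples receive a
   contaminant mass fraction `kit_load · min(biomass)/biomass(site)`.
   With `kit_load = 0.15` and biomass 1/1/0.3/0.1 for oral/nasal/vaginal/
   milk, carry-over is ≈1.5%, 1.5%, 5%, 15% — milk worst, reproducing the
   qualitative gradient the decontamination rule is meant to handle.
6. Sequencing depth per sample is log-normal(9.2, 0.8) (median ≈ 10k
   reads), floored at 200 so the <1000-read sample filter is exercised;
   counts are multinomial, with an optional Dirichlet overdispersion
   parameter for power studies.
7. A random bifurcating tree over all ASVs (uniform pair joining,
   exponential(0.1) branch lengths).

Defaults are the emulated study conditions: 45 animals in three groups
(18/15/12), four sites, four occasions, 8 controls.  Milk can be split
into quarters (`milk_quarters`), off by default; animal-level aggregation
is tested either way.  The ground truth records the planted kitome, cores,
transfer events and the realized pre-noise communities, which serve as the
sharing oracle.

What the generator does **not** emulate: real taxonomic structure,
phylogenetic signal in community assembly (the tree is independent of the
templates), temporal autocorrelation beyond single-step turnover,
sequence-level artefacts (chimeras, index hopping), or compositional
correlations between ASVs.  Passing tests therefore demonstrate that the
statistics recover *planted* structure of the kinds listed — not that any
particular biological result generalises.

## Problem sizes and numerical choices

The test suite runs herds of 5–20 animals with pools of 100–300 ASVs, and
calibration studies of 400–500 simulations with 199 permutations each —
sizes chosen so the whole suite completes in about a minute while keeping
Monte-Carlo standard errors small enough for 3-SE assertions.  The
acceptance script runs the full 45-animal default once (~1 minute).
Tolerances: exhaustive oracles at `1e-12`; closed-form equivalences at
`1e-9`; simulation-based checks at 3 Monte-Carlo standard errors.
Distance matrices are symmetrised and diagonal-zeroed after validation to
absorb float round-off; permutation p-values use the add-one estimator so
they never reach 0.

## Known limitations

* PERMANOVA offers no restricted/blocked permutation schemes; repeated
  measures on the same animal are handled only by including the animal as
  a fixed factor.
* The dispersion test permutes the computed distances rather than
  recomputing centroids per permutation; both conventions circulate and
  the implemented one is calibration-tested here.
* Mixed-effects alpha-diversity models and differential abundance are out
  of scope.
* The hand-rolled Ward implementation is O(n³) and intended for herd-scale
  inputs (hundreds of samples), not thousands.
* BIOM support covers the JSON (1.0) flavour only, not HDF5.
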