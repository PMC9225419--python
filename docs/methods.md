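# Methods

`microsev` analyzes gut-microbiome count tables against an *ordered* clinical
spectrum — healthy controls (HC) < asymptomatic / undifferentiated autoimmune
syndrome (Asym/UAS) < Sjögren's syndrome / systemic lupus erythematosus
(SS/SLE) — and asks three questions: do relative abundances shift monotonically
with severity, does host HLA genotype modify those shifts, and are they
reflected in anti-Ro autoantibody titers.  This note documents the models, the
numerical choices, and what the synthetic cohorts do and do not establish.

## Compositional representation

16S counts are relative: a sample's counts are a multinomial draw from a
composition, so Euclidean statistics on raw proportions are biased.  All
testing therefore happens in log-ratio coordinates:

* **clr** (univariate): `clr_i(x) = ln(x_i / g(x))` with `g` the geometric
  mean of the sample's closed proportions.  Rows sum to zero by construction.
* **tree-based ilr** (multivariate): one balance per internal node of a
  bifurcating tree over the taxa.  With uniform weights the balance at a node
  splitting leaves into sets L and R is
  `sqrt(|L||R| / (|L|+|R|)) * ln(g(x_L)/g(x_R))`,
  and the balance basis is orthonormal: Euclidean distance between balance
  rows equals the Aitchison distance between the compositions (verified to
  1e-8 in the test suite).  A `mean_descendants` variant weights each taxon by
  its mean relative abundance across samples, using weighted geometric means
  and weighted node normalizers; it down-weights rare taxa but is no longer an
  isometry.  The uniform variant is the tested contract.

**Pseudocount.** Zeros are replaced by adding 0.5 to every count before
closure (the conventional half-count; exposed everywhere as `pseudocount`).
The choice matters most for rare taxa, which is one reason for the abundance
filter below.

**Pre-test filters.** Taxa whose counts sum to zero over the cohort are
removed, then taxa with mean relative abundance < 1e-4.  Besides matching
standard practice, the second filter has a statistical role here: an
essentially-all-zero taxon has a clr trajectory driven entirely by the
per-sample centering term, so any strong community trend is mirrored into it
with almost no noise and the rank test will flag it.  Filtering keeps such
taxa out of the multiple-testing family.

**Tree.** When no phylogeny is supplied, a tree is derived from the taxonomy:
lineages nest the leaves, and multifurcations are resolved into random
cherries with a seeded RNG (unit branch lengths).  A user Newick tree
overrides; it must be strictly bifurcating and cover the analyzed taxa.

## Diversity

Shannon entropy `H = -sum p_i ln p_i` is computed in nats on unfiltered
proportions (zeros contribute nothing), with the effective taxon number
`e^H`.  Group comparisons: Welch t-test for two groups (a batch-adjusted
linear-model variant is available, since whether the original comparisons
adjusted for batch is not documented — both are provided), and for the
three-group trend a linear model of H on the ordinal score (HC = −1,
Asym/UAS = 0, SS/SLE = +1) plus sequencing-batch dummies, p from the score
coefficient's t-test.

## Per-taxon rank GLMs

clr values are rank-transformed within each taxon (midranks for ties) because
conditional normality of clr values is unreliable; the rank response makes
the t/F reference distributions accurate at these sample sizes.  Designs, all
including batch dummies:

* `ordinal3`: rank ~ score; 1-df trend test (two-sided — effects in both
  directions are reported).
* `discrete3`: rank ~ two group indicators; 2-df F-test, order-agnostic.
* `two_group`: rank ~ indicator for any (possibly pooled) split, e.g. HC vs
  all anti-Ro positive mothers combined.

Taxa whose ranks are constant get p = 1 (not NA) so FDR family sizes stay
fixed.  The implementation solves all taxa at once against the shared design
matrix (pseudoinverse + per-column residual variance); it is checked
coefficient-for-coefficient against statsmodels OLS in the tests.  Null
calibration (type-I error within [0.035, 0.065] at nominal 0.05, KS-uniform
p-values) is exercised over 2000 simulations.

## Multiple testing and the taxonomic stepdown (TSD)

Within a comparison family, Benjamini–Hochberg step-up adjustment (via
statsmodels, verified against an independent brute-force implementation).

TSD exploits the taxonomic hierarchy to shrink the hypothesis space: all
phyla are tested with BH across phyla; for each phylum with adjusted p <
alpha (default 0.05) its gate opens and only its classes are tested, BH
within that sibling set; recursion continues to species or until no gate is
open.  Counts at each level are re-aggregated from the full table (not
residualized on the parent).  Internally nodes are keyed by the full lineage
path `kingdom;...;level` so identical rank names under different parents can
never merge; the public per-level aggregation keys by the rank name alone.
A structural invariant — no emitted node under a closed gate — is asserted on
every run.  Under a global null the probability of any species-level
discovery is bounded by alpha (checked over 500 simulated cohorts).

Note a genuinely compositional subtlety the tests surface: because clr ranks
are scale-free, a strong monotone shift in one lineage induces an equally
*rankable* opposite shift in the rest of the community, so "unperturbed"
phyla are not silent controls.  Gating behaves correctly; interpretation of
which lineage drives a community shift needs the effect sizes, not only p.

## Interaction models

Candidates are the FDR-significant genera from the differential step.
Abundance enters as the genus-level clr value, so coefficients are per clr
unit.

* **HLA x genus.**  Four SLE-risk class II alleles (DRB1\*03:01, DRB1\*15:01,
  DQB1\*02:01, DQB1\*06:02), carrier-coded (dominant).  Default model:
  logistic regression of SS/SLE vs Asym/UAS among anti-Ro positive mothers on
  clr + carrier + clr x carrier; the reported odds ratio is
  `exp(interaction coefficient)` with a Wald 95% CI.  A proportional-odds
  variant over all three groups is provided (the regression family behind the
  original odds ratios is not documented; binary coding is the default
  because a single OR per interaction is most naturally a binary or
  proportional-odds quantity).  Requires carrier status for >= 80% of
  samples and both carrier strata non-empty; complete separation is returned
  as a non-estimable result rather than raised.
* **Titer x disease.**  Linear model of a titer (anti-Ro52/Ro60, IgA/IgG; raw
  units by default, log1p optional) on clr + disease group + clr x group
  among anti-Ro mothers; per-group fitted lines are returned for interaction
  plots.
* **Screen.**  All allele x taxon and titer x taxon models; flagged at a
  descriptive reporting threshold with *no* multiplicity adjustment by
  default (an optional BH column can be added), mirroring the exploratory
  character of this step.

## PERMANOVA and PCA

One-way PERMANOVA (Anderson's pseudo-F from the among/within decomposition of
squared distances) on the Aitchison distance of the balance matrix.  p-values
use label permutations with the add-one rule `p = (1 + #{F* >= F}) /
(1 + n_perm)`; default `n_perm = 19999` so the smallest attainable p is
5e-5.  An exhaustive mode enumerates all label orderings for small n and is
verified against full enumeration.  Permutations are unrestricted (the
original permutation scheme is undocumented; defaults are stated rather than
guessed).  PCA is a column-centered SVD of the balances with explained-
variance fractions; single-PC associations with covariates use an OLS slope
test (numeric) or Welch t-test (binary), with a Bonferroni report for the
number of PCs examined.

## Synthetic cohorts

The generator produces cohorts with the structure the analysis assumes, so
every stage is testable without access to the original sequencing deposit.

Model: per-taxon latent log-abundances `eta ~ Normal(base_logmean,
base_logsd)` plus per-sample noise, batch offsets, and planted group effects;
proportions by softmax; counts `Multinomial(depth_i, p_i)` with `depth_i ~
Poisson(seq_depth_mean)`.  This logistic-normal/multinomial choice maps
planted log-scale effects directly onto clr expectations.  Defaults (chosen
once, as study-like conditions): groups (23, 43, 82); a 6-level taxonomy with
8 phyla / 14 classes / 24 orders / 40 families / 150 genera / 200 species
(each rank's units nested randomly in the rank above, every parent with at
least one child); `base_logmean = 0`, `base_logsd = 2` (strongly uneven
communities, a few dominant genera); depth 32 000; 3 batches with batch
effect SD 0.25; per-sample log-noise SD 1.

Planted structure:

* *Ordinal effects* — genus-level shifts of `sign * delta * score` on the log
  scale (default 13 genera at delta = 1, alternating sign).
* *Non-monotone effects* — per-group offset triples.
* *HLA interactions* — planted on the outcome side: disease state of anti-Ro
  mothers is re-drawn from a logistic model whose linear predictor contains
  the centered genus clr x carrier product at the planted log-OR, with
  intercept `ln(82/43)` so expected group sizes match; centering the clr only
  shifts a carrier main effect the fitted model already includes.  The
  re-draw happens *before* severity effects are planted, so ordinal structure
  refers to final group labels.
* *Titer interactions* — titers for anti-Ro mothers drawn from a linear model
  with per-group slopes in the genus clr; healthy controls get missing HLA
  and titers, as in a cohort genotyped/serotyped only for the anti-Ro women.

Reproducibility: one `SeedSequence` per `generate` call, spawned into
per-stage streams, so identical spec + seed is bit-identical and adding one
planted effect does not perturb unrelated draws.

What the generator does **not** emulate: taxon-taxon correlation beyond
closure (no ecological interaction structure), overdispersion beyond the
logistic-normal (no Dirichlet-multinomial extra variance), read-level
artifacts (chimeras, PCR bias), age/medication covariates, and HLA linkage
disequilibrium between the four alleles (carriers are drawn independently).
Passing recovery tests therefore demonstrate correctness of the estimators
under the assumed model, not robustness to real-data violations of it.

## Simulation sizes used by the checks

Chosen to characterize each property with adequate Monte-Carlo precision:
rank-GLM calibration, 2000 null cohorts x 50 taxa; TSD global-null error,
500 study-scale cohorts; severity-effect recovery, 100 study-scale cohorts;
HLA interaction bias/coverage, 1000 cohorts of 125 anti-Ro mothers over 20
even-abundance single-species genera with carrier frequency 0.5 (balanced
strata isolate estimator behavior from stratum-size noise); titer
interaction power, 300 such cohorts.  The acceptance script uses the same
designs at 40/300/200 replicates and reports the Monte-Carlo `n` beside each
value.

## Known limitations

* The `mean_descendants` ilr weighting follows the formula documented above;
  the exact normalization used by other implementations of weighted balances
  is defined only by those implementations, so only the uniform variant
  carries an isometry guarantee.
* Proportional-odds HLA models need carrier data for healthy controls to use
  all three outcome levels; with HC genotypes missing the model reduces to
  the binary comparison.
* TSD power depends on signal surviving aggregation: a severity effect in a
  genus that is a small fraction of its phylum can be invisible at the
  phylum gate, in which case flat genus-level BH testing is more sensitive.
* PERMANOVA assumes exchangeability under the null; batch-restricted
  permutation is available but unrestricted permutation is the default.
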