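# Methods

`ryrmod` implements the computational chain of a multi-species drug-modifier
screen for ryanodine-receptor (RyR1) myopathy models: hit calling in a
*C. elegans* developmental-arrest suppressor screen, structural-similarity
enrichment of the resulting hits, chemical-genetic interaction scoring of
zebrafish larval movement speed, and calcium-transient / qPCR readouts from
myotube experiments.  Every stage has a seeded synthetic-data generator that
emulates the statistical structure the stage assumes, so the whole pipeline
is testable without external data.

## Worm screen: hit calling and rank statistics

Wells of approximately 20 synchronized L1 *unc-68* (RyR-null) worms are
exposed to nemadipine-A, a dihydropyridine-class L-type calcium channel
inhibitor that arrests these mutants at the L1–L3 stages, plus one candidate
chemical per condition in duplicate wells.  After six days the developed
(L4 + adult) worms per well are counted.

- **Primary hit**: ≥ 1 developed worm in *every* replicate well
  (`call_hits`, parameters `min_escaped` and `require_all_replicates`).
- **Random escapees**: wells develop ≥ 1 worm by chance at a well-level rate
  of roughly 5–8%; `escapee_rate` reports the fraction of wells with ≥ 1
  developed worm, rounded to one decimal as a percentage.
- **Imputation**: only developed worms were counted, so arrested larvae are
  recovered post hoc as `imputed_L1L3 = max(0, assumed_n − L4 − adult)` with
  `assumed_n = 20` by default.  Because the true plated count varied
  (~15–25), wells whose developed count exceeds `assumed_n` are clamped at
  zero and flagged rather than rejected.
- **Rank test**: each worm is scored 1 (L1–L3), 2 (L4) or 3 (adult) and
  condition stage distributions are compared to a reference group with a
  tie-corrected Kruskal–Wallis test followed by Dunn's post-test versus the
  reference.  Which wells constitute the "random escapee" baseline is not
  derivable from the data model, so the reference group is an explicit
  required argument.  Dunn p-values are Bonferroni-adjusted over the
  vs-reference family by default (the convention of the commonly used
  implementation of "Dunn's multiple comparisons post-test"); Holm, Šidák
  and BH are available.  All-tied data return H = 0, p = 1: the tie
  correction's denominator vanishes and the biological reading is "no
  difference".  For pooled N ≤ ~12 an exact permutation omnibus p is
  available (`method="exact"`, full enumeration of group assignments).

The escapee process in the generator is per-worm independent Bernoulli; the
per-worm probability reproducing a target well-level rate r for n-worm wells
is p = 1 − (1 − r)^(1/n) (`per_worm_escape_prob_for_well_rate`).  Escaped
worms are split 50/50 between L4 and adult — the split is not identifiable
from well-level data and hit calling only uses the sum.

## Structural enrichment

Compounds are binary fingerprints; similarity is the Tanimoto coefficient
|a∧b|/|a∨b| (0 for two empty fingerprints, by convention).  The hit × library
Tanimoto matrix is clustered agglomeratively using Euclidean distance
between score vectors with complete linkage (scipy), which guarantees
monotone merge heights and a deterministic dendrogram for a fixed input
ordering.  A cluster is *structural* when strictly more than half of its
within-cluster compound pairs exceed a Tanimoto threshold (0.55 by default);
singletons are maximally cohesive by convention.  The default dendrogram cut
("auto") is the smallest number of clusters such that every non-singleton
cluster is structural; fixed-height and fixed-count cuts are alternatives.

Enrichment of a compound group (structural cluster or annotation class) is a
two-sided Fisher exact test on the 2×2 table (hits in group, non-hit group
members, other hits, everything else), using the sum-of-point-probabilities-
≤-observed convention, which reproduces the printed drug-library p-values
exactly at four decimals (e.g. 2 of 9 DHPR inhibitors among 18 hits in 1280
compounds → p = 0.0063).  The sample odds ratio uses the standard
infinity-on-zero-denominator convention.  The test suite checks the p-value
against an exhaustive-enumeration hypergeometric oracle in exact rational
arithmetic, both at small N and at the 1280-compound scale.

The synthetic library plants clusters as shared bit cores (48 core bits per
cluster, each present with probability `within_cluster_bit_overlap`) over a
sparse background (2% bit density on 256 bits).  These densities mirror real
sparse structural fingerprints and put within-cluster Tanimoto well above
the 0.55 threshold at the default overlap of 0.9 while leaving between-
cluster similarity near zero.  Fingerprints are synthetic, not
chemistry-derived: the Tanimoto and clustering mathematics are identical,
and removing structure parsing keeps the test path dependency-free.

## Chemical-genetic interaction on movement speed

Larval speeds are normalized per assay to the mean of vehicle-treated
wild-type siblings, putting the four group means on a scale where
W (WT/vehicle) ≡ 1.  With G the mutant/vehicle and C the WT/chemical mean,
the expected double-perturbation phenotype is G + C − 1 (additive) or G·C
(multiplicative); the unnormalized equivalents are Wg + Wc − W and
Wg·Wc / W.  The interaction score ε is the observed mutant/chemical mean
minus the expectation.  Both ε values are always reported; classification
(positive/negative/none) keys on the multiplicative ε by default — the
standard choice for fitness-like traits — gated by the genotype × treatment
interaction term of a two-way fixed-effects ANOVA at α = 0.05 (type-II sums
of squares, so unbalanced designs are handled; Tukey HSD gives all pairwise
group contrasts).  When interaction and residual sums of squares both vanish
(noise-free data) the F ratio is 0/0 and p is reported as 1.  Additive
expectations below zero are reported as-is with a floor flag, since speed
cannot be negative.

Note the ANOVA interaction null is additivity on the normalized scale, so
type-I behaviour of the classifier is defined with respect to additively
generated data; under a multiplicative no-ε model with non-unit main
effects, the interaction term is non-null by construction.

`power_two_groups` computes two-sided two-sample t-test power from the
noncentral t distribution (pooled variance by default, Welch optional), the
computation behind "n = 9 larvae per group suffices" style assay planning.
The degenerate zero-variance equal-means case returns α with a warning.

The speed generator plants group means 1, g, c and g + c − 1 / g·c /
g·c + ε (additive / multiplicative / custom) before Gaussian noise on the
raw scale, truncated at zero since speeds are nonnegative; no noise model is
implied by the data beyond this.

## Calcium transients, paired resting Ca²⁺, ΔΔCt

A Fura-2 ratiometric trace is reduced to a peak response: baseline = mean
340/380 ratio over the 10 s immediately before caffeine addition; peak
change Δ = maximum ratio within 30 s after addition minus baseline;
normalized Δ divides by the cell's own baseline.  No smoothing is applied by
default — the definition is peak minus baseline — and traces that do not
cover both windows are rejected rather than silently shortened.  Because the
peak is a maximum over ~300 samples, its estimate under noise is positively
biased by roughly 2–3 noise SDs; this bias is shared across groups of equal
noise, so group comparisons (the analysis surface) are unaffected, but
absolute amplitudes at amplitude ≈ 0 should be read with the bias in mind.
Group comparisons across genotype × treatment reuse the interaction module's
ANOVA machinery.

Paired resting-Ca²⁺ measurements (same cells at 25 °C then 37 °C) are
compared with a paired t test by default (Wilcoxon optional); between-group
comparisons use a two-sample test on the per-cell deltas.  Units are
whatever the instrument produced (nM or ratio); no ratio→concentration
calibration is implemented.

ΔΔCt: per sample, ΔCt = mean Ct(target) − mean Ct(reference, *Tbp* by
default); ΔΔCt subtracts the control-condition (negative-control siRNA) mean
ΔCt; fold = 2^(−ΔΔCt).  The computation is efficiency-free — adding a
constant to every Ct changes nothing — and no Pfaffl-style efficiency
correction is implemented.

The transient generator produces baseline + A·f(t) + noise with f a
double-exponential (rise τ 1 s, decay τ 8 s, typical of caffeine-evoked
myotube transients) scaled to unit continuous-time peak, so the sampled peak
equals A up to discretization; the closed-form peak location
τ_r·τ_d/(τ_d−τ_r)·ln(τ_d/τ_r) anchors exact zero-noise tests.

## Orchestration and reproducibility

All interchange formats are plain TSV (all source data are small tabular
measurements).  The pipeline runner expands one config seed into per-stage
seeds via `numpy.random.SeedSequence`, and every generator takes one
explicit integer seed with no global state, so identical config + seed gives
byte-identical outputs; the manifest records parameters, per-stage row
counts and output checksums.  The `ryrmod` CLI exposes each stage
(`simulate`, `worm`, `chem`, `interact`, `calcium`, `qpcr`, `run`); nested
generator parameters (rescue-effect maps, per-cluster hit rates) are set via
config file rather than flags.

## Validation scales and what passing shows

Simulation-based checks run at: 200 seeds for rescuer sensitivity /
false-confirmation of the duplicate-plus-retest criterion (40 conditions, 5
planted rescuers, 8% escapee well rate); 500 seeds for ε recovery at
n = 50/cell, noise SD 0.1; 200 seeds for type-I classification; 100 seeds
for cluster recovery (60-compound libraries, three planted 8-member
clusters) and for calcium group ordering (n = 30 cells, amplitudes 0.2 vs
1.0).  These sizes make the Monte-Carlo error small relative to each stated
tolerance.  The generators reproduce the *statistical structure* each stage
assumes — they do not model pharmacokinetics, dose–response, real chemistry,
plate effects or instrument drift, so passing tests demonstrate correctness
of the analysis chain under its stated assumptions, not robustness of the
biology to violations of them.

## Known limitations

- The screen's actual biological hit lists (145 retested, 74 confirmed)
  cannot be recomputed: the underlying well-level data are not deposited.
  The package validates the hit-calling machinery on synthetic screens
  instead.
- The kinase-library class enrichment p-values cannot be recomputed because
  the class sizes within that 880-compound library are not published; the
  identical Fisher machinery covers them.
- Dunn's post-test and the two-sided Fisher convention match the most common
  implementations; other software may differ in adjustment or sidedness
  conventions.
- The peak-of-maximum bias under noise, above.
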