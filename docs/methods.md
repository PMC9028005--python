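# Methods

This note documents the statistical model behind each pipeline stage,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were
genuinely open.

## Batch correction

`metareverse.combat` implements the parametric empirical-Bayes
location/scale model: after gene-wise standardization against the grand
mean and pooled variance (with the case/control label kept as a
covariate so the biological contrast is not absorbed), per-batch
per-gene location γ̂ and scale δ̂² estimates are shrunk towards
batch-level priors — normal on γ, inverse-gamma on δ² — whose
hyperparameters come from method-of-moments fits across genes, and the
data are back-transformed with the shrunk estimates. Conventions match
the reference R implementation (pooled variance with N denominator,
per-batch scale with ddof 1, fixed-point posterior solve to 1e-4), and
the test suite verifies agreement with `sva::ComBat` to 1e-8.

Numerical edge cases: a single batch is returned untouched; genes whose
pooled variance is numerically zero (below 1e-12 relative to the squared
grand mean) are passed through unadjusted and logged; when the per-batch
scale estimates are identical across genes the inverse-gamma moments
degenerate, and the posterior is taken in closed form at its limit
(common scale, location shrunk with that scale). A batch containing only
one biological group would make the covariate design unidentifiable, so
the fit proceeds without the covariate and warns.

One consequence of shrinkage worth knowing: a planted constant shift is
removed *exactly* only when the standardized batch effect is identical
across genes; with independent per-gene noise a small shrinkage residual
remains (well under 10% of the shift in the tests). The diagnostic
`batch_variance_report` quantifies residual batch signal as per-gene
one-way ANOVA F statistics.

## Random-effects meta-analysis

Per gene and cohort the effect is Hedges' g (small-sample-corrected
standardized mean difference, case minus control) with the standard
large-sample variance. The small-sample correction J matters at the
default cohort sizes (15–37 per arm). Cohorts are combined with
DerSimonian–Laird: non-iterative moment estimate of the between-study
variance τ², inverse-variance weights 1/(var + τ²), two-sided normal
test on the weighted mean, BH FDR across genes. A REML alternative for
τ² is available via `statsmodels` for sensitivity analyses but DL is the
default, being the canonical non-iterative choice in expression
meta-analysis tools. The implementation is vectorized across genes and
agrees with `metafor::rma(method="DL")` to machine precision.

Universe and exclusions: the analysis runs on the intersection of the
cohorts' gene sets; genes present in a single cohort and genes with zero
pooled variance in any cohort are excluded and counted. Direction is the
sign of the combined effect; per-cohort fold-change columns in the
output are mean log-scale differences and therefore dataset-scale
dependent. Within-cohort adjusted p-values are BH over all genes of that
cohort.

**Known limitation — small-k conservatism.** With only two cohorts the
τ² estimate is extremely noisy: under homogeneity Q exceeds its degrees
of freedom about half the time, τ̂² is then positive, and the combined
z-test is conservative. Empirically the type-I fraction at p < 0.05 is
≈ 0.03–0.04 rather than 0.05 at the default cohort sizes, and DEG
sensitivity at δ = 1 plateaus around 0.7 (a fixed-effect combination
reaches ≈ 0.87 on the same data). This is a property of the estimator,
not a defect of the implementation; the acceptance checks that assume
nominal calibration record it.

## Enrichment

Directional over-representation uses the hypergeometric upper tail with
the universe equal to the genes that entered the meta-analysis — not the
genome — which is the standard conditioning for DEG enrichment. Up- and
down-regulated DEGs are tested separately and BH correction is applied
within each (collection × direction) stratum, producing the two-column
layout used for heatmaps. Only enrichment (not depletion) is tested.
Transcription-factor analysis is the same machinery run over TF-target
GMT collections.

## Consensus drug signatures

Replicate z-score vectors are combined per gene with unweighted
Stouffer, Σzᵢ/√k, which preserves the standard-normal marginal under
independent replicates; a weighted variant is exposed for libraries that
carry replicate quality weights. No directional flipping or cell-line
modelling is applied — replicates are taken as given. The FDA-approved
flag filters the library before scoring (default on).

## Anti-signature screen

The disease signature is the vector of signed combined effect sizes over
the DEGs, restricted to the drug-library universe (a ±1 binary mode
exists for sensitivity analysis; the signed-magnitude default uses the
information the meta-analysis actually produced). Each drug is scored by
cosine similarity between that vector and its meta-signature on the same
genes. The null re-draws, per permutation, a uniformly random gene
subset of the universe of the same size, keeping the disease values
fixed — this tests whether the *identity* of the DEGs drives the match,
which is the question a repurposing screen asks; a drug-agnostic
rotation null is available behind a flag. The test is one-sided
(lower tail) because the screen is explicitly for signature reversal;
p uses the add-one estimator (1 + #{null ≤ obs})/(n_perm + 1), so the
minimum attainable p at the default 1000 permutations is 1/1001 and p is
never zero — printed zeros in screening tables are rounding. BH is
applied jointly across all scored drugs; hits require negative cosine
and FDR ≤ α. Drugs sharing fewer than 10 genes with the disease vector
are flagged low-overlap and excluded. Internally genes and drugs are
processed in sorted order, making results invariant to input ordering
and reproducible from the seed.

BBB annotation joins on case-folded, whitespace-trimmed compound names
with no salt or stereochemistry normalization; unmatched drugs are
`unknown` and drop out of the permeable-only view.

## Clustering

The top k (default 50) most anti-similar drugs are clustered by
complete-linkage agglomeration on cosine distance (1 − cos). The
agglomeration is implemented directly with the Lance–Williams max
update and a lexicographic tie-break on sorted leaf-name tuples, because
deterministic merge order under ties is part of the output contract
(dendrogram text, merge table, similarity matrix in leaf order); the
tests verify equality with a from-scratch max-over-leaves agglomerator
and with `scipy` heights on tie-free instances. Complete linkage cannot
produce height inversions, and the tests assert monotonicity.

## Synthetic data: what it emulates and what it does not

`simulate_cohorts` draws gene baselines μ_g ~ N(7, 1) on a log-intensity
scale, adds a per-cohort per-gene batch shift N(0, batch_shift_sd), a
group effect ±δ on a planted DE subset (signs split evenly), and i.i.d.
Gaussian noise. Default study conditions: 5000 genes, 200 DE genes at
δ = 1, noise sd 1, batch shift sd 1, and two cohorts of 18/37 and 18/15
control/case samples — the sizes of the two entorhinal-cortex studies
the pipeline was designed around, so that power behaviour is comparable.
The generator does not emulate probe-level effects, count noise,
gene–gene correlation, or batch×variance interactions beyond the scale
term ComBat models; passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed model, not performance
on real microarray data.

`simulate_drug_library` gives background drugs i.i.d. N(0, 1) replicate
z-vectors. A planted anti-drug of strength a ∈ [0, 1] has replicates
z = −a·√p·u + √(1−a²)·ε with u the unit disease-direction vector over
the p-gene universe and ε ~ N(0, I). The √p scaling makes each replicate
an approximately unit-variance z-vector at every strength (the per-gene
signal at a DE gene is then about a·√p·u_g ≈ ±1 for the defaults),
gives cosine ≈ −a against the full universe, and yields the boundary
behaviours one wants from a planted truth: a = 1 with zero noise is an
exact reversal (cosine −1), a = 0 is indistinguishable from background.
Mixing the unit vector without the √p factor would bury the planted
signal below the 1/√m cosine noise floor of an m-gene disease vector and
make "planted" drugs unrecoverable at any realistic strength.

`simulate_gene_sets` builds GMT collections in which a stated fraction
of sets draw at least half their members from the planted DE genes.
`simulate_bbb_table` covers 90% of the drug list (benchmark tables never
cover a whole screening library) and labels each covered drug permeable
with probability `bbb_fraction` (default 0.5). All generators derive
their streams from one master seed via SeedSequence spawning, so every
artifact is a pure function of (config, seed).

## Problem sizes and tolerances used in the checks

Closed-form estimators are checked against independent direct-formula
oracles at 1e-10 on 1000 random instances, and against R reference
implementations (`sva::ComBat` at 1e-8, `metafor` during development).
Calibration and recovery checks use the default study conditions above;
the drug-screen checks use 200 drugs over 1000 genes with a 150-gene
disease vector, 3 replicates per drug and 1000 permutations, aggregated
over 20 seeds in the tests (5 seeds in the acceptance script, which
favours a quick single run). The end-to-end determinism check runs the
full pipeline twice at reduced size (600 genes, 40 drugs, 300
permutations) and compares artifacts byte for byte.

## Known limitations

* Two-cohort DL meta-analysis is conservative (see above); with many
  cohorts the issue fades.
* The permutation null treats drug signatures as fixed and re-draws gene
  subsets; it does not model inter-drug correlation in real libraries.
* BBB matching is by plain compound name; synonyms, salts and brand
  names will not join.
* Fold-change columns mix scales across platforms; only the
  standardized effects are cross-cohort comparable.
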