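# Methods

`poolgs` implements genomic selection for outbred forage breeding programs
in which the unit of selection is a *synthetic population* (an intercross of
4–6 parents) genotyped as a pool and phenotyped as replicated sward plots.
This note records the models, the synthetic-data generator that stands in
for a proprietary breeding dataset, and the numerical and design choices.

## 1. Pool genotyping

Pooled sequencing observes allele frequencies, not genotypes. For each
bi-allelic variant the per-sample AD field gives reference/alternate read
depths `(r, a)`; the reference allele frequency is `r / (r + a)`.

Reliability rules (with their default thresholds):

- **Locus rule** — a locus is removed when *strictly more than* 50% of the
  pools have total depth `r + a < 100` reads. Depth of evidence is counted
  over both alleles; the rule could alternatively be read as reference-only
  depth, but total depth is the natural measure of call reliability.
- **Call rule** — an individual frequency estimated from `< 40` reads is
  re-coded as missing. Zero-depth entries are missing, never a division
  error.

Both inequalities are strict; a locus with exactly half its pools below 100
reads is retained, and a call at exactly 40 reads is kept.

## 2. LD-kNN imputation of allele frequencies

The classical LD-kNN genotype imputation is generalised from discrete
genotype classes to continuous frequencies. For a target locus `j` with a
missing entry in population `p`:

1. rank all other loci by squared Pearson correlation (`r²`) of allele
   frequencies with locus `j`, computed over populations observed at both
   loci; pairs sharing fewer than 5 observations are excluded; keep the top
   `l` (default 17, as in the published parameterisation, with `k = 11`);
2. compute the distance from `p` to every population observed at `j` as the
   *mean absolute frequency difference* over those `l` loci (missing
   coordinates are skipped, which rescales the Manhattan distance by the
   number of coordinates used);
3. impute with the inverse-distance-weighted mean (`w = 1/max(d, 1e-8)`)
   of the `k` nearest donors.

Because the published method defines distances and votes for genotype
classes only, the continuous adaptation (Manhattan distance, weighted mean
instead of weighted vote) is this package's interpretation; all pieces are
exposed in `ImputationParams`. Ties are broken by stable input order.
Fallbacks: fewer than `k` donors → use all; a locus with no donors at all →
the population's own mean frequency, else the global mean. Observed entries
are never modified, and imputed values are convex combinations of observed
values at the same locus except in the fallback cases.

Imputation is performed once on the complete data set before forward
validation, mirroring the study design (genotype processing is phenotype-
free, so this cannot leak phenotypic information into prediction years; the
no-leakage audit in the test suite checks the phenotype pathway).

`assess_imputation` masks a fraction of known entries uniformly at random
(re-drawing if a locus would lose all observations) and reports the Pearson
correlation between true and imputed values.

## 3. Two-stage phenotype adjustment

**Seasons.** Each biomass harvest is allocated to one of five seasons of
the southern-hemisphere forage year — autumn (Mar–May), winter (Jun–Jul),
early spring (Aug–Sep), late spring (Oct–Nov), summer (Dec–Feb) — by the
growth window since the previous harvest (or sowing): the harvest belongs
to the season containing most window days, ties broken toward the season of
the harvest date. Seasonal responses are sums of a plot's harvests per
production year; the two production years are repeated records of the same
trait. An `average` response (mean of the five seasonal sums) is carried as
a sixth category. Heading date (days since 1 September) is a single score
per row plot.

**Stage 1 (within trial).** Per trial and season, the model
`value = population (fixed) + block (random) + error` is fitted by REML.
The solver profiles the residual variance analytically and optimises the
block-to-error variance ratio on the log scale by bounded Brent search
(tolerance 1e-8); a companion fit with population random (two variance
ratios, Nelder–Mead) yields `sigma2_population` for the line-mean
heritability

    H² = σ²_pop / (σ²_pop + σ²_error / n_records),

with `n_records` the records per population in that fit (blocks ×
production years). Each population's adjusted mean is accompanied by a
weight equal to the inverse variance of that mean — the diagonal version of
the standard two-stage weighting; the full-covariance variant is not
implemented.

**Reference chaining.** Trials are expressed relative to a chain of
reference-check cultivars with overlapping eras. Within every trial the era
anchor's adjusted mean is subtracted (anchor = 0 exactly); the offset of
each next anchor relative to the first is estimated from the stage-2
combination of the *previous* era's trials, where the next anchor also
appears, and added to the next era's values. A missing anchor or a missing
overlap era is an error naming the broken link.

**Stage 2 (combination).** Scaled values are combined per season in the
one-way random-effects model `value = g_pop + e`, `g ~ N(0, σ²_g)`,
`Var(e) = 1/weight`. Because stage-1 weights are absolute inverse
variances, the residual variance is *known*; only `σ²_g` is estimated, by
marginal maximum likelihood (the likelihood factorises over populations).
This identification matters: with nearly every population appearing in a
single trial, a model with a free residual scale cannot separate it from
`σ²_g` and collapses. No intercept is fitted, so predictions shrink toward
the anchor (zero); in noise-free data the anchor's final value is exactly 0
and predictions equal weighted means.

## 4. Genomic relationships and group clustering

Genotype codes are `x = 2·af ∈ [0, 2]`. With per-locus mean frequency `p_j`
over the analysed populations, the SNP-based relationship estimator uses

    G_ik = (1/m) Σ_j (x_ij − 2p_j)(x_kj − 2p_j) / (2p_j(1−p_j)),  i ≠ k
    G_ii = 1 + (1/m) Σ_j (x_ij² − (1+2p_j)x_ij + 2p_j²) / (2p_j(1−p_j)),

excluding monomorphic loci (with `m` reduced accordingly). Note two
properties of the continuous-frequency adaptation verified in the tests:
the diagonal formula does not equal the off-diagonal formula evaluated on
duplicate rows, and sample-frequency centring gives iid populations a mean
off-diagonal of about `−v̄/(n−1)` rather than exactly zero.

Clustering runs partitioning around medoids (deterministic BUILD + SWAP,
implemented here) on the dissimilarity `d = max(G) − G` with zero diagonal,
choosing `k ∈ {2..10}` by maximum average silhouette width; if no positive
silhouette exists the method falls back to `k = 2` with a warning and the
assignment is flagged low-confidence. The largest cluster of the reference
(whole-data) clustering defines Group A and the second Group B; re-clustered
subsets inside forward validation are mapped onto A/B by majority overlap
with those labels, extra clusters become `unassigned`, and per-locus mean
frequencies are always recomputed on the subset being clustered. The
alternative dissimilarity `1 − G/max(G)` would give identical PAM solutions
for fixed `k` (the transform is affine); the max-shift form is used for
simplicity.

## 5. BayesA

The prediction model is `y = u·1 + X v + e` with marker-specific variances
`v_i ~ N(0, σ²_{v_i})`, scaled-inverse-chi-square priors on every variance,
and continuous genotype codes. Priors are elicited from a trait
heritability `h²` (the mean within-trial heritability of the reference
trials): with `ν_v = ν_e = 5`,

    S_v = var(y) · h² · (ν_v + 2) / Σ_j var(X_j)
    S_e = var(y) · (1 − h²) · (ν_e + 2),

so the implied total marker variance matches `h²·var(y)` and the residual
prior mode `(1 − h²)·var(y)`. Inference is single-site Gibbs with a running
residual (O(nm) per sweep, numba-compiled), 12,000 iterations with 2,000
burn-in by default; marker variances update as
`(ν_v S_v + v_i²)/χ²_{ν_v+1}` and the residual as
`(ν_e S_e + Σ w e²)/χ²_{ν_e+n}`. Phenotype-stage weights enter as
per-record residual precision multipliers (normalised to mean 1 so `σ²_e`
keeps the trait scale); this default can be switched off. Columns of `X`
are mean-centred with the constants stored for prediction-time reuse; GEBVs
are `u + X_centred·v̄` with posterior means over post-burn-in samples.
Identical seeds reproduce chains bit for bit.

Before any fit, loci are filtered to those whose allele-frequency variance
across the *current reference populations* is strictly above 0.01.

## 6. Forward validation

For prediction year `Y` with gap `g` (default 1), the reference is every
population sown in years `≤ Y − g`, minus one extra year for biomass
(populations sown the year before are still being assessed in the field).
Scopes: `global`, or within Group A/B after re-clustering the
reference ∪ prediction subset. A group scope is skipped when its reference
holds fewer than 50 populations; the same floor is applied to the global
scope (the emulated program never predicted from very small references —
without the floor, early desk-scale years with ~25 reference populations
dominate the summary). Per year/scope/season the pipeline variance-filters
loci on the reference, elicits priors from the reference trials' mean
heritability, fits BayesA, predicts GEBVs for the new populations, and
reports accuracy (Pearson correlation with adjusted phenotypes), a
10,000-resample bootstrap (mean, SD, 2.5/97.5 percentiles; degenerate
resamples are redrawn rather than scored), the bias slope (OLS of phenotype
on GEBV; 1 = unbiased, > 1 = under-prediction), and the moving average of
accuracy over current and prior years. Reference-side artifacts (retained
loci, priors, training data) are computed by one function from reference
data only, which the no-leakage audit exploits.

## 7. The synthetic breeding program

No data from the emulated program are public, so the generator produces a
full analog with known truth. What it emulates, and how:

- **Two germplasm groups.** Ancestral allele frequencies and group-specific
  deviations come from a Gaussian copula along a linear map (7 chromosomes,
  unit-spaced loci, exponential correlation decay, default 30 map units);
  group deviations follow the Balding–Nichols model, so realised Hudson-type
  Fst matches `group_divergence` (default 0.3). Founder haplotypes are
  thresholded from the same copula, giving within-group LD.
- **Synthetic populations.** Each year ~24 new populations are formed from
  4–6 parents. Parent populations are drawn from the elite half (by true
  average biomass value) of populations 3–6 years old, recycling elite
  material as real programs do; each chosen parent contributes one diploid
  plant sampled with copula-correlated haplotypes. Plant sampling is
  essential: forming crosses as deterministic means of parent frequencies
  erodes between-population genetic variance to nothing within a few cycles,
  whereas segregation regenerates it each generation — with LD, so markers
  track it. The exposed `form_population` (exact mean of parental
  frequencies) retains the closure property that a cross of identical
  parents reproduces the parent.
- **Group B enters late** (year 5 of 10, 25% of new crosses), within-group
  crossing only.
- **Traits.** Causal loci are drawn at intermediate frequency (mean group
  frequency in [0.2, 0.8]; loci near fixation contribute no variance) and
  are part of the genotyped panel, as expected for a transcriptome-based
  assay. Biomass: 90 causal loci with season-correlated effects
  (correlation 0.5 across the five seasons). Heading: 10 loci of large
  effect. Marker effects differ between germplasm groups with cross-group
  correlation 0 for biomass and 0.8 for heading — calibrated to the
  observed pattern that biomass prediction does not transfer across groups
  while heading prediction largely does — and the between-group trait mean
  difference is set to 0 genetic SD by default.
- **Phenotypes.** Two trials per year, threefold replication, two
  production years with a fixed six-harvest schedule per year (so every
  season receives at least one harvest and the allocation logic is
  exercised). Per trial and season, the residual SD is set so the line-mean
  H² (records = blocks × production years) matches the target:
  seasonal targets 0.43/0.55/0.55/0.41/0.26 (autumn…summer; overall mean
  ≈ 0.44) for biomass and 0.86 for heading. Trial effects (SD = 0.5 genetic
  SD) and block effects (SD = 0.5 residual SD) add the spatial/temporal
  structure the two-stage analysis removes. Three check cultivars with
  overlapping eras anchor the reference chain. `residual_scale = 0` gives
  the exact noise-free limit (all environmental terms vanish).
- **Pooled reads.** A pool of `2 × 60` gene copies is resampled binomially
  from the true frequency; total depth is negative-binomial (gamma–Poisson)
  with mean 300 and shape 1.0 — strong overdispersion mimicking
  expression-dependent RNA-seq coverage — which yields ~12% of calls below
  40 reads, matching the emulated data's missing-call level; reference
  reads are binomial in the pool frequency.

**Desk scale.** Default sizes (10 years × 24 populations, 600-locus panel,
100 founders per group) are chosen so a complete program analysis runs in
well under a minute. The panel is deliberately scaled down with the
reference size: at a few hundred reference populations, a panel of tens of
thousands of markers would make BayesA's estimation-noise floor — not the
biology — the dominant term, which is not the regime being mirrored. What
passing tests show is therefore that the *pipeline recovers the qualitative
regime* (high accuracy for the simple high-h² trait, moderate for seasonal
biomass, group-A-restricted prediction at least as good as global once the
second group appears, accuracy ordered by heritability); they do not show
that real sequencing data of a specific program would reach any particular
accuracy. Features of real data not emulated: genotyping error beyond
binomial sampling, G×E across years, spatial field trends beyond block
effects, overlapping generations in trials, and selection on observed
(rather than true) values.

## 8. Numerical choices

- REML: variance ratios on `log λ ∈ [−12, 12]`; Brent (`xatol 1e-8`) for
  one ratio, Nelder–Mead with two starts for two; the profile residual
  variance is floored to avoid log-of-zero in noise-free data.
- Stage-2 ML: `log σ²_g ∈ [−14, 14]`, Brent; noise-free shortcut when a
  replicated population shows exactly zero residuals.
- Imputation: distance floor `ε = 1e-8`; all ties by stable input order.
- GRM: monomorphic tolerance `2p(1−p) > 1e-9`.
- PAM: BUILD initialisation + best-improvement SWAP; deterministic, so the
  seed argument only preserves the interface.
- Gibbs sampler: chains keyed by 31-bit seeds derived from
  (seed, year, scope, season) via `SeedSequence`; weights normalised to
  mean 1.
- Bootstrap: degenerate resamples redrawn (bounded at 100 rounds) rather
  than scored as zero, preventing spurious mass at undefined correlations.

## 9. Known limitations

- The continuous-frequency LD-kNN distance/weighting is an interpretation;
  the original in-house adaptation is unpublished.
- Stage-1 weights are diagonal (per-mean inverse variances); covariances
  between adjusted means within a trial are ignored, as is conventional in
  two-stage trial analysis but approximate.
- The anchor-subtraction step propagates the anchor's own error into every
  value of a trial; with three replicates this is visible as a small
  correlated noise floor in adjusted values.
- PAM is exact best-improvement search, O(k·n²) per sweep — fine for
  hundreds of populations, not for tens of thousands.
- Group scopes skip years with small references instead of borrowing
  information across groups; no admixture modelling.
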