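# Methods

## The model

`pedgwas` scans a quantitative trait measured on pedigreed animals (the
motivating setting is dairy cows with repeated lactation records) for
additive, dominance and pairwise additive-by-additive marker effects with
the single-marker mixed linear model

```
y = 1 mu + X b + Z u + W pe + e
u  ~ N(0, A sigma_g^2)      pedigree polygenic effects
pe ~ N(0, I sigma_pe^2)     cow-level permanent environment
e  ~ N(0, I sigma_e^2)      record-level residual
```

`A` is the numerator relationship matrix built from the pedigree by the
tabular method with inbreeding; `Z = W` maps records to cows. The fixed
part `X b` changes with the tested effect:

* additive: `x_a(j) a_j`
* dominance: `x_a(j) a_j + x_d(j) d_j` (the test is on `d_j`)
* epistasis: `x_a(j) a_j + x_a(k) a_k + x_e(jk) a_jk` (test on `a_jk`),
  optionally plus conditioning markers' additive covariates.

Marker covariates are allele-frequency-centred: with `p` the frequency of
the counted allele A and `q = 1 - p`, genotypes aa/Aa/AA map to
`{-2p, q-p, 2q}` (additive) and `{-2p^2, 2pq, -2q^2}` (dominance). Under
Hardy-Weinberg class frequencies these contrasts are mean-zero and mutually
orthogonal, which is what makes the per-marker variance partition
`sigma_a^2 = 2pq a^2` and `sigma_d^2 = 4 p^2 q^2 d^2` coherent; both are
reported as percentages of the null-model phenotypic variance
`sigma_p^2 = sigma_g^2 + sigma_pe^2 + sigma_e^2`. The construction of the
epistatic covariate is genuinely open in this literature; we use the
elementwise product of the two centred additive covariates. A documented
hazard follows from the algebra: for two markers in complete LD at p = 1/2
the product is collinear with the dominance contrast.

Allele frequencies are computed per analysis population, since the codings
are defined by the frequency *in the population being analysed*; effect
signs are therefore comparable across populations only when the panels
share allele labelling (the generator guarantees this).

## Pre-correction

Records are first adjusted for herd-year-season, parity, age class and
month of calving by OLS on the full recorded set (statsmodels), and the
residuals of genotyped animals become the scan response. OLS rather than a
mixed pre-correction is the simplest defensible reading of a two-stage
design; the test suite documents that at simulated scale the two-stage
estimates agree with a joint fit within sampling error, but also that the
absorbed fixed-effect degrees of freedom visibly shrink the residual
variance when records are few (hundreds) — a small-n artifact that vanishes
at the record counts (tens of thousands) such scans are run at.

## Estimation and testing

Variance components of the SNP-free null model are estimated by
average-information REML with step-halving and a classical EM-REML fallback
whenever the AI matrix is near singular (that condition — e.g. `A = I` with
single records, where polygenic and residual variance are confounded — is
flagged on the result). Convergence requires both the log-likelihood change
and the relative parameter change to fall below 1e-6; components are kept
non-negative by projection. All REML linear algebra is dense in the number
of records, which is the right trade-off at the package's simulated scale
(thousands of records).

Marker effects are generalized-least-squares solutions of Henderson's
mixed-model equations. Because `u` and `pe` share the incidence `Z`, the
two random effects collapse into one cow-level effect with covariance
`G* = A sigma_g^2 + I sigma_pe^2`, and the absorbed coefficient matrix
`M = Z'Z + sigma_e^2 G*^{-1}` is factorized once per scan; each marker then
costs two per-cow aggregations and a small solve. The record-level
covariance `V` is never inverted explicitly outside the test oracles, which
check the absorbed solution against direct `V^{-1}` GLS to 1e-8. The focal
effect is tested with a two-sided Wald F on 1 numerator df and
`n_records - rank(fixed design)` denominator df. Rank deficiency of the
fixed design (monomorphic marker, complete-LD pair, conditioning marker
equal to a pair member) is detected by QR and reported as not-testable;
such markers are excluded from the test count T.

Two fitting modes exist: `fixed-vc` (default) reuses the null components
for every marker; `per-snp-reml` re-estimates them with the marker in the
model. The suite shows the two agree to |Δ(-log10 p)| < 0.15 for ordinary
markers at a few hundred cows; a large planted QTL is the documented
exception, since its presence in the fixed part legitimately changes the
REML polygenic variance.

## Thresholds, FDR, validation, epistasis screen

Genome-wide significance is Bonferroni `alpha / T` with an optional
round-to-nearest-power-of-ten convention (0.05/408,255 ≈ 1.2e-7 quoted as
1e-7); suggestive fallbacks (defaults 1e-4 discovery, 1e-2 validation) are
used when nothing passes. Each stage reports the closed-form FDR

```
%FDR = P (1 - S/T) / ((S/T) (1 - P)) x 100
```

which exceeds 100% when the hit rate S/T falls below the threshold P, is
increasing in P and decreasing in S, and is undefined (NaN, with a warning)
at S = 0. Significant markers are merged into regions by single linkage
within 1 Mb — the distance over which strong LD is plausible in these
populations — with the top marker per region chosen by smallest p, ties to
the smaller coordinate.

Cross-population validation takes two forms. *Individual*: a discovery hit
must be significant in the validation population; direction concordance is
recorded; stage T is the number of hits actually tested there. *Segment*: a
hit is confirmed by any significant validation marker within ±500 kb
(inclusive); stage S counts distinct significant validation markers in the
union of windows and stage T all distinct testable validation markers in
that union — the metadata of every report states this definition, since a
segment-stage T is not otherwise canonical.

The epistasis screen tests all `n(n-1)/2` unordered pairs of additively
significant discovery markers against the pairwise Bonferroni threshold
`0.05 / (n(n-1)/2)` (same rounding option). The conditional re-scan re-tests
every significant pair with a designated tag marker's additive covariate
added; pairs that lose significance were proxies of that single effect.

## The synthetic herd generator

The generator exists so every stage is testable without proprietary herd
data. It emulates, with known truth:

* **Pedigree**: discrete generations, balanced sexes, each offspring a
  random sire x dam mating from the previous generation (sires reused, as
  under artificial insemination).
* **Genotypes**: founder haplotypes are mosaics of a few ancestral
  templates (geometric block length, default 2 Mb, light mutational noise),
  so r^2 decays with map distance; gametes recombine at 1 cM/Mb through the
  pedigree. Founders draw two haplotypes from a 30-haplotype pool, giving
  Hardy-Weinberg founder genotypes at pool frequencies.
* **Phenotypes**: configured additive/dominance effects and additive x
  additive pairs at named panel loci, polygenic values from the pedigree
  Cholesky, cow permanent-environment effects, 1-4 records per cow
  (mean 2.5), and four random-level fixed factors (herd-year-season 25,
  parity 4, age class 5, month 12; level SD 0.5).
* **Variance presets**: the default split (0.3, 0.1, 0.6) is a
  milk-yield-like trait (h^2 = 0.3); `SimulationConfig.low_heritability()`
  gives a fertility-like trait (0.04, 0.16, 0.80).
* **Two populations**: partially overlapping founder haplotype pools
  (default 50%) on a shared map, so some causal variants segregate in both
  "breeds" and some in one — allowing genuine non-replication.

Desk-scale defaults are ~2,000 phenotyped cows and 5,000 markers on 5
chromosomes; tests use smaller instances (stated below).

### The hidden causal variant and its tags

The `hidden_causal` block reproduces the configuration in which a strong,
purely additive causal variant that is *not on the panel* manufactures
spurious pairwise interactions among its tags. The construction is nested
carrier sets on the founder haplotype pool: the mutation marks a carrier
set C (default frequency 0.2, typical of a selected large-effect allele);
the best tag (*hub*, target r^2 = 0.9) marks a slightly larger ancestral
set H ⊇ C; every other tag (targets 0.3-0.7) marks a set containing H.
Realized genotype-level r^2 to the causal dosage is measured and must fall
within ±0.1 of target (membership is resampled up to a retry limit). This
nesting mirrors a recent mutation on a single haplotype background eroded
outward by recombination, and has two consequences the package's headline
test depends on: two-tag allele combinations localize H better than any
single tag (so product covariates pick up real signal and the interaction
scan fires although no epistasis exists), and the causal allele is
conditionally independent of every tag given the hub (so adding the hub's
additive covariate removes the artifact entirely — the conditional re-scan
comes back empty). An earlier design with independently noised tags was
discarded: the relevant three-locus haplotype moment is proportional to
(1 - 2p) and nearly cancels for alleles near frequency 1/2, producing an
artifact too weak and too erratic to characterize at desk scale.

What the generator does **not** emulate: coalescent-accurate LD, selection
and drift dynamics, genotyping or imputation error, censored fertility
records, and age effects that are truly continuous. Passing tests therefore
demonstrate correctness of the machinery under the stated generative model,
not robustness to those real-data complications.

## Problem sizes used by the test suite

Simulation-based checks are sized to run on one CPU in minutes, as the
package's own choice of desk scale: type-I calibration pools ~5,000 null
markers over 20 independent 300-cow herds; effect recovery uses ~30
replicates of 1,000 cows; REML recovery 7 replicates of 260 cows with two
records each; the hidden-causal interaction artifact 6 replicates of 3,000
cows (interaction power at the 2,000-cow default is marginal; discovery
herds at the scale this emulates run to ~7,000 cows); the power-ordering
comparison 200 replicates of 500 unrelated individuals. Where a check isolates one engine
(REML, the artifact screen) the generator's true variance components or a
raw (fixed-effect-free) response are used so the result is not confounded
with the two-stage pre-correction's small-sample behaviour.

## Numerical choices

* Variance-component floor 1e-10 x var(y); components pinned near the floor
  are reported as exactly 0.
* AI matrix condition number above 1e8 triggers the EM step and the
  `ai_singular` flag.
* QR rank tolerance for the fixed design: 1e-8 relative to the largest
  diagonal of R.
* p-values are floored at the smallest positive float to keep
  -log10 transforms finite.
* The relationship-matrix Cholesky used to draw polygenic values adds
  1e-10 jitter to the diagonal.
* Missing genotypes (the data this emulates were imputed, so missingness is
  exceptional) are mean-imputed on the coded scale, contributing no
  information; all-missing markers are flagged and excluded.

## Known limitations

* No genomic relationship or dominance relationship matrices; the polygenic
  term is pedigree-only by design.
* No genetic groups for unknown parents; unknown parents are unrelated,
  non-inbred founders.
* The closed-form FDR is a population-level expectation, not an FDR-
  controlling procedure; it is reported, never used to select markers.
* Censoring of fertility-type records is not modelled, matching the
  two-stage design this follows.
* The X chromosome is treated as autosomal, which is adequate only for
  all-female analysis sets.
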