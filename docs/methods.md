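# Methods

## The model

For a quantitative trait y measured once per individual (here: the derived
two-visit change), the variance-components model assumes

y ~ N(Xβ, V),  V = 2Φ σ²_g + Π σ²_q + I σ²_e,

with Φ the pedigree kinship matrix, Π the matrix of locus-specific pairwise
IBD proportions, σ²_g the additive polygenic variance, σ²_q the variance
attributable to a QTL at the scanned locus, and σ²_e the residual. The
polygenic null model sets σ²_q = 0. All fits are **maximum likelihood, not
REML**, so the H1 and H0 log-likelihoods are directly comparable and
LOD = (ln L₁ − ln L₀)/ln 10 is well defined. The cost of ML is a mild
downward bias in variance-component estimates of order p/n (here p = 1
fixed effect), negligible at family-study sample sizes.

Heritability is h² = σ²_g/(σ²_g + σ²_e). Its p-value is a likelihood-ratio
test of σ²_g = 0 against the boundary null, the ½χ²₀ + ½χ²₁ mixture. Its
standard error comes from the delta method applied to the inverse observed
information in (σ²_g, σ²_e), with the information matrix obtained by central
finite differences of the profiled log-likelihood (relative step 10⁻⁴); at
the h² = 0 boundary the SE is reported as NaN, since the usual asymptotics
do not hold there.

## Numerical strategy

β is profiled out by GLS and the residual scale σ²_e analytically, leaving
the variance *ratios* a = σ²_g/σ²_e (and b = σ²_q/σ²_e under H1) as free
parameters, maximised by bounded L-BFGS-B with a ≥ 0, b ≥ 0 and a
log-likelihood convergence tolerance well below 10⁻⁸; three fixed perturbed
restarts run only when the first optimisation fails to converge. Under H1
the search starts exactly at the H0 optimum (a = â₀, b = 0), which
guarantees ln L₁ ≥ ln L₀ and hence LOD ≥ 0 by construction — when Π = 2Φ the
components are confounded, the optimiser finds no gain, and the LOD is 0 to
optimiser precision.

The likelihood factorises over families. Families are grouped by size and
processed as stacked blocks with batched Cholesky factorisations, which is
what makes 200-replicate null calibrations run in seconds. The same
factorisation yields per-family log-likelihood contributions evaluated at
the *global* MLEs, so the per-family LOD decomposition (PEDLOD) sums to the
total LOD exactly (within 10⁻⁸ floating-point accumulation). Evaluating at
global rather than per-family estimates is what the cumulative-LOD
family-selection rule implicitly assumes; it is also the only choice that
makes the decomposition additive.

Degenerate inputs: a kinship matrix with no off-diagonal relatedness makes
σ²_g and σ²_e unidentifiable and raises an error in the polygenic fit; in
the measured-genotype association the ratio is then irrelevant (any value
yields the same GLS fit) and is pinned at 0, which reduces the model to
OLS.

## Association

The measured-genotype test appends the variant dosage to the fixed effects
and re-estimates the variance ratio per variant by default (a fast mode
reuses the null-model ratio; the mode is logged). The Wald statistic uses a
degrees-of-freedom-corrected residual variance (RSS/(n − p)) and a
Student-t reference with n − p degrees of freedom. At family-study sample
sizes this is indistinguishable from the conventional normal reference, and
it has the clean property that with an identity kinship matrix the result
coincides *exactly* with OLS — which is how the implementation is
cross-checked against statsmodels.

Significance tiers follow genome-wide convention: significant at p < 5×10⁻⁸,
suggestive for 5×10⁻⁸ < p < 10⁻⁵ (both strict; boundary values are logged).
The linkage LOD threshold is 3.0, with a conventional suggestive tier at
1.9 available as clearly-labelled optional output.

simpleM computes the marker–marker correlation matrix on dosages
(pairwise-complete observations; composite genotypic correlation, since no
phase information is assumed), eigen-decomposes it, and takes n_eff as the
smallest k whose top-k eigenvalues capture ≥ 99.5% of the total — the
standard variance fraction for this method. The gene-level threshold is
α/n_eff and a gene "replicates" when its smallest marker p-value beats that
threshold. Omics features (expression, metabolites) are tested by plain OLS
with covariates, with per-family Bonferroni verdicts (e.g. 0.05/188 ≈
2.7×10⁻⁴ for a 188-metabolite panel, 0.05/13 ≈ 3.8×10⁻³ for 13 compound
classes).

## Trait derivation

With exactly two visits per subject, growth-curve slopes are statistically
equivalent to per-subject slopes — a random-slope mixed model is not
identifiable from two points — so the default change trait is the
annualised difference (y₂ − y₁)/(t₂ − t₁), with the raw difference
available as an alternative mode. Covariate adjustment is a two-stage OLS
(residuals on intercept + covariates, categorical columns expanded to
indicators, constant columns absorbed by the intercept) followed by the
Blom transform, Φ⁻¹((r − 3/8)/(n + ¼)) with average ranks for ties. Familial
correlation is deliberately *not* modelled at this stage; every downstream
genetic test carries the kinship random effect. The stage order
derive → adjust → transform is fixed, logged, and recorded in the output
metadata, because transforming before adjusting changes results. Baseline
(visit-1) covariate values are used by default; this and the visit used for
undiagnosed-diabetes exclusions (visit 1) are configurable.

Two-stage adjustment has a known small cost: covariates that are
constant within families (field center) or structured by generation (age)
absorb a sliver of between-family polygenic variance, biasing ĥ² downward
by ~0.01 in the recovery experiments. This mirrors the design of real
family studies and is left as-is.

## Quality control

Variant filters: call rate ≥ 98%, MAF ≥ 1% (monomorphic variants fail this
rule rather than erroring), and an exact Hardy–Weinberg test at p ≥ 10⁻⁶.
The HWE test enumerates all heterozygote counts compatible with the
observed allele counts and sums probabilities no larger than the observed
configuration's — a chi-square approximation is unreliable at a 10⁻⁶
threshold for low-MAF variants, which is exactly where the filter operates.
Dosages are rounded to hard calls for the HWE test (nearest integer,
ties-to-even); intermediate dosages are rounded rather than set missing,
for simplicity, and the policy is logged. Missing dosages are tracked as
NaN and never imputed.

Sample exclusions are a pure function of four fields: T2D diagnosis, T2D
treatment, fasting glucose ≥ 126 mg/dL, HbA1c ≥ 6.5% (evaluated at
visit 1); missing values are non-exclusionary and logged. Both filters are
idempotent.

## The simulator

The generator emulates a two-generation family study of longitudinal HbA1c
change. Defaults are the scenario the analysis is calibrated under: visit
gap 7.8 years; baseline 5.5% HbA1c with 0.3% between-subject SD; modest
baseline covariate effects of age, sex and field center; slope heritability
0.368; a diallelic QTL of allele frequency 0.06 explaining 30% of slope
variance; slope scale 0.013 %HbA1c/year (≈ 0.1% change over a 7.8-year
gap); 19 unlinked null markers alongside the QTL; 200 families of the
nuclear-with-4-sibs template.

Founder alleles carry unique labels; each child inherits one uniformly
random allele per parent per locus. Labels give *exact* IBD — the bridge
invariant E[Π] = 2Φ connects the simulator to the linkage model and is
tested. Loci are unlinked by design: the analysis consumes per-locus IBD
matrices directly, so a recombination map would add nothing but
approximation error. The QTL is additive in dosage (no dominance). Visit-1
measurement noise is carried into visit 2 (y₂ = y₁ + s·gap), so the
derived slope isolates the latent slope exactly. All randomness flows from
one seeded generator; a fixed seed reproduces every file byte-for-byte.

What the simulator does **not** emulate: longevity-based ascertainment of
families (the sampling bias such studies note but do not correct),
genotyping error, non-MCAR missingness, linked markers / LD structure, and
multi-visit (> 2) trajectories. Passing recovery and calibration tests
therefore demonstrates correctness of the estimators under the assumed
model, not robustness to those real-data complications.

## Problem sizes used in validation

Heritability recovery uses 200 six-member families × 20 seeds × three true
h² levels; LOD null calibration uses 200 scans of 20 loci on 50 families;
type-I calibration uses 500 null marker tests on 50-family datasets;
percent-of-linkage accounting averages 5 replicates of the 200-family QTL
scenario (single-replicate percentages carry ±10–15 point boundary noise);
kinship oracles use 200,000 gene drops per pedigree. These sizes keep each
quantity's Monte-Carlo error comfortably inside its acceptance band while
the whole validation suite completes in a few minutes.

## Known limitations

- No multipoint IBD estimation: Π matrices are inputs (or exact simulator
  output), in the variance-components tradition of precomputed sharing.
- No ascertainment correction for non-randomly sampled families.
- Genome-wide empirical LOD significance (gene-dropping null distribution
  of the peak) is not implemented; the fixed LOD > 3 threshold is used.
- D′/haplotype LD metrics are out of scope (no phasing); marker correlation
  is genotypic.
- The heritability SE is a curvature-based approximation; near the h² = 0
  or 1 boundaries it should be interpreted cautiously.
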