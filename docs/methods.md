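# Methods

`abaqg` estimates genetic parameters for a single-generation aquaculture
breeding study — growth, meat and foot-color traits of Pacific abalone
(*Haliotis discus hannai*) reared as pedigreed full-sib families — and
ships a synthetic-data generator that emulates the study design closely
enough that every estimator can be validated by parameter recovery.

## The design being emulated

A nested mating design: 81 sires and 124 dams produce 141 full-sib
families; each sire serves one or two dams. The printed counts admit one
simple reconciliation, which the generator uses: 60 sires with two dams
and 21 with one (141 families), with 17 dams serving two sires (124
unique dams), which creates a small number of maternal half-sib links.
About 80 offspring per family are tagged (11,280 animals). Survival to
harvest is 79.84% (note that 9006/11,280 = 79.84% exactly; the
alternative tagging total of 12,800 sometimes quoted for this design is
arithmetically inconsistent with that percentage and is not used). Tag
retention is 88.84%, leaving ~8,001 identified survivors; per-trait
record counts are thinned to the harvest table of the study
(shell lengths at 6/18/24/30 months: 6,259/5,492/6,843/7,948 records;
total wet weight 7,993; foot color 7,913). Meat traits are measured by
dissection on a stratified subsample: 20–25 survivors from each of 30
families, 680 animals in total.

## Trait architecture

Continuous traits follow y = μ + gender + a + f + e per trait, with
additive values a having covariance A ⊗ G (A the pedigree numerator
relationship matrix, G the additive covariance across traits), an
optional full-sib common-environment effect f (defaults to zero
variance, matching the study's final models), and residuals e drawn
jointly across traits from E. Breeding values are generated by the
Mendelian-sampling recursion a_i = ½(a_s + a_d) + φ_i with
Var(φ_i) = d_i·G, d_i = ½ − ¼(F_s + F_d), which realizes A ⊗ G exactly
without forming A.

Default means, SDs and heritabilities are the study's harvest
descriptives and REML estimates: h² = 0.71/0.62/0.45/0.48 for shell
length at 6/18/24/30 months, 0.48 for total wet weight (Tww), 0.31 for
meat weight (Mw), 0.14 for meat yield (My); r_g(SL₃₀,Tww)=0.90,
r_g(Tww,Mw)=0.92, r_g(Tww,Fc)=−0.04, r_g(Tww,My)=−0.60. Residual
correlations are derived from the printed phenotypic correlations via
r_e = (r_p·σp_i·σp_j − r_g·σa_i·σa_j)/(σe_i·σe_j). Correlations never
printed (e.g. SL×Mw) are completed by chaining through Tww
(r(SL,Mw) := r(SL,Tww)·r(Tww,Mw)); survival is uncorrelated with
everything. The completed 9×9 correlation matrices are checked for
positive semi-definiteness (eigen-clipped only if needed; with the
chained completion no printed entry is altered).

Small fixed gender effects (female/male/unidentifiable, frequencies
4210:2983:898) are placed on the size and weight traits, re-centered to
zero mean under the sex frequencies, and their variance is carved out of
σp² before the σa²/σe² split — so the simulated phenotypic SDs and the
generating h² both match the study's tables exactly. Sex is assigned
i.i.d., not balanced within families.

**Foot color** is a 4-point ordinal score (1 = pale yellow, preferred;
4 = dark) generated from a liability: l = a + e with σa² chosen so the
standard sire–dam latent heritability 2(σs²+σd²)/(σs²+σd²+σf²+1) equals
0.46 (σs² = σd² = σa²/4 = 0.149), and σe² = 1 − σa²/2 so that a sire–dam
decomposition of the liability has residual variance exactly 1 — the
probit identification constraint. Cutpoints are solved in closed form so
the score distribution has mean 1.42 and SD 0.64 with mode at category
1; matching two moments leaves one degree of freedom, fixed by the tail
convention p₄ = p₃/2 (the observed category counts are not published),
giving category probabilities (0.646, 0.304, 0.033, 0.017).

A note on the latent-heritability formula: the conversion from sire+dam
variance to additive variance carries a factor 2 (σa² = 2(σs²+σd²));
the liability-scale phenotypic variance σs²+σd²+σf²+1 already contains
the Mendelian-sampling half of σa² inside the unit residual. With this
accounting the three shares — h², c² = σf²/(σs²+σd²+σf²+1), and the
environmental residual share (1−σs²−σd²)/(σs²+σd²+σf²+1) — sum to
exactly one. Only with the factor 2 are the study's two foot-color
results mutually consistent: a latent h² of 0.46 predicts a linear-score
h² of ≈0.30 after ordinal attenuation (Σφ(τ_k)² shrinkage of the
familial covariance), close to the reported 0.26, whereas without the
factor the prediction would be ≈0.6.

**Survival** is the binary threshold of its own liability (default
latent h² 0.15 — the study analyzes survival with a threshold model but
prints no estimate; 0.15 is typical for survival in aquaculture stocks)
at the quantile giving a 79.84% survival rate. Mortality hides all other
traits of the animal.

**Meat traits** have two modes. *Composite* (default): the yield ratio
My is simulated as a Gaussian trait (mean 0.51, SD 0.04, h² 0.14) and
meat weight is derived as Mw = My·Tww, so My = Mw/Tww holds identically.
The printed Mw moments (30.64/13.03) are mutually inconsistent with the
printed My and Tww moments under My = Mw/Tww on a random subsample
(they would require corr(My,Tww) ≈ −2.9), so composite mode prioritizes
the yield calibration and accepts Mw moments of ≈32/8. *Direct*: Mw and
My are each simulated as Gaussian traits at their published
heritabilities — the clean configuration for recovery experiments on a
ratio trait that otherwise has no closed-form heritability.

## Pedigree machinery

The tabular method builds dense A for desk-scale pedigrees; inbreeding
coefficients use the Meuwissen–Luo recursion; A⁻¹ is assembled sparsely
by Henderson's rules with inbreeding-aware Mendelian-sampling variances
(founders unrelated and non-inbred — the standard base-population
assumption for a first recorded generation). The same factorization
A = (I−T)⁻¹D(I−T)⁻ᵀ gives log|A| = Σ log d_i for the likelihood and
A·x by two triangular solves for the AI machinery. Pedigrees are
topologically sorted with a deterministic input-order tie-break;
parents named but never declared become founders.

## REML

Linear animal models (univariate through the 5-trait multivariate) are
fitted on Henderson's sparse mixed-model equations with record-level
missingness: each animal enters only the trait equations where it is
observed, and the residual covariance applies only to co-observed pairs
(assembled per missingness pattern). The restricted log-likelihood uses
−2lR = (n−p)log 2π + log|R| + log|G| + log|C| + y′Py, verified in the
tests against a direct dense evaluation to ~1e−9.

Optimization is average-information Newton ascent with step-halving.
The AI matrix is exact at any parameter value (it only needs MME solves
with the current factorization). The gradient's trace terms tr(P·V̇) are
computed exactly via dense inverses when the system is small (≤1200
observations) and otherwise by seeded Hutchinson probes (48 Rademacher
vectors; one extra MME solve per probe) — unbiased, deterministic given
the fit seed. Univariate fits take 5 EM-REML warm-up steps first (the
EM update is also used to assert likelihood monotonicity in the tests);
multivariate fits warm-start from the univariate components with
off-diagonals initialized from sample phenotypic correlations, which in
practice reaches the optimum in 5–15 AI iterations — a deliberate
substitute for multivariate EM warm-up, whose residual update under
record-level missingness is both awkward and slow. Convergence requires
the relative likelihood change below 1e−8 (1e−7 in probe mode) together
with small parameter changes; variances are pinned at 1e−8·σp² when they
hit the boundary and flagged; correlations are capped at |0.999|.
Standard errors of h², r_g and r_p come from the delta method on the
inverse AI matrix. The fits are exposed sklearn-style
(`AnimalModelREML(...).fit(data, pedigree)`) with a functional wrapper
`fit_reml`.

`profile_loglik` is a deliberately independent dense oracle (V built
from tabular A; ≤500 records) used by the tests to confirm that the
sparse path's optimum sits at the brute-force grid maximum.

## Threshold model

Foot color (and binary survival) are fitted with a Bayesian probit
sire–dam model via Gibbs sampling with latent-liability augmentation:
truncated-normal liability draws given the observed categories; then a
*blocked* multivariate-normal update of all location effects — mean,
gender, sire, dam and (optionally) family — from one small Cholesky
solve; then variance draws SS/χ²_{n−2} (flat priors on variances); then
Albert–Chib uniform updates of the interior cutpoints. τ₁ is anchored
at 0 with the mean left free; binary traits have no free cutpoint.
Defaults: chain 20,000, burn-in 5,000, thinning 10. Split-R̂ and an
initial-positive-sequence ESS are reported per parameter; R̂ > 1.1
flags (not fails) the fit.

Two estimation choices deviate from the obvious construction, both
forced by the design's information structure. First, single-site Gibbs
updates are useless here: family effects are collinear with sire+dam at
family resolution, and the blocked update improves the effective sample
size of h² by an order of magnitude. Second, the family variance σf² is
separated from the dam variance only by the 17 dam-sharing pairs, so its
likelihood is nearly flat; under a flat prior its posterior mean is
substantially positive even when the generating σf² = 0, dragging the
posterior-mean latent h² from 0.46 down to ≈0.36. A REML-style point
estimate would sit at the σf² = 0 boundary instead. The default model
therefore omits the family term (`include_family=False`) — mirroring
the emulated study's own finding that the component was negligible and
not retained — and recovers the generating latent h² without bias; the
term remains available for sensitivity analysis, with the caveat above.

The interior-cutpoint updates mix slowly (a known property of the
uniform conditional scheme); this affects τ₂/τ₃ precision but not the
variance ratios that define h², which is why the recovery targets use
moderate chains without harm.

## Pipeline and recovery scoring

`run_standard_suite` reproduces the study's model set on any phenotype
table + pedigree: descriptives; the 5-trait multivariate REML (shell
lengths + Tww); bivariates of Tww with foot color, meat weight and meat
yield; the linear foot-color model; the threshold foot-color model; and
the binary survival threshold model — assembling the conventional
report layout (h² on the diagonal, genetic correlations above,
phenotypic below). Stage failures mark the bundle partial without
aborting the rest. `recovery_study` loops simulate→fit→score and
reports truth, replicate mean/SD, bias and ±2SE coverage; because the
original farm data are not deposited, replicate recovery at the
published parameter values is the package's verification surface.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds;
simulation output is byte-identical across runs at a fixed seed, and
REML probe vectors and Gibbs chains are seeded. The test suite scales
replicate counts to stay desk-sized (e.g., 3–4 recovery replicates at
the full design; smaller designs for invariance checks);
`scripts/acceptance.py` re-runs the same computations at 10 replicates
(30 for the n=680 meat-yield target) with fresh seeds derived from its
`--seed`.

## What passing tests do and do not show

The generator draws multivariate-normal liabilities and residuals with
exactly the published variance structure, i.i.d. missingness and a
single environment. Real data add what the simulator omits: common
rearing environments before sea transfer (c² > 0), survivorship bias
correlated with growth, measurement error in dissection traits,
genotype-by-environment interaction, and non-normal residuals.
Parameter recovery here therefore validates the estimators and the
arithmetic, not the biology; estimates on real data inherit the upper-
bound caveats that apply to any animal model without a common-
environment term. Known limitations: no genomic relationships, no
multi-generation selection simulation, no multivariate threshold–linear
joint models, and the dense A builder is quadratic (the sparse inverse
is what scales).
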