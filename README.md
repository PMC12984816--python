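# abaqg — quantitative genetics for abalone breeding designs

`abaqg` is a Python toolkit for estimating genetic parameters in
single-generation aquaculture breeding studies, built around the design
used for Pacific abalone (*Haliotis discus hannai*): a nested mating
scheme (81 sires × 124 dams → 141 full-sib families, ~80 tagged
offspring each) phenotyped at harvest for staged shell lengths, total
wet weight, an ordinal foot-color score, survival, and dissection-based
meat traits on a 680-animal subsample. It is aimed at breeding-program
analysts who want pedigree-based heritabilities and genetic correlations
for growth and processing-quality traits, and at methodologists who
want a fully simulated testbed for such designs.

Three pieces work together:

- **Simulator** — generates the nested design and multitrait phenotypes
  with exact pedigree covariance (Mendelian-sampling recursion), a
  calibrated ordinal foot-color liability, heritable survival, and the
  study's missingness pattern, plus a sidecar with the generating truth.
- **Linear animal models** — y = μ + gender + a (+ f) + e with
  Var(a) = A ⊗ G, fitted by AI-REML on sparse mixed-model equations
  (univariate to 5-trait multivariate, record-level missingness),
  h² = σ̂a²/(σ̂a²+σ̂e²), r_g = Ĝ₁₂/√(Ĝ₁₁Ĝ₂₂), delta-method SEs from the
  average-information matrix.
- **Threshold model** — Bayesian probit sire–dam model for ordinal
  foot color and binary survival (liability augmentation, blocked Gibbs,
  Var(e) ≡ 1), reporting the latent-scale heritability
  h² = 2(σ̂s²+σ̂d²)/(σ̂s²+σ̂d²+σ̂f²+1) and c² = σ̂f²/(σ̂s²+σ̂d²+σ̂f²+1).

## Worked example

```python
from abaqg import DesignSpec, simulate_population, fit_reml, fit_threshold
from abaqg.genpar import se_delta
from abaqg.pipeline import attach_parentage, descriptive_stats

pop = simulate_population(DesignSpec(seed=2), seed=2)
print(descriptive_stats(pop.phenotypes).round(2))

fit = fit_reml(pop.phenotypes, pop.pedigree, traits=["SL_30"], seed=2)
print(f"h2(SL_30) = {fit.h2[0]:.2f} +/- {se_delta(fit, 'h2:SL_30'):.2f}")

data = attach_parentage(pop.phenotypes, pop.pedigree)
tfit = fit_threshold(data, response="Fc",
                     chain_length=4000, burn_in=1000, thin=3, seed=2)
print(f"latent h2(Fc) = {tfit.h2_latent[0]:.2f} +/- {tfit.h2_latent[1]:.2f}")
```

Output:

```
              N   mean     SD    min     max
trait
SL_6       6339  23.89   2.65  14.19   34.12
SL_18      5632  46.56   4.12  31.53   62.33
SL_24      6961  62.56   4.41  47.41   79.85
SL_30      8085  76.45   5.27  52.90   97.96
Tww        8135  62.88  14.28  10.55  116.32
Fc         8062   1.39   0.62   1.00    4.00
Mw          680  31.25   7.71   5.49   51.74
My          680   0.51   0.04   0.37    0.64
survival  11280   0.81   0.39   0.00    1.00
h2(SL_30) = 0.49 +/- 0.05
latent h2(Fc) = 0.48 +/- 0.06
```

One simulated harvest reproduces the target descriptives (shell length
at 30 months ~76.7 mm, foot-color score mean ~1.4 with category 1 the
mode, meat yield ~0.51 on the 680-animal dissection subsample). The
univariate REML fit recovers the generating h² of 0.48 for SL_30 within
its standard error, and the threshold model recovers the generating
latent foot-color heritability of 0.46; a linear model on the same 1–4
scores lands near 0.30 — the expected ordinal-scale attenuation.
Estimator classes (`AnimalModelREML`, `ThresholdSireDamModel`) expose
the same functionality sklearn-style with `fit()` and
trailing-underscore attributes.

There is also a CLI:

```sh
abaqg simulate --out sim/                 # pedigree.csv, phenotypes.csv, truth.json
abaqg fit --pedigree sim/pedigree.csv --phenotypes sim/phenotypes.csv \
          --models multi5,biv_mw,thresh_fc --out fits/
abaqg recover --replicates 20 --seed 7 --out recovery/
```

`fit` accepts any pedigree CSV (`id,sire,dam,sex`, unknown parents coded
0/NA/blank) and phenotype CSV with matching ids.

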