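# skewipm

Size-structured population analysis for annually censused perennial
plants: skew-normal growth kernels, integral projection models (IPMs)
with a discrete seedling stage, AICc model selection, life table
response experiments (LTREs), and parametric-bootstrap uncertainty.

## Who this is for

Plant demographers with the classic marked-individual data set — per
plant and year: size, survival, flowering status, flower count, plus
seedling quadrat counts — who want to ask where and when a population
grows (λ, λ_s), which vital rates control growth (elasticities), which
rates drove the observed differences among sites and years (LTRE), and
how certain any of it is (bias-corrected bootstrap intervals that
include model-selection uncertainty).

## The model

Plants of size x on [L, U] plus a first-year seedling class B project as

    n(y, t+1) = ∫ S(x) G(y, x) n(x, t) dx + G_s(y) S_s B(t)
    B(t+1)    = ∫ P_f(x) f_w(x) P_r n(x, t) dx

Growth G is a skew normal whose location ξ, scale ω, and shape α are
each linear in covariates and fitted jointly by maximum likelihood — so
size-dependent growth variance and shrinkage-driven skew are vital rates
in their own right, with their own sensitivities and LTRE contributions.
Kernels are discretized into 100 size classes (CDF differences at class
edges, columns renormalized so no growth mass is evicted), λ is the
dominant eigenvalue, λ_s comes from 5000-step stochastic simulation over
a site's annual kernels, and lifespan from projecting a 100-seedling
cohort to 99% mortality.  Every regression coefficient is perturbed by
10⁻⁵ on its link scale for sensitivities/elasticities; LTRE
contributions are (coefficient deviation from the across-cell mean) ×
sensitivity.  The bootstrap resamples, per vital rate, a model from the
95% AICc-weight confidence set and coefficients from its estimated
multivariate normal, 5000 times by default.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The package ships a synthetic study generator (3 sites × 3 annual
transitions, 200 marked plants and one seedling cohort per cell) with
known true vital rates, so the whole pipeline runs without field data:

```python
import skewipm as ski

params = ski.reference_params()
census = ski.generate_census(params, n_per_cell=200, seed=1)
seedlings = ski.generate_seedlings(params, census, n_quadrats=40, seed=2)

cfg = ski.PipelineConfig(seed=1, shifted_counts=True)
analysis = ski.DemographyAnalysis(cfg).fit(census, seedlings)

print(analysis.lambda_.round(3))        # deterministic lambda per site x year
print(analysis.lambda_s_.round(3))      # stochastic lambda per site
print("lifespan:", analysis.lifespan_, "years")
```

prints

```
       1      2      3
A  1.135  1.064  1.219
B  1.023  0.891  1.141
C  1.062  0.954  1.163
A    1.142
B    1.023
C    1.063
lifespan: 58 years
```

Site A grows in every transition (λ > 1, λ_s = 1.14), site B hovers at
replacement, and year 2 is the worst year everywhere — matching the
generating parameters, whose true λ ranges 0.87–1.20.  The dredge picks
site and year structure where the truth has it, e.g. the growth model:

```python
best = analysis.selected_["growth"]
print("growth terms:", best.terms_mu, best.terms_sigma, best.terms_nu)
# growth terms: ('size', 'site', 'year') ('size', 'site', 'size:site') ()
```

The LTRE attributes between-site differences in λ to vital rates —
here survival and mean growth favour site A at the expense of B:

```python
print(analysis.ltre_.per_rate_site.round(3).loc[["survival", "growth_mu", "flowering"]])
# site           A      B      C
# survival   0.138 -0.105 -0.033
# growth_mu  0.075 -0.059 -0.017
# flowering  0.042 -0.026 -0.016
```

`analysis.bootstrap(n_iter=...)` attaches bias-corrected 95% intervals
and significance flags to every output, including pairwise λ differences
among years and λ_s differences among sites.

A CLI mirrors the library:

```bash
skewipm simulate --out census.csv --seedlings-out seedlings.csv --seed 1
skewipm all --census census.csv --seedlings seedlings.csv --outdir report/
```

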