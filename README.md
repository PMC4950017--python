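# pedbias

**How much does nonrandom extra-pair paternity bias heritability estimates
from social pedigrees?**

In wild populations of socially monogamous birds, pedigrees are usually
assembled from observations of breeding pairs.  Extra-pair paternity (EPP)
puts wrong paternal links into that *social* pedigree: an extra-pair young
(EPY) is credited to its social father although an extra-pair male (EPM)
sired it.  If the studied trait itself influences who gains extra-pair
matings and who is cuckolded, the resulting pedigree errors are nonrandom,
and quantitative-genetic estimates can be distorted in ways the classical
random-error results do not cover.  `pedbias` is a toolkit for quantifying
that distortion, aimed at quantitative geneticists working with wild
pedigrees.

## What it computes

**Closed-form bias.**  For father–offspring regression on the social
pedigree, the expected estimate for a trait of true heritability h² is

```
E[ĥ²] = h² · [ 1 + δ̄·γ·(β_e|z − 1) + β_δ|z·Δ ]
```

where δ̄ is the EPP rate, γ the phenotypic variance of cuckolded males
relative to all males, β_e|z the regression of EPM phenotype on the
cuckolded father's phenotype, β_δ|z the regression of the cuckoldry
indicator on father phenotype, and Δ the mean EPM-minus-father phenotype
gap.  Random misassignment reduces this to `h²·(1 − δ̄)`.

**Empirically structured simulation.**  A permutation engine draws EP events
conditional on a social pedigree under a logit-linear mating model,
`P(i cuckolds j) ∝ exp(λ·d_ij + β·f(z_i, z_j))`, with five scenario score
functions (males with large traits gain EPP; suffer less cuckoldry; both;
males cuckold the most dissimilar males; the most similar males) and
strength β interpretable as a standardized selection gradient.  Traits of
stated heritability are gene-dropped down the pedigree, EPY breeding values
are re-derived after reassignment, and heritability is estimated on both the
social and the simulated genetic pedigree by father–offspring regression and
by a REML animal model (`h² = V_A/(V_A+V_R)`).

**Synthetic study population.**  A generator emulates the published shape of
a six-cohort great tit study (960 founders, 593 adult-recruit offspring,
12.5% EPY, spatially clustered nests, EPY clustered within broods), so the
whole pipeline runs without any field data.

## Worked example

```python
import pedbias as pb

pop = pb.generate_pedigree(seed=1)            # social + reference genetic pedigree
sc  = pb.EppScenario("iii", beta=0.8,          # large males gain EPP and keep paternity
                     lam=pop.config.lambda_ref)

traits = pb.simulate_trait(pop.social, "social", h2=0.5, seed=1)
genetic, traits2, events = pb.permute_paternity(
    pop.social, traits, sc, pop.n_events_per_year, pop.p_additional, seed=2)

stats = pb.compute_bias_statistics(pop.social, genetic, traits2)
est_g = pb.h2_animal_model_reml(genetic, "genetic", traits2)
est_s = pb.h2_animal_model_reml(pop.social, "social", traits2)
print(f"delta_bar={stats.delta_bar:.3f}  Delta={stats.delta_cap:.2f}")
print(f"h2 genetic={est_g.h2_hat:.3f}  h2 social={est_s.h2_hat:.3f}")
```

prints

```
delta_bar=0.128  Delta=1.76
h2 genetic=0.506  h2 social=0.440
```

With 12.8% of offspring reassigned and extra-pair males ~1.8 phenotypic SD
above the fathers they cuckold, the correct (genetic-pedigree) animal model
recovers the simulated h² = 0.5, while the social pedigree underestimates it
by ~13% — a single-replicate view of the scenario-iii bias.

The same stages are exposed as a CLI (`pedbias generate`, `simulate-trait`,
`permute`, `estimate`, `grid`, `summarize`); `pedbias grid --reps 100`
runs the full h² × scenario × β factorial and writes per-replicate results
and per-cell summaries as CSV.

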