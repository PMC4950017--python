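# Methods

## The problem

In wild populations of socially monogamous birds, pedigrees are usually built
from observations of breeding pairs.  Extra-pair paternity (EPP) makes some of
those paternal links wrong: an extra-pair young (EPY) is attributed to its
social father although an extra-pair male (EPM) sired it.  Random paternal
misassignment is known to depress heritability estimates only mildly (by at
most the EPP rate for father–offspring regression).  The question this package
addresses is what happens when the misassignment is *nonrandom* — when the
studied trait itself influences who gains and who loses paternity.

## Analytical model

For father–offspring regression, the expected heritability estimate from the
social pedigree is

    E[h2_hat] = h2 * [ 1 + delta_bar * gamma * (beta_e|z - 1)
                         + beta_delta|z * Delta ]

with, per offspring record:

| symbol       | meaning                                                            |
|--------------|--------------------------------------------------------------------|
| `delta_bar`  | EPP rate (probability the genetic sire differs from the social one)|
| `gamma`      | var(social-father phenotype among EPY records) / var(over all records) |
| `beta_e|z`   | OLS slope of EPM phenotype on the cuckolded father's phenotype     |
| `beta_delta|z` | OLS slope of the 0/1 cuckoldry indicator on father phenotype     |
| `Delta`      | mean (EPM phenotype − cuckolded father's phenotype)                |

This identity is exact at population moments (it follows from decomposing
cov(z, z(1−δ) + δe) into conditional moments; `tests/test_acceptance.py`
verifies it against full Monte Carlo).  The grouping of terms is the unique
one that reproduces its three special cases: random EPP
(`gamma=1, beta_e|z=0, beta_delta|z=0` → `h2·(1−delta_bar)`), like-for-like
cuckoldry (`gamma=0, Delta=0` → `h2`, unbiased), and maximal-gap cuckoldry
(`gamma=0, beta_delta|z=−1, Delta=1` → `0`).  When the social fathers of EPY
show no phenotypic variance, `gamma = 0` and `beta_e|z` is undefined; its
whole term then vanishes, which the code encodes by reporting `beta_e_z` as
absent.

## Simulation pipeline

One replicate of the permutation experiment:

1. **Gene drop** (`genedrop`).  A unit-variance trait of heritability h2 is
   simulated down the social pedigree: founders draw breeding values
   a ~ N(0, h2); a non-founder takes the midparent mean plus a Mendelian
   deviation N(0, h2/2); an unknown parent's half-share is replaced by an
   independent N(0, h2/4) draw (a phantom unrelated founder), keeping
   var(a) = h2.  Phenotype z = a + eps with eps ~ N(0, 1−h2).  The Mendelian
   variance omits the inbreeding correction (the analytical model assumes
   none; synthetic pedigrees carry essentially no inbreeding); an optional
   flag restores the 1 − (F_s+F_d)/2 factor.
2. **EPP permutation** (`permutation`).  Cohorts are processed
   chronologically.  In year t the probability that male i sires EPY in the
   brood of social father j is proportional to
   `exp(lambda*d_ij + beta*f(z_i, z_j))`, normalized over ordered pairs
   (i ≠ j); the five scenario score functions f are `z_i`, `−z_j`,
   `z_i − z_j`, `|z_i − z_j|`, `−|z_i − z_j|`.  The per-year number of events
   equals the count observed in the reference genetic pedigree; fathers are
   drawn *without replacement* (one EP event per social father per run),
   EPMs with replacement.  Per event one brood member is always reassigned
   and each remaining one follows independently with probability
   `p_additional`.  Reassigned offspring (and, transitively, their
   descendants) have their breeding values re-derived — retaining every
   Mendelian, phantom-parent and environmental draw — before later years are
   drawn, so trait-dependent mating in later cohorts sees updated phenotypes.
   The candidate EPM pool of year t is every male at least one year older
   than the cohort, the same pool the reference generator uses; this keeps
   the β = 0 permutation distribution consistent with the reference pedigree
   (the structure-preservation tests depend on that consistency).
3. **Estimation** (`heritability`).  Both pedigree versions are fitted.
   Father–offspring regression: `2·cov(z, o)/var(z)` over pair records.
   Animal model: y = mu + a + e with cov(a) = V_A·A, fitted by REML in the
   eigenbasis of A, profiled to a one-dimensional bounded search over
   h2 ∈ [0, 1−1e−6] (xatol 1e−10); V_A ≥ 0 is enforced by the parameter
   boundary, approximate SEs come from the numerical curvature of the profile
   likelihood, and tiny negative eigenvalues of A are clamped to zero.  REML
   is the package's estimator throughout: it is deterministic, two orders of
   magnitude faster than MCMC at these sample sizes, and agrees closely with
   posterior means for well-identified variance components.  The A matrix is
   built by the exact recursive tabular method (inbreeding handled exactly),
   and the social pedigree's eigendecomposition is cached across replicates.

## The synthetic study population

`synthetic.generate_pedigree` emulates the *shape* of a multi-year nest-box
study of a resident passerine: by default 960 founders and 593 adult-recruit
offspring born over the six cohorts 2004–2009, a 12.5% EPY rate, nests on a
100 m grid with 10 m jitter, and EPY clustered within broods
(`p_additional = 0.5`).  Founders enter over several cohorts; recruits breed
in later cohorts, so multi-generation links exist.  The reference genetic
pedigree is produced by trait-independent, distance-weighted EP events drawn
until each cohort reaches its share of the target EPY count; the realized
per-year event counts are what the permutation engine conditions on.

Parameters the source study does not print are explicit knobs with defaults
chosen once: recruited brood sizes follow a zero-truncated Poisson with mean
1.6 (recruitment to the adult population, not clutch size); `p_additional`
is 0.5; the distance coefficient defaults to `lambda = −0.011 m⁻¹`,
calibrated so that the median EPM–father distance under β = 0 is about two
nest spacings (≈ 200 m), a typical scale for extra-pair matings in nest-box
studies.  `lambda` is a per-metre log-linear rate, so only the ratio of decay
length to nest spacing matters.

What the generator does *not* emulate: survival and dispersal (males remain
candidates in all later cohorts), immigration structure, clutch-size
demography, assortative pairing, and any real spatial habitat structure.
Passing tests therefore show that the estimators and the bias mechanics
behave correctly on a pedigree of realistic size and topology — not that the
defaults reproduce any particular wild population beyond the counts and the
EPY rate they were set to.

## Experiment sizes

The factorial experiment crosses h2 ∈ {0.1, 0.3, 0.5, 0.7}, scenarios i–v and
β ∈ {0, 0.1, 0.2, 0.4, 0.8, 1.6}, 100 replicates per cell by default
(`--reps` rescales).  The acceptance recomputation uses 50 REML replicates
per headline cell, 100 permutation-only replicates for the phenotype-gap
statistic, 200 replicates per cell for the closed-form-versus-Monte-Carlo
check, and runs the full 120-cell grid at 10 replicates on a reduced
population (240 founders, 150 offspring, same shape); these sizes give
Monte Carlo SEs comfortably inside the comparison bands while keeping a full
run in the minutes range.

## Numerical and design notes

- Topological order is the (stable) cohort sort; the validator enforces
  strict parent-before-offspring cohorts, which also rules out cycles — the
  explicit cycle search only runs to name a cycle when that check fails.
- Weight matrices are exponent-shifted before exponentiation, so scenario
  scores are overflow-safe; an all-zero weight mass raises an error
  suggesting rescaling β or λ.
- Sequential event drawing renormalizes after deleting the drawn father's
  column; ties and degenerate single-father years behave exactly
  (enumeration-tested at three males).
- `structure_summary` counts full sibs as pairs sharing a known dam and a
  known sire; half-sib pairs share the one link without being known full
  sibs.  The cuckoldry counts are reported absent (not zero) when the
  genetic sire column is missing entirely.
- Proportional bias uses the genetic-pedigree estimate as the denominator;
  the variant normalized by the input h2 is also emitted
  (`prop_diff_true`).
- The 15-cell closed-form-versus-Monte-Carlo family is tested at a Šidák
  familywise band (z ≈ 3.2) rather than 2 SE per cell, which would falsely
  reject in about half of seed draws even for an exact identity.

## Known limitations

- Under strongly dissimilarity-seeking cuckoldry (scenario iv at β = 1.6)
  the realized variance ratio reaches γ ≈ 2 with β_e|z ≈ −0.8, and the
  social-pedigree animal model underestimates a h2 = 0.7 trait by ≈ 24%
  proportionally.  This magnitude is sensitive to the distance-decay
  calibration and to the breadth of the candidate-male pool: a stronger
  spatial constraint or a narrower pool damps the extremity of
  dissimilar-male choice and lowers the figure toward ≈ 20%.
- The MCMC animal model is not implemented; REML is the sole variance-
  component estimator.
- The theory treats regression on the social father only; maternal links are
  assumed correct throughout.
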