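# Methods

## The social animal model

Traits recorded on group-housed pigs are modelled with two genetic effects
per animal: a direct effect (DGE) on the animal's own record and an indirect
(social) effect (IGE) exerted on every pen mate's record.  For traits
*t* = 1..3 (ADG, BF, FCR) the record of animal *i* in pen *p* and litter *l*
is

    y_it = x_i' b_t + p_pt + l_lt + d_it + sum_{j in pen(i), j != i} s_jt + e_it .

Pen, litter and residual effects are multivariate normal across traits with
3x3 covariance matrices P0, L0, R0; the stacked direct and indirect effects
follow MVN(0, G0 (x) A) with a 6x6 genetic covariance G0 ordered
(d_ADG, d_BF, d_FCR, s_ADG, s_BF, s_FCR) and A the pedigree numerator
relationship matrix.  The classical animal model (AM) is the special case
with a single additive effect per trait (3x3 genetic covariance).

The total breeding value of an animal in a pen of n is TBV = d + (n-1) s;
its variance sigma2_d + 2(n-1) sigma_ds + (n-1)^2 sigma2_s measures the
heritable impact of selection on the population mean.  The phenotypic
variance convention used for all ratios is

    sigma2_Phe = sigma2_d + (n-1) sigma2_s + sigma2_pen + sigma2_litter + sigma2_e ,

the variance of one record among n-1 unrelated pen mates (an animal's own
direct-indirect covariance is excluded because it does not affect itself).

## Reference parameters and trait scales

`duroc_reference_components()` encodes the posterior-mean parameter set
estimated for a Duroc fattening line: direct heritabilities 0.31 / 0.39 /
0.25, phenotypic variances 0.75 / 11.84 / 4.44, indirect genetic variances
4e-3 / 0.04 / 0.03, and the full 6x6 genetic correlation structure (e.g.
r(d_ADG, d_BF) = 0.52, r(s_ADG, d_FCR) = 0.70, r(d,s) within trait -0.29 /
-0.09 / -0.17).  This matrix is jointly positive definite (smallest
eigenvalue of the correlation matrix 0.022), so it is usable as a generating
truth without repair.

These variances are on an analysis scale in which ADG and FCR are ten times
their kg units (raw phenotypic SDs of roughly 0.09 kg/d and 0.24 kg/kg imply
variances one hundredth of the quoted ones; BF in mm is unscaled).  The
package therefore simulates, evaluates and ranks on the analysis scale, and
converts to real units only when reporting: generation means and response
slopes for ADG and FCR multiply deviations by 0.1 and add the population
means (0.82 kg/d, 18.19 mm, 2.77 kg/kg), so responses and profits are on the
scale a producer reads.  `BreedingConfig.trait_scale` exposes the divisors.

Pen and litter variance fractions are not published; both default to 5% of
phenotypic variance per trait, a typical magnitude for common-environment
effects in fattening data, and the residual absorbs the remainder so
sigma2_Phe is preserved exactly.  Cross-trait pen/litter/residual
covariances default to zero.

## Synthetic data

`synth` generates datasets with the recorded population's structure: 1144
animals in 97 pens of 7-15 across 10 batches, litters nested in dams
(litter sizes 4-12), end-age covariate N(177, 9^2).  Genetic effects are
sampled by pedigree recursion under the infinitesimal model: founders from
G0, descendants as mid-parent plus a Mendelian deviation with covariance
G0 * (0.5 - 0.25 (F_s + F_d)).  Every simulated record stores its components,
so y reconstructs exactly from systematic + pen + litter + direct + received
social + residual parts (asserted to 1e-12).

What the generator does not emulate: feeding-station measurement error,
missing records, selection history in the base population, heterogeneous
variances across batches.  Passing tests therefore demonstrate correctness
of the machinery under the stated model, not robustness to those real-data
features.

## Mixed-model equations and BLUP

`mme` assembles Henderson's equations with R0^-1 weighting across traits;
identical per-trait designs let the data part be written R0^-1 (x) W'W.
Random blocks are augmented with P0^-1 (x) I, L0^-1 (x) I and G0^-1 (x) A^-1
(joint over d and s under the SAM).  A^-1 comes from Henderson's rules with
Meuwissen-Luo inbreeding, exact for inbred pedigrees and linear-time, so the
cumulative pedigrees of a five-generation run (tens of thousands of animals)
are cheap.  Every pedigree animal gets equations, which propagates
predictions to unrecorded candidates (a childless unrecorded offspring gets
the parent average, verified against the equations).

Fixed-effect rank deficiency is resolved by zeroing the first level of each
factor; when no factor is fitted an explicit intercept is added.  Solvers:
sparse LU for systems up to ~15k equations, Jacobi-preconditioned conjugate
gradients beyond (tolerance 1e-8 on the relative residual); the two agree to
1e-6 on test systems.  Direct factorization is avoided on large SAM systems
because the pen cliques of the social design fill in badly.

## REML

`reml` fits the AM by EM-REML.  Exact EM (dense inverse of the coefficient
matrix) is used up to 3000 equations; its restricted likelihood is
non-decreasing at every step (asserted) and its fixed point matches the
closed-form ANOVA estimator on balanced one-way data to 1e-6.  Larger
systems switch to Hutchinson stochastic trace estimation: each EM step does
one sparse LU factorization plus twelve Rademacher probe solves, making the
per-step cost nearly size-independent at the price of Monte Carlo noise in
the updates (monotonicity is then only approximate; the estimate still lands
within ~10% of the closed form on a 4000-record check).  Restricted
log-likelihoods are computed through the MME factorization identity and are
invariant to the constraint choice.  Estimated matrices are kept positive
definite by eigenvalue flooring at 1e-8 x trace, flagged when applied.
Within the breeding-program pipeline REML starts from the collapsed
generating components and runs at most 25 iterations per generation.

## Gibbs sampling

`gibbs` samples the SAM or AM posterior under flat priors on systematic
effects and all covariance matrices.  Location effects are updated
single-site from their normal full conditionals (a numba kernel maintaining
the residual vector); each covariance matrix is then drawn from its
inverted-Wishart full conditional with degrees of freedom
(levels - dimension - 1), the limiting form of the flat prior.  The sampler
refuses factors with too few levels for a proper conditional.  Chains are
bit-reproducible given the seed.  Checks: the one-dimensional conditional
matches the scaled inverse chi-square closed form (Kolmogorov distance
< 0.05 at 5000 draws), and with fixed variance components the chain's mean
location effects converge to the BLUP solution.

Desk-scale defaults are 50k iterations / 5k burn-in / thinning 10; the
published protocol (1M / 100k / 10) is available through `GibbsConfig`.
Single-site updates mix slowly for the weakly identified direct/indirect
split, so short chains on the 1144-animal design need a burn-in of the order
of 10-20k iterations before the heritability ratios stabilise; the recovery
test uses 30k-iteration chains with a 12k burn-in.

DIC uses the conditional-deviance convention: D is the multivariate-normal
residual deviance given the location effects, DIC = Dbar + pD with
pD = Dbar - D at the posterior means of residuals and R0.

## The breeding program

`nucleus` simulates a closed nucleus of 400 sows and 20 boars (any width is
configurable): four batches per generation, each sow farrowing in every
batch, litter sizes Poisson(6.25) truncated at 1, sexes Bernoulli(1/2),
pens of eight filled in litter processing order within batch (the last
partial pen keeps its actual size for phenotype generation and is excluded
from accuracy summaries; fewer than a quarter of pens end single-litter).
Records accrue in all four batches; the genetic evaluation at generation t
uses the candidate batches (first two) of generations <= t plus the later
batches of generations < t.  Evaluation fits ADG and BF only — FCR is
recorded but never evaluated — with batch and realized litter size as
systematic effects.  Selection takes the best 200 females per candidate
batch and the best male of each sire family (ties broken by id); five
generations are run and responses are OLS slopes of candidate-cohort means
on generation number 1..5.

Matings avoid pairs sharing any ancestor within two generations (a shared
parent counts).  The balanced assignment (each boar serving n_sows/n_boars
sows) is found by bipartite max-flow on the compatibility graph.  In
reduced-width nuclei the constraint can become structurally unsatisfiable
after a few generations of family concentration; the simulator then relaxes
in logged tiers — larger quotas, unbalanced loads, and finally the
least-related compatible boar for the blocked sows — rather than aborting
the replicate.  `make_matings(strict=True)` preserves the hard-failure
contract.

## Economic index and profit

The index combines predicted effects with percentage weights at two levels,
traits (ADG vs BF, BF negative) and genetic effects (DGE vs IGE, the IGE
term multiplied by the seven pen mates it is expressed in).  Each trait's
genetic aggregate is divided by the trait's total-breeding-value SD before
the weights apply, so a 50/50 setting means equal selection emphasis rather
than equal raw units: raw analysis-scale predictions would let BF dominate
ADG by a factor ~4.5 in SD terms, which reproduces the all-weight-on-BF
column of the published response grid at every trait-weight setting and is
incompatible with the published sign change of the ADG response across the
grid.  Standardization uses the generating components of the replicate (the
same quantity under SAM and collapsed AM evaluation), and applies equally to
true and predicted index values; `standardize_index=False` restores the raw
formula.

Profit per pig: B = FBW*P_BW - (P_pl + FCR*(FBW-IBW)*P_fd +
P_fx*(FBW-IBW)/ADG) - penalty(BF), with FBW = 110 kg, IBW = 20 kg,
P_BW = 1.164 EUR/kg, P_pl = 35 EUR, P_fd = 0.252 EUR/kg, P_fx = 0.09 EUR/d.
Markets: B1 unconstrained; B2 penalised outside 6-10 mm BF; B3 outside
10-20 mm.  The published penalty rate (0.012 EUR per mm outside the band)
is interpreted as a price reduction per kg of final body weight — 1.32
EUR/pig/mm — because a flat per-pig rate cannot produce profit responses of
the published order (EUR-scale gaps between B2 and B1 against mm-scale BF
responses imply an effective rate near 1.2 EUR/mm).  Distance is measured
to the nearest band edge; a flat-rate variant remains available
(`per_kg_penalty=False`).

## Uncertainty propagation

Responses are computed one replicate per variance-component draw, so the
replicate slopes sample the posterior distribution of the response; the
summaries report posterior mean, SD and the P(>0) tail flags at 0.95 (0.9
optionally for FCR).  When a file of posterior draws is not supplied,
`sample_draws` emulates posterior spread by Wishart-resampling each matrix
around the reference values (relative SD ~15%); real draws from a Gibbs run
can be written and read back losslessly (12 significant digits) through the
draws file format.

## Problem sizes used in the shipped checks

The acceptance script runs the nucleus at half width (200 sows / 20 boars,
pens of 8, five generations, 20 replicates per scenario), which preserves
the selection fractions (16% of females; best male per sire family), family
sizes (20 sows per boar) and records-per-candidate of the full program
while keeping a four-scenario study within a desk-scale compute budget; the
width affects mainly the replicate-to-replicate spread, which averaging over
20 replicates absorbs.  Test-suite simulation checks use 3-5 replicates with bands set by
the published posterior SDs, the REML-BLUP check runs a 48-sow, 3-generation
program, and Gibbs recovery uses three 30k-iteration chains on fresh
1144-animal datasets.

## Known limitations

- Single-site Gibbs mixing is slow for the d/s split; published-scale chains
  (1M iterations) are supported but take hours.
- Stochastic-trace EM-REML trades exact monotonicity for scalability above
  3000 equations.
- The economic index standardization and the weight-scaled BF penalty are
  reconstructions from the published response tables (the printed formulas
  are ambiguous on both points); both have raw/flat variants.
- No overlapping generations, culling on phenotype, or inbreeding management
  beyond the grandparent rule.
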