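# Methods

## Background and scope

`haploci` analyses brood counts from crossing experiments in a haplodiploid
host (the spider mite *Tetranychus urticae*) infected with a
CI-inducing *Wolbachia*. In haplodiploids, unfertilized eggs develop into
haploid males and fertilized eggs into diploid females. Cytoplasmic
incompatibility (CI) — the embryonic defect induced when sperm from an
infected male fertilizes an uninfected egg — therefore has two visible
phenotypes: affected fertilized eggs may die (female-mortality CI, FM-CI)
or may lose the paternal genome and develop into viable haploid males
(male-development CI, MD-CI). The package covers four analyses over such
data:

1. estimation of CI strength and phenotype per cross via Bayesian binomial
   models and corrected indexes;
2. attribution of the variation to male genotype, female genotype and
   their interaction via WAIC model comparison and finite-population
   variance decomposition;
3. inference of the Mendelian architecture of a maternal modifier of the
   CI phenotype from F2 backcross broods via an ordered binomial mixture;
4. a generative simulator of both experiments with known ground truth,
   used for all recovery testing.

## Responses and corrected indexes

Each brood (one replicate cross) is scored as eggs, adult females and
adult males. Three binomial responses are derived:

- `F` — adult females / eggs;
- `MD` — adult males / eggs;
- `FM` — failed eggs / (eggs − adult males).

Raw proportions confound CI with nuclear and temporal effects, so each
incompatible cross (uninfected ♀ × infected ♂) is paired with the
compatible control (uninfected ♀ × uninfected ♂) of the *same* genotype
pair, and corrected indexes are computed from the model-estimated
proportions:

    CI_corr = 1 − F_obs / F_c
    MD_corr = (MD_obs − MD_c) / (1 − MD_c)
    FM_corr = (FM_obs (1 − MD_corr) − FM_c) / (1 − FM_c)

All three are computed per posterior draw and summarized afterwards (mean
and 0.09/0.50/0.91 percentiles); computing them from posterior summaries
would understate uncertainty in the ratios. Draws from the three response
models are coupled positionally (the MD_corr draw enters the FM_corr
formula at the same sample index); absent a joint model this positional
coupling is the only coherent way to propagate MD_corr into FM_corr.
Values below 0 are legal and deliberately not clipped — a negative
CI_corr says the incompatible cross out-produced its control.

## The binomial models

Every response is modelled as `numerator ~ Binomial(denominator, p)` with

    logit(p) = inf * mgeno * fgeno + (1 | day)

where `inf` is the male infection state, `mgeno`/`fgeno` the parental
genotypes (treatment coding, alphabetical first level as reference), `*`
denotes main effects plus all interactions, and day cohorts enter as
zero-mean random intercepts with an estimated scale. Rows with a zero
denominator for the modelled response carry no likelihood and are dropped
per model (an all-male brood leaves FM undefined but still informs F and
MD). Priors are weakly regularizing on the logit scale: coefficients
N(0, 1.5), intercept N(0, 3), day-intercept scale half-N(0, 1). The
inheritance-experiment fits omit day intercepts (single-cohort design).

### Sampling

Posterior sampling is Hamiltonian Monte Carlo written for this model
family, using the analytic gradient of the log posterior:

- the chain starts at the conditional posterior mode (L-BFGS), uses the
  mode's Hessian (central differences of the analytic gradient) as a
  constant mass matrix, draws jittered trajectory lengths of 8–32
  leapfrog steps, and adapts its step size by dual averaging during
  warmup (target acceptance 0.8);
- the day-intercept scale is *not* part of the HMC block. With centered
  day intercepts the joint density is unbounded as σ_day → 0, so a joint
  mode does not exist and a constant-metric HMC step is unreliable there;
  log σ_day is instead updated between trajectories by univariate slice
  sampling from its exact conditional given the intercepts. This mixes
  cleanly in both regimes (strong day structure and none at all);
- defaults are 2 independent chains × 5 000 iterations with 1 000 warmup.
  Retained draws are thinned to ≈4 000 total.

Convergence is checked per parameter with the rank-normalized split R̂
and effective sample size (via `arviz`); a fit is flagged when any
parameter has R̂ ≥ 1.01 or ESS < 400. Pointwise log-likelihoods (for
WAIC) are evaluated on the retained draws, including binomial constants.

Predictions per cross type are population-level: the inverse-logit of the
fixed-effect linear predictor, excluding day intercepts, so all crosses
are compared on an average day. Whether to marginalize over day effects
instead was an open choice; exclusion keeps the index ratios free of
day-effect noise and is the conventional reading of "controlling for
temporal effects".

## Model comparison and variance decomposition

Four fixed-effect structures are compared per response — `inf`,
`inf*mgeno`, `inf*fgeno`, `inf*mgeno*fgeno`, all with day intercepts —
chosen as the natural nested set that always retains the male infection
effect. WAIC is computed from the pointwise log-likelihood matrix:

    lppd = Σ_i log mean_s exp(ll_si)        (log-sum-exp)
    p_waic = Σ_i var_s(ll_si)               (ddof-1 sample variance)
    waic = −2 (lppd − p_waic)

with a standard error from the pointwise contributions and a paired
standard error for differences to the best model. Lower is better.

The relative impact of model terms is quantified by the finite-population
standard deviation of each term's realized per-level effects: per draw,
the term's coefficients with the treatment-coding reference level included
as 0, centered, SD with a J−1 denominator (J = number of levels, so a
two-level term with effects {0, c} scores |c|/√2). The day group uses the
sampled day intercepts. This is the standard ANOVA-style convention for
comparing "how much each factor moves the linear predictor" across
factors with different numbers of levels; the exact convention was an
open design choice and is fixed here as stated.

## The segregation mixture

In the backcross design (heterozygous F1 ♀ × modifier-line ♂), each F2
female is homozygous for a recessive modifier at one locus with
probability ½; with k unlinked loci all required, the expected fraction
of modifier-expressing females is 0.5^k. The MD counts of incompatible
F2 broods are modelled as an ordered mixture of two binomials,

    md_num_i ~ w Bin(md_den_i, p_hi) + (1 − w) Bin(md_den_i, p_lo),

with p_hi parameterized as p_lo plus a positive logit-scale increment, so
the ordering holds in every draw by construction and w always denotes the
high-MD component (label switching is impossible). Priors: w uniform on
[0, 1]; base logit and log-increment N(0, 1.5). The three-parameter
posterior is sampled with the `emcee` ensemble sampler (16 walkers, same
chain/iteration defaults), with the same R̂/ESS diagnostics.

The monogenic report gives the posterior summary of w, whether 0.5 lies
in the 0.09–0.91 interval, and the posterior mass within a band of each
candidate 0.5^k.

**Identifiability.** w is only interpretable when the two components
separate. If every brood shares one MD level, the components collapse
onto that level and w becomes diffuse (approaching its uniform prior)
rather than concentrating at 0 — the fit then reports "no separated
components", not "zero weight". Data with identical MD in every brood are
flagged non-identifiable and the report declines to rank hypotheses. The
mixture is fitted to incompatible broods only, separately by maternal
origin; MD-CI is not expressed in compatible crosses, so mixing classes
would dilute the signal.

## The generative simulator

One brood is simulated as a chain of binomial thinnings: eggs are drawn
from a negative binomial (mean `eggs_mean`, default 80 for 5-female
diallel discs and 40 for single-female inheritance broods; dispersion 20
— replicate totals in such assays are overdispersed relative to Poisson);
each egg is fertilized with probability `fert` (default 0.9, the high
fertilization typical of mated spider-mite females); unfertilized eggs
are candidate males; in incompatible crosses each fertilized egg is
CI-affected with probability θ, and an affected egg becomes a candidate
male with probability φ (MD-CI) or dies (FM-CI); unaffected fertilized
eggs are candidate females; every candidate survives to adulthood with
probability 1 − `base_mort` (default 0.05), identically for both sexes.
Rescue crosses (infected ♀) behave as compatible. θ and φ can vary per
(male, female) genotype pair, which is how male-driven CI and
male × female interactions are generated. Day cohorts share a logit-scale
normal effect (SD `day_sd`, default 0.3) applied to fertilization and
survival, matching the role of the day intercepts in the models.

In the ideal limit (no baseline mortality, large broods) the expected
proportions give F_obs = f(1−θ), MD_obs = (1−f) + fθφ,
FM_obs = θ(1−φ)/(1−θφ) against F_c = f, MD_c = 1−f, FM_c = 0; substituting
into the index formulas cancels the fertilization rate f and yields

    CI_corr = θ,   MD_corr = θφ,   FM_corr = θ(1−φ),

so CI_corr = MD_corr + FM_corr exactly. `closed_form_indexes` exposes this
limit and anchors the recovery tests; with `base_mort > 0` the MD and FM
indexes acquire an O(base_mort) bias, which is why exactness is asserted
only in the ideal limit.

The inheritance simulator generates parental, F1 and F2 single-female
broods with pedigree annotations. Each F2 female is homozygous at each of
`k_loci` independently with probability ½ and expresses `phi_high` only if
homozygous at all loci (threshold epistasis), else `phi_low` — the minimal
family containing both the monogenic and the polygenic hypothesis. Both
reciprocal F1 origins are simulated and are statistically identical here,
since the modifier is nuclear and both F1s are heterozygous; any
real-data asymmetry between origins (e.g. cytoplasmic effects) is outside
this generative model.

### What the simulator does not emulate

No within-host *Wolbachia* density dynamics, no imperfect maternal
transmission, no linkage between modifier loci, no brood-level
overdispersion beyond the day effects, and no egg-count differences
between compatibility classes. Passing recovery tests therefore shows the
*estimation machinery* is correct under the stated generative assumptions,
not that real mite data satisfy those assumptions.

## Numerical choices and degenerate inputs

- Records with `eggs = 0` are kept in files but excluded from every
  likelihood (zero-draw binomial rows are undefined).
- `ci_corr` raises if any compatible-cross F draw is exactly 0, `md_corr`
  if any MD_c draw is 1, `fm_corr` if any FM_c draw is 1 — these signal a
  degenerate control cross rather than being silently propagated.
- All-zero or all-success strata are legal in fits; the priors regularize
  the corresponding logits.
- The problem sizes in the test-suite are scaled-down versions of the
  study design (e.g. single- to three-genotype diallels, 1 200–4 000
  MCMC iterations) chosen so the full suite completes in minutes while
  leaving the assertions' tolerances meaningful; the acceptance script
  uses 10 replicate simulations of the 30-brood F2 design.
- Seeds: every simulation and every sampler run is reproducible from an
  integer seed; chains derive per-chain generators from (seed, chain).

## Known limitations

- The sampler is specialized to the model families shipped here
  (binomial-logit GLMs with at most one random-intercept block, and the
  two-component mixture); it is not a general-purpose PPL.
- WAIC is the only predictive criterion (no LOO-CV, Bayes factors or
  stacking), mirroring the analysis this package reproduces.
- The mixture uses plain binomial components; extra-binomial variation
  within phenotype classes would inflate the apparent separation of
  components.
- The finite-population SD convention (reference level as 0, J−1
  denominator) is one of several in use; comparisons across packages
  should check conventions before comparing magnitudes.
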