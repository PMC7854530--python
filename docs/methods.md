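# Methods

## Scope and data model

`nhnet` analyses Nursing Home Compare (NHC) style open tables keyed by
"Federal Provider Number" at a sequence of semi-annual processing
dates.  Facilities are placed into hospital referral regions (HRRs)
through a ZIP→HRR crosswalk; a facility belongs simultaneously to an
American state and an HRR, and HRR boundaries cross state lines, so the
two groupings are cross-classified, not nested.  The analysis cohort is
complete-case: a provider enters only if it is present with every
required covariate, at least one registered-organization owner, and a
resolvable HRR at *every* date.  Missing values are flagged, never
imputed; the smaller sample of the MDS-adjusted model arises purely
from the completeness filter over measure codes.

## Owner matching

Registered organizations must use their exact legal name from the
public organic record, and those names are unique within a state, so
ownership ties are matched by exact key.  Normalization is deliberately
minimal: remove commas and periods, collapse whitespace runs, trim,
upper-case.  Upper-casing is an addition beyond the minimal rule (real
NHC names are already upper case; fixtures may not be).  No suffix
canonicalization is applied — "LLC" and "L L C" remain distinct —
because the exact legal string is the identifier; aggressive cleaning
would manufacture false merges.  Facilities owned solely by individuals
are excluded from network construction (personal names are not unique
keys).  One normalized key is one owner *within each HRR network*; the
same key appearing in two HRRs yields two independent nodes, a direct
consequence of using the HRR as the focal area.

## Ownership networks

Per HRR and date, a two-mode graph links facilities to owner keys; the
one-mode projection ties two facilities with weight equal to their
number of shared owners.  A facility with projection degree ≥ 1 has
*multiple affiliation* (super-organization); an isolate has *single
affiliation*.  Ownership groups are communities of the
multiple-affiliation subgraph found by weighted-modularity optimization
on the projection (resolution 1.0, configurable).  Running community
detection on the projection rather than on the bipartite graph is a
choice: groups are groups of facilities.  Modularity is additive over
connected components, and ownership components are typically small
near-cliques where Louvain's greedy local moves can miss shallow
optima; components of up to eight nodes are therefore solved *exactly*
by exhaustive maximum-modularity search, while larger components take
the best of five seeded Louvain restarts (default seed 20160301) with
the whole-component and all-singletons partitions as extra candidates.
The reported partition therefore never scores below the
connected-components or singleton baselines.  A singleton community
containing a connected node — possible in principle, never for planted
cliques — is merged into its heaviest neighbouring community, so groups
(all of size ≥ 2) exactly partition the multiple-affiliation set.
Groups-of-size-≥-2 is forced by the reported mean group sizes (~3.1–3.2),
which are inconsistent with counting isolated facilities as groups of
one.

## Market concentration

HHI is the sum of squared certified-bed shares over facilities of an
HRR; the affiliation-accounted AHHI pools each ownership group's beds
into one share before squaring; ΔHHI = AHHI − HHI ≥ 0 is concentration
attributable purely to super-organization.  Pooling uses the Louvain
groups by default (connected components are an option; for planted
clique structures the two coincide).  Zero-bed facilities are excluded
with a warning.  Indices are reported on the 0–1 scale.

HRR-level covariates for the regression are: prevalence of
multiple-affiliation facilities (%), mean ownership-group size (an HRR
with no groups gets 1.0, flagged — every facility standalone), and
ΔHHI.  National summaries are unweighted across HRRs with sample
(n−1) standard deviations.

## The outcome model

The Total Weighted Health Survey Score is a weighted count of cited
care deficiencies; raw values are discretized to the nearest integer
(half away from zero) to serve as a Poisson outcome.  The model is

    y_i ~ Poisson(exp(x_i'β + u_state[i] + u_hrr[i] + u_fac[i] + e_i))

with independent Gaussian random intercepts per state, HRR and facility
and an observation-level Gaussian residual e_i (log-normal Poisson)
absorbing overdispersion; the facility intercept carries the repeated
semi-annual measures.  Continuous covariates are mean-centered over the
analysis sample.  Two fixed-effect variants exist: Model 1 carries the
ordinal Five-Star rating as dummies (category 1 reference); Model 2
replaces it with the 21 MDS measure-code prevalences (the rating is
derived from those measures; carrying both would be collinear).
Reference levels: for-profit ownership, multiple affiliation, and their
combination for the ownership × affiliation interaction.

Priors: fixed effects Normal(0, 10⁸); variance components half-Cauchy(0, 5)
by default, with an inverse-gamma(0.001, 0.001) compatibility option.
The default chain schedule is 115,000 iterations, burn-in 15,000,
thinning 10 — exactly 10,000 kept draws.

### Sampler

No probabilistic-programming backend is used; the sampler is a purpose-
built adaptive Metropolis-within-Gibbs scheme (the sampling algorithm is
an implementation contract — any scheme passing the closed-form-limit
and recovery tests conforms):

- **Initialization** at a cheap mode guess: least squares of log(y+½)
  on X, residual level means (shrunk) for the random intercepts.
- **Fixed-effect block:** multivariate random walk preconditioned by
  the inverse Fisher information X'WX (+ prior precision), globally
  scaled by 2.4/√p with acceptance-rate adaptation during burn-in.
- **Interweaved moves:** for each grouping factor, a second
  fixed-effect proposal in the factor's sufficient parameterization —
  u′_k = u_k − x̄_k′(β′−β) — so the likelihood resists only through
  within-level covariate variation.  Without these, coefficients of
  covariates that barely vary within a facility mix at a crawl against
  the facility intercepts.
- **Ridge Gibbs draws:** columns (nearly) constant within a factor's
  levels admit an exact conditional draw holding v = u + x̄'β_sub
  fixed; the Gaussian prior terms cancel against the proposal, leaving
  only the (tiny) within-level likelihood change in the acceptance.
  With the observation-level term this becomes an exact full-β Gibbs
  draw along v = Xβ + e, the classic auxiliary-variable update.
- **Per-level vectorized random-walk updates** for every random-effect
  factor, with per-level step sizes adapted toward 0.44 acceptance.
- **Exchange sweeps:** nested pairs of factors (facility within HRR,
  facility within state, observation within facility) have
  likelihood-invariant directions — shift a coarse level, compensate
  its fine levels.  These are exact Gibbs draws and remove the slow
  collective modes between intercept layers.  An analogous recentering
  sweep trades each factor's mean against the model intercept.
- **Conjugate variance updates** via the inverse-gamma scale-mixture
  representation of the half-Cauchy.

All adaptation stops at the end of burn-in, so the kept draws target
the exact posterior.  Diagnostics (split-chain effective sample size
and split-R̂ via arviz) are attached to every fit; a chain with
min ESS < 100 or max R̂ > 1.05 is flagged, never silenced.

### Summaries

PR = exp(posterior mean coefficient); interval bounds are the
exponentiated coefficient-scale 95% HPDI (shortest window over sorted
draws, first window on ties); pMCMC = 2·min(frac > 0, frac < 0),
floored at 1/n_kept and printed as a "<" bound at the floor.  ICCs
divide each variance component's draw by the sum of all four
(state + HRR + facility + observation); a Poisson-specific
distributional variance can optionally be added to the denominator but
is excluded by default.  Per-state and per-HRR random-intercept PRs
(exp of posterior-mean intercept) are exported for mapping.

## Synthetic data generator

The generator fabricates NHC-dialect tables with planted truth.  What
it emulates, with defaults at the observed national magnitudes:
~30 facilities per HRR (600 facilities, 20 HRRs, 8 states, 5 dates);
56.8% of facilities in super-organization nationally with an
across-HRR spread of SD 16.7; group sizes from a shifted geometric with
mean 3.2 (support 2–8); ownership type shares 74.3 / 6.5 / 19.2%
(for-profit / government / non-profit); lognormal certified beds
(median 90, log-SD 0.7); outcome counts with marginal mean ≈ 59 and
variance-component shares 0.175 (state) and 0.073 (HRR) of a 0.904
total latent variance, which also puts the outcome's SD/mean ratio
(~1.2) at the observed level.  30% of HRRs straddle two states, giving
genuine cross-classification.  Owner names are decorated with commas,
periods, stray spacing and case noise that always normalizes back to
the planted key.  Outcomes are drawn from the same design matrix the
inference stage builds, at the configured true coefficients, so
recovery is exactly identified; the emitted raw score adds sub-0.5
jitter that the discretization rule removes.

What it does **not** emulate: real CMS name-typo distributions (all
decorations are normalization-invariant by construction), facility
entry/exit between dates (balanced panel), ownership churn, spatially
correlated covariates, or informative missingness (MDS codes are
knocked out at random).  Passing tests therefore demonstrate
correctness of the pipeline's mechanics and calibration of its
inference under the stated generating process — not robustness to real
data's dirtiness.

## Experiment sizes

Test-suite experiments run at desk scale, chosen as the package's own
reference conditions: parameter recovery uses 20 replicates of 2,000
facilities × 5 dates (20 HRRs, 8 states) with reduced chains
(11,500 / 1,500 / 10); interval-width monotonicity compares 1k / 2k /
5k facility-date rows at fixed facilities-per-HRR density (7 / 13 / 33
HRRs), since holding the number of HRRs fixed while adding facilities
shrinks the numeric scale of the concentration covariates and
mechanically inflates their coefficients' scale.  The acceptance script
fits 2,000 facilities × 5 dates with 48 HRRs / 24 states, where the
variance-share posteriors are stable.

## Numerical choices and edge cases

- Discretization: round half away from zero ("nearest integer" left
  the tie rule open).
- Linear predictors are capped at 50 inside exponentials; a generator
  configuration implying a predictor above 30 is rejected.
- Variance draws are floored at 1e-12.
- Rank deficiency is detected by greedy Gram–Schmidt and reported with
  the aliased column names (a simulator evaluating a *given* β skips
  the check).
- Zero-bed facilities are excluded from concentration with a warning;
  an HRR with zero total beds is an undefined market (error).
- Empty panels, empty HRR sets and all-individual ownership lists
  produce explicit empty results, not exceptions.
- HPDI requires ≥ 100 draws; at fewer the estimator is refused rather
  than silently unstable.

## Known limitations

- Exact key matching understates connectivity whenever real records
  misspell a legal name; market concentration is accordingly a lower
  bound in that regime.
- With few grouping levels (e.g. 8 states) variance-component posterior
  means are heavy-tailed under the half-Cauchy prior; ICC point
  estimates at that scale are noisy even when the β posteriors are
  well calibrated.
- Frequentist coverage of 95% HPD intervals estimated from 1,000 kept
  draws carries Monte-Carlo endpoint noise of a few percent of the
  interval width; borderline coverage counts in small replicate sets
  can flip on that noise.
- Lagged effects of ownership change are not modelled; only a
  contemporaneous changed-ownership indicator enters the design.
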