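# nhnet

Ownership networks, market concentration and care-deficiency modelling
for United States nursing homes, from Nursing Home Compare (NHC) style
open data.

## The problem

Many American nursing homes are held by webs of registered organizations
(LLCs, trusts, corporations) rather than by a single visible chain.
Because registered organizations must use their exact legal name on
statutory documents, shared ownership is recoverable from public data by
exact key matching on lightly normalized owner names.  `nhnet`
implements a two-step procedure over five semi-annual processing dates:

1. **Network step.**  Within each hospital referral region (HRR — one of
   306 US health-care markets), build the two-mode facility/owner graph,
   project it onto facilities (edge weight = number of shared owners),
   classify each facility as *multiple affiliation* (super-organization:
   shares at least one owner with another facility in its HRR) or
   *single affiliation*, detect ownership groups with Louvain modularity,
   and compute market concentration:

   - HHI = Σᵢ (bedsᵢ / total beds)² over facilities,
   - AHHI = the same sum after pooling the beds of each ownership group,
   - ΔHHI = AHHI − HHI ≥ 0, the concentration attributable purely to
     super-organization.

2. **Regression step.**  A Bayesian hierarchical Poisson model of the
   Total Weighted Health Survey Score (TWHSS, a weighted deficiency
   count y, discretized to the nearest integer):

   y ~ Poisson(exp(x'β + u_state + u_HRR + u_facility + ε)),

   with additive cross-classified state and HRR random intercepts (HRRs
   cross state lines), a facility intercept for the repeated measures,
   and an observation-level log-scale residual for overdispersion.
   Effects are reported as prevalence ratios PR = exp(E[β | data]) with
   95% highest-posterior-density intervals, two-sided tail probabilities
   (pMCMC), and intraclass correlation coefficients per variance
   component.  Inference is a custom adaptive Metropolis-within-Gibbs
   sampler (see `docs/methods.md`).

A synthetic-data generator plants known ownership groups,
cross-classified geography, and outcomes with known coefficients, so the
entire pipeline is testable offline with exact ground truth.

## Worked example

```python
from nhnet import (GeneratorConfig, generate, derive_hrr_networks,
                   compute_hrr_metrics, national_summary)

data = generate(GeneratorConfig(n_facilities=150, n_hrrs=6, n_states=3,
                                n_dates=3), seed=42)
panel = data.assemble()
networks = derive_hrr_networks(panel, seed=42)
metrics = compute_hrr_metrics(networks)
s = national_summary(metrics, date=1)
print(f"HRRs: {s.totals['n_hrrs']}, facilities: {s.totals['n_facilities']}")
print(f"prevalence of multiple affiliation: {s.means['prevalence_multiple_pct']:.1f}%")
print(f"mean ownership-group size: {s.means['mean_group_size']:.2f}")
print(f"HHI {s.means['hhi']:.3f}  AHHI {s.means['ahhi']:.3f}  "
      f"dHHI {s.means['delta_hhi']:.3f}")
```

prints

```
HRRs: 6, facilities: 150
prevalence of multiple affiliation: 49.3%
mean ownership-group size: 3.32
HHI 0.057  AHHI 0.104  dHHI 0.047
```

i.e. six synthetic markets in which about half the facilities share an
owner with a neighbour, ownership groups average ~3.3 facilities, and
pooling group beds roughly doubles measured concentration.  Fitting the
regression step on a generated panel and printing the coefficient table:

```python
from nhnet import ModelSpec, MCMCSettings, build_design, fit_poisson_glmm, summarize
from nhnet.synthetic_data import RECOVERY_SPEC

bundle = build_design(data.model_frame(), RECOVERY_SPEC)
samples = fit_poisson_glmm(bundle, MCMCSettings(n_iter=11_500, burn_in=1_500,
                                                thin=10, seed=7))
print(summarize(samples).fixed[["term", "pr", "l95_hpdi", "u95_hpdi"]].head(4))
```

```
               term         pr  l95_hpdi   u95_hpdi
0         intercept  30.541598  9.859115  74.291850
1  staffing_cna_hrd   1.183451  0.903988   1.561265
2   staffing_rn_hrd   0.778035  0.524310   1.243883
3     occupancy_pct   0.991461  0.979832   1.003403
```

(Small synthetic sample, hence wide intervals; a PR of 0.78 for RN
staffing means each extra adjusted RN hour per resident day is
associated with ~22% fewer cited deficiencies on average.)

There is also a CLI:

```bash
nhnet simulate --seed 1 --out fixture/
nhnet run --config run.yaml          # full two-step pipeline
```

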