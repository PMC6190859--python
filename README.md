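# sinktrace

Signature-based microbial source tracking (MST) for water quality, with
background-aware source libraries, signal-quality scoring and hierarchical
Bayesian follow-up models.

## The problem

Fecal pollution of raw water is traced by decomposing a contaminated "sink"
16S community into contributions from candidate source environments (animal
feces, sewage) using a library of reference communities. Many bacteria are
cosmopolitan: sewage and dog feces in particular share large OTU sets with
natural water. A library that contains no water communities has nowhere to
put those shared reads except the fecal sources, so it overestimates
contamination and misattributes sources. `sinktrace` implements and compares
three library designs:

* **WB** — fecal/sewage sources only (no background);
* **LB** — plus a background source of clean water from the sink's own
  location;
* **DM** — plus a background selected by Dirichlet-multinomial mixture
  clustering when no local samples exist.

It is aimed at microbiome researchers and water-quality practitioners who
want to run the comparison end to end on their own OTU tables or on
synthetic communities with known truth.

## The model

Source proportions are inferred by a collapsed Gibbs sampler on a
Dirichlet-multinomial mixture with an extra Unknown source. For read *i* of
OTU *t*:

    P(z_i = v | z_-i) ∝ (n_v^(-i) + β) · P(t | v)
    P(t | v known)    = (m_vt + α₁) / (m_v· + α₁T)
    P(t | Unknown)    = (u_t^(-i) + α₂N) / (u_·^(-i) + α₂NT)

with defaults α₁ = 0.001, α₂ = 0.1, β = 10. Beyond mixing proportions, the
sampler reports a per-OTU source posterior (normalized to one per observed
OTU per sink); OTUs with posterior ≥ 0.7 toward a source are its
*source-accurate* OTUs and their fraction among attributed OTUs (> 0.1) is
the signal's accuracy — a direct read-out of how much of a signal rests on
confidently placed taxa.

Two hierarchical Bayesian models relate MST output to fecal-indicator
bacteria (FIB): a multivariate GLMM correlating the three per-sink
contamination totals with E. coli / enterococci / coliform counts through a
correlated observation-level residual (LKJ prior on the correlation), and a
Poisson GLMM with offset estimating how the background libraries change the
rate of source-accurate OTUs (rate ratios exp(β₁), exp(β₂) vs the WB
baseline). See `docs/methods.md` for the full specification.

## Worked example

```python
from sinktrace import (RunConfig, ScenarioSpec, run_experiment,
                       true_contamination)

cfg = RunConfig(scenario=ScenarioSpec(), seed=7,
                mcmc_chains=4, mcmc_iterations=600, mcmc_burnin=300)
bundle = run_experiment(cfg)

tc = true_contamination(bundle.truth)
clean = tc.index[tc == 0]
print(bundle.totals.loc[clean, ["WB", "DM", "LB"]].mean().round(4))
c = bundle.correlations
print(c[(c.response_1 == "DM") & (c.response_2 == "coliforms")]
      [["mean", "q2.5", "q97.5"]].round(3))
```

This simulates the default scenario (8 fecal/sewage sources, 3 water
locations, 10 sinks of which 5 are clean and 5 carry 0.5–10% sewage), builds
all three libraries per sink, runs the Gibbs sampler, scores signals and
fits both Bayesian models. Output:

```
WB    0.0290
DM    0.0013
LB    0.0013
dtype: float64
    mean   q2.5  q97.5
8  0.349  0.052  0.587
```

Reading: on truly clean sinks the background-free WB library reports ~2.9%
contamination — over twenty times the DM/LB estimates — because water OTUs
shared with sewage and dog feces have nowhere else to go; and the DM
contamination totals correlate positively with coliform counts (posterior
mean 0.35, 95% interval excluding zero) while the corresponding WB
correlation is weaker with an interval straddling zero.

A CLI mirrors the library: `mst simulate`, `mst build-library`, `mst gibbs`
and `mst run --config run.yaml`.

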