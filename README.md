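# wsforecast

Forecasting mutational routes to the **wrinkly spreader (WS)** phenotype of
*Pseudomonas fluorescens* SBW25.

WS mutants arise by activation of one of three diguanylate-cyclase pathways
— **Wsp** (7 genes, 8.4 kb), **Aws** (3 genes, 2.3 kb) and **Mws** (one
gene, 3.9 kb) — and the central question is whether knowledge of the
genotype-to-phenotype map suffices to predict *which* pathway evolution
will use, and how often.  This package implements that forecasting analysis
end to end for researchers working on evolutionary predictability and
mutation-rate estimation:

* **Null models of pathway usage.**
  Model I uses locus length: P(pathway used) = 1 − (1 − p)ⁿ ≈ np with n in
  bp.  Model II uses gene count.  Model III classifies each reaction of a
  mass-action ODE model of the pathway as *enabling* (raising its rate
  raises the WS reporter) or *disabling*, and weights pathways by reaction
  counts (6:4:3 for Wsp:Aws:Mws).  Model IV is a Bayesian Monte-Carlo
  model:

  P(WS ∩ m ∩ pathway) = Σᵢ P(WS | mᵢ) · P(mᵢ),

  where mᵢ ∈ {−1, 0, +1}ⁿ is a mutation vector over the pathway's mutable
  reaction rates, the prior P(mᵢ) is a product of per-reaction enabling and
  disabling probabilities p_e and p_d, and P(WS | mᵢ) is estimated by
  integrating the pathway ODEs under randomly sampled rate constants
  (10^U[−2,2]), initial concentrations (U[0,10]) and mutation effect sizes
  (10^U[0,2] enabling, 10^U[−2,0] disabling).  Mutational hotspots enter
  all models as a multiplicative factor k.

* **Mutation rates from fluctuation assays** via the Ma–Sandri–Sarkar
  maximum-likelihood estimator on the Luria–Delbrück distribution, with
  Stewart confidence intervals (μ = m/N_t).

* **Mutation-spectrum analytics**: resampling tests for hotspots,
  mutation-rate-adjusted fractions, and selection-vs-no-selection
  contingency comparisons.

* **Competition fitness**: selection coefficients s = ln(R(t)/R(0))/t with
  marker-cost correction.

* **Synthetic data generators** reproducing the statistical shape of all
  three experimental data classes, so every stage is testable without any
  external data.

## Worked example

The numbered scripts under `analysis/` run the full story.  Generate a
study-shaped synthetic data set and estimate pathway mutation rates:

```bash
python analysis/01_simulate_experiments.py --seed 0
python analysis/02_estimate_rates.py
```

```
Aws : mu = 5.16e-09 per cell per generation (95% CI 3.98e-09-6.69e-09, m = 0.258, C = 200)
Mws : mu = 5.56e-10 per cell per generation (95% CI 3.83e-10-8.05e-10, m = 0.028, C = 400)
Wsp : mu = 3.45e-09 per cell per generation (95% CI 2.57e-09-4.63e-09, m = 0.172, C = 200)
Aws vs Mws: z = +9.64, p = 5.62e-22
sum of pathway rates: 9.163e-09 (measured WT rate was ~1.12e-8)
```

The simulated truth (6.5, 0.74, 3.7 ×10⁻⁹) is recovered within the
confidence intervals; Aws mutates to WS about twice as fast as Wsp despite
being the smaller target.  The null models predict the opposite priority:

```bash
python analysis/03_null_models.py
```

```
Model I  (bp):    Wsp/Aws = 3.65, Aws/Mws = 0.59
Model II (genes): Wsp/Aws = 2.33, Aws/Mws = 3.00
Wsp: disabling ['r2', 'r6'], enabling ['r1', 'r3', 'r4', 'r5']
Model III equal: 6:4:3
Model II hotspot factors: k = 10.3 (Aws/Wsp), 6.8 (Aws/Mws)
Model III hotspot factor (p_d=1e-3, p_e=1e-4): k = 3.91 (Aws/Wsp)
```

Reconciling the gene-count model with the measured rates requires a
10.3-fold hotspot in Aws; the reaction-level Model III needs only ~4-fold —
and the spectrum analysis (`analysis/05_spectrum_analysis.py`) shows such a
hotspot is real: a single 33-bp in-frame deletion in *awsX* accounts for
29% of all WS-causing mutations (rate-adjusted), a multiplicity never
reached in a million uniform resamplings.  `analysis/04_model_iv.py` runs
the Monte-Carlo Model IV, and `analysis/06_fitness.py` computes the
competition fitness of representative mutants, which explains why the
spectrum observed *under* selection differs (e.g. *wspR* mutants are
severely impaired: s ≈ −0.35 per generation).

The same stages are available as a CLI (`wsforecast simulate|rates|predict|
spectrum|fitness|report|run`) or as one call through
`wsforecast.pipeline.run_pipeline`.

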