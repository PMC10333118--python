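# tigersynth

Synthetic-control impact evaluation of protected-area policy, with
placebo-based inference, robustness checks, and conversion of averted
forest loss into avoided CO2e emissions and their monetary value.

The package was built around the evaluation design used to assess
India's tiger-reserve gazettement policy: ~45 protected areas received
enhanced protection between 2007 and 2015, ~117 protected areas with
tiger presence but no reserve status serve as donors, and the outcome
is each reserve's cumulative forest loss over 2001–2020 (hectares).
It is aimed at conservation scientists and impact-evaluation
practitioners who want the full chain — counterfactual, significance,
robustness, carbon accounting — as tested, scriptable components.

## The method

For a treated reserve with intervention year T0, the counterfactual
cumulative-loss trajectory is a convex combination of donor reserves
from the same landscape grouping:

    Y_synth(t) = Σ_j w_j Y_j(t),   w_j ≥ 0,  Σ_j w_j = 1.

Donor weights solve the nested synthetic-control problem: the inner
quadratic programme minimises the predictor discrepancy
`(X1 − X0 w)' diag(v) (X1 − X0 w)` over the simplex, where the
predictors are eleven structural deforestation drivers (population
density, road length, precipitation, elevation, slope, aspect,
baseline aboveground biomass, purchasing power, reserve age, travel
time to a city, area) plus the mean pre-intervention cumulative loss;
the outer search chooses the predictor weights v to minimise the
pre-intervention mean squared prediction error (MSPE) of the implied
counterfactual.

* **Effect**: averted forest loss = `Y_synth(2020) − Y_obs(2020)` (ha);
  positive values mean the policy reduced deforestation.
* **Inference**: each donor is refit as a pseudo-treated unit
  (the treated reserve joining its donor pool); the p-value is the
  descending rank of the treated post/pre MSPE ratio among all
  treated+placebo ratios divided by their count. With n placebos the
  attainable floor is 1/(n+1) — more than 20 donors are needed before
  p < 0.05 is possible.
* **Robustness**: a backdated pseudo-intervention (default 2005)
  screens for anticipation effects; donor pools trimmed to reserves at
  least 1/10 and 1/4 of the treated area are refit and scored for
  direction, ±20 % magnitude and significance concordance.
* **Carbon accounting**: averted hectares × reserve carbon densities
  (tC/ha, scaled from their 2010 reference year by the forest-cover
  ratio) × 3.67 tCO2e/tC, with the belowground pool released along a
  10-year linear decay. Values are reported at the social cost of
  carbon for India (US$86/tCO2e) and the voluntary offset price
  (US$5.8/tCO2e).

A fully tested synthetic-data generator (`tigersynth.simulate`)
produces study-shaped panels with known injected effects, so every
stage is testable without any geospatial input.

## Worked example

```python
import pandas as pd
import tigersynth as ts

cfg = ts.SimConfig(n_groups=1, donors_per_group=40, treated_per_group=1,
                   effect_rho=0.3, seed=7)       # 30% loss-rate cut in 2007
study, truth = ts.simulate_study(cfg)
rid = study.treated_ids[0]

fit = ts.fit_synthetic(study, rid)
ens = ts.placebo_distribution(study, rid)
carbon = study.carbon.set_index("reserve_id").loc[rid]
effect = pd.Series(fit.effect_series, index=fit.years)
acc = ts.account_for_reserve(rid, effect, carbon, study.intervention_year(rid))
```

prints (via the fields of `fit`, `ens` and `acc`):

```text
reserve: G1-T01  intervention: 2007
true averted ha:       185.5
estimated averted ha:  305.6
mspe_pre 0.93  mspe_post 30224.22  ratio 32631.5
p-value: 0.0244  (n_placebos=40)
avoided tCO2e: 79859 +/- 16893
SCC value kUSD: 6867.88   offset kUSD: 463.18
top donors: [('G1-D036', 0.507), ('G1-D001', 0.266), ('G1-D030', 0.161)]
```

The pre-period fit is tight (MSPE 0.93 ha²) and the placebo test is
significant at its floor for this donor count (p = 1/41). A single
replicate's effect estimate carries post-period noise — here 306 ha
against a true 186 ha — while across replicates the estimator is
unbiased (see the parameter-recovery tests). The carbon account then
converts the estimated hectares into avoided emissions and their two
valuations.

The same chain is scriptable:

```bash
tigersynth simulate --preset paper-shape --seed 1 --outdir sim/
tigersynth -v report --outcomes sim/outcomes.csv --covariates sim/covariates.csv \
    --treatments sim/treatments.csv --carbon sim/carbon.csv --outdir results/
```

writing `report.json`, `effects.csv`, `carbon.csv` and
`robustness.csv`.

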