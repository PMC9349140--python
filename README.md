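# mscua

Markov cohort cost-utility analysis of **teriflunomide sequencing in
relapsing–remitting multiple sclerosis (RRMS)**: starting teriflunomide in
treatment-naïve patients versus starting it after previous exposure to other
disease-modifying therapies (DMTs), from both the healthcare-sector and the
societal perspective in an Italian setting.

## The model

Two hypothetical cohorts of 1000 RRMS patients (naïve and experienced) move
through four mutually exclusive health states — controlled RRMS (entry
state), relapse, remission, death — over 7 annual Markov cycles. Because
relapsing naïve patients may switch from teriflunomide to a second-line DMT
(alemtuzumab, cladribine, fingolimod, natalizumab or ocrelizumab) from the
second cycle onwards, live states are expanded by treatment arm. Each cycle:

* death strikes every live compartment at the age- and sex-specific
  all-cause probability (female-share-weighted, cohort ageing one year per
  cycle);
* surviving controlled/remitted patients relapse with probability
  *p*(EDSS), a logistic function of the cohort's disability score;
* 20% of surviving relapsers remit; 10% of the non-remitting naïve
  relapsers switch (cycles ≥ 2).

Costs (three blocks: A healthcare sector, B out-of-pocket, C patient time
and informal care), life-years (LYS) and QALYs = LYS × state utility accrue
with half-cycle correction (within-cycle decedents earn half a cycle) and
3% annual discounting. Strategies are compared by the incremental
cost-utility ratio ICUR = ΔC/ΔQALYs, by strong dominance (ΔC < 0, ΔQ > 0),
and — probabilistically — by the net monetary benefit
NMB(λ) = λ·QALYs − Cost over a willingness-to-pay grid, yielding CEAC and
CEAF curves from a 10,000-iteration PSA in which each of the 438
distributed parameters (of 721) is drawn from its assigned family: beta
(probabilities, utilities), Dirichlet (switch shares), gamma (resource
volumes, EDSS), normal (non-drug unit costs, truncated at zero).

The full 721-parameter registry behind the published analysis is not
redistributable, so the package ships a **synthetic generator**
(`mscua.generate_registry`) that reproduces the registry's statistical
structure and the settings printed in the main text, and is loosely
calibrated to the published cost shares and outcome magnitudes.

## Worked example

```python
import mscua

model = mscua.CostUtilityModel.from_synthetic(seed=0)
results = model.fit()
print(results.summary())
```

```
Cost-utility analysis -- base case
============================================================
cohorts: 1000 patients, 7 annual cycles, discount rate 3.0%

[HEALTHCARE_SECTOR]
  experienced  cost €   89,236.98   LYS  6.399   QALYs  3.151
  naive        cost €   86,279.52   LYS  6.404   QALYs  3.623
  ΔC €-2,957.46   ΔQALYs +0.473   ICUR €-6,256.10/QALY   [STRONGLY_DOMINANT]

[SOCIETAL]
  experienced  cost €  113,378.12   LYS  6.399   QALYs  3.151
  naive        cost €  104,935.58   LYS  6.404   QALYs  3.623
  ΔC €-8,442.54   ΔQALYs +0.473   ICUR €-17,859.04/QALY   [STRONGLY_DOMINANT]
```

Starting teriflunomide first-line costs *less* and yields *more* QALYs than
starting it after other DMTs — it is strongly dominant under both
perspectives (the negative ICUR is reported for completeness only; under
dominance the verdict, not the ratio, carries the decision). Sensitivity
analyses hang off the same objects:

```python
tornado = results.run_owsa("HEALTHCARE_SECTOR")   # one-way SA, sorted
yearly  = results.yearly_icur()                   # ICUR at horizons 1..7
psa     = results.run_psa(n_iter=10000, seed=1)   # probabilistic SA
curves  = mscua.ceac(psa)                         # acceptability curves
```

A command line covers the same ground end to end:

```bash
mscua synth demo/            # write a synthetic registry + config
mscua basecase demo/config.yaml
mscua all demo/config.yaml   # full bundle: tables, tornado, PSA, CEAC/CEAF
```

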