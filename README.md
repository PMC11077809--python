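# amgcap

**Needs-based capitation financing from morbidity-adjusted healthcare
cost models.**

Regional health services that split their budget across territorial
areas by historical spending reward past spending, not present need.
`amgcap` implements the alternative: model each insured person's annual
cost from objective need variables — sex, 5-year age band, and Adjusted
Morbidity Group (AMG, a 31-way stratifier crossing morbidity type with
complexity level) — and allocate a fixed budget in proportion to each
area's *need-adjusted population*. It is written for health-economics
and health-service analysts who want the full workflow: model selection,
validation, morbidity cost weights, and the final allocation table.

## The model

Individual annual cost $Y_i > 0$ is fit with a gamma GLM, log link:

$$\mathbb{E}[Y_i] = \exp(x_i'\beta), \qquad
  \operatorname{Var}[Y_i] \propto \mathbb{E}[Y_i]^2,$$

selected from the menu customary for skewed cost data (gaussian /
poisson / gamma / inverse-gaussian families x identity / log /
square-root links) by a dual approach: an AIC/BIC grid over all 12
pairs, plus a Box-Cox $\lambda$ for the link and the modified Park test
— OLS of $\ln(y_i-\hat\mu_i)^2$ on $\hat\eta_i$, whose slope estimates
the variance power $p$ in $\mathrm{Var} \propto \mu^p$ — for the family.
Validity is checked with the Pregibon link test, a modified
Hosmer-Lemeshow decile test, and the Copas cross-validation test
(holdout slope = 1), alongside auxiliary $R^2$, RMSE and MAE on the
euro scale.

An area's **need index** is its predicted average cost over the system's
(unit scale); its **adjusted population** is covered population x need
index; the budget is allocated by raw population, by adjusted
population, and by historical share, and the needs-based and historical
columns are compared.

Because the calibrating person-level data (a Spanish regional health
service, 1.25M cost-incurring users, 2017) are not public, the package
ships a synthetic-population generator calibrated to that system's
published per-AMG composition and cost gradients; all simulation-based
tests and examples run on it. See `docs/methods.md` for the full model
account and the generator's limitations.

## Worked example

```python
from amgcap import *
from amgcap.simulate import SimConfig, generate_population, area_table
from amgcap.capitation import render_allocation, area_cost_summary
from amgcap.effects import weight_table

cfg = SimConfig(n_persons=50_000, seed=42)   # defaults emulate the 2017 system
records = generate_population(cfg)

X, y, enc = build_design(records)
model = fit_glm(X, y, ModelSpec("gamma", "log"), enc)
print("pseudo-R2:", round(pseudo_r2_deviance(model), 3))

park = modified_park_test(records)
print(f"Park slope: {park.slope:.3f} -> {park.recommended_family}")
```

```
pseudo-R2: 0.315
Park slope: 2.018 -> gamma
```

The deviance pseudo-$R^2$ of 0.315 says the need variables explain about
a third of the deviance in individual costs; the Park slope of 2.018
recovers the variance-power exponent 2 of the gamma family the costs
were drawn from. Morbidity cost weights relative to the healthy group
(selected rows):

```python
w = weight_table(model, records)
```

```
          coefficient   ame_eur  predicted_mean_eur  relative_weight
amg_code
1               0.000       NaN              225.46            1.000
321             0.581    180.25              396.79            1.760
335             3.916  11258.28            12513.53           55.501
405             4.354  17580.87            19893.87           88.235
```

A person with chronic disease in 4+ systems at the highest complexity
(AMG 335) costs about 55 times a healthy person; the most complex
neoplasm group (405) about 88 times. Finally the allocation of a 1,842
MEUR budget across the nine simulated areas:

```python
mu = predict(model, X)["mu"]
areas = area_table(cfg, records)
areas["need_index"] = need_index(area_cost_summary(records, mu))
print(render_allocation(allocate_budget(1842.0, areas)).to_string())
```

```
         covered_population  need_index  adjusted_population  alloc_population  alloc_adjusted  alloc_historical  difference
area_id
I                     10786     0.96047                10360               329             316               307        9.25
II                    11436     1.04469                11947               349             364               373       -9.14
...
VI                    11025     1.02275                11276               336             344               315       28.52
IX                     2193     1.08762                 2385                67              73                83      -10.41
```

Area VI spends well below its need (its generator configuration
under-spends relative to case mix), so the needs-based column hands it
28.5 MEUR more than its historical share; area IX, which over-spends
relative to need, would lose 10.4 MEUR.

The same workflow is available as a CLI
(`amgcap simulate | fit | select | diagnose | weights | allocate |
report`), e.g.

```sh
amgcap simulate --n 50000 --seed 42 --out persons.csv --areas-out areas.csv
amgcap fit --data persons.csv --family gamma --link log --out model.json
amgcap allocate --data persons.csv --model model.json --areas areas.csv \
    --budget 1842 --out allocation.csv
```

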