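# u5dgap

Sex inequality in under-five deaths (U5D) across low- and middle-income
countries: survey-style recoding, a neighborhood socioeconomic index,
risk-difference and Mantel–Haenszel inequality statistics with meta-analysis
across countries, collinearity screening, and a from-scratch Fairlie-type
nonlinear decomposition of the male–female mortality gap. A built-in
clustered-survey simulator with a known gap structure makes every stage
testable without access to any registration-gated microdata.

## Who this is for

Epidemiologists and demographers quantifying *pro-male* inequality (excess
male under-five mortality) from pooled child-level survey data — one row per
live birth with a death-before-60-months indicator, sex, sampling weight,
cluster and country identifiers, and categorical covariates — or from a
published country summary table when microdata are unavailable.

## The statistics at the core

For each country, deaths by sex form a 2×2 table. The risk difference
`RD = 1000·(p_m − p_f)` (per 1000 live births; RD > 0 is pro-male) carries a
binomial Wald variance and a pooled-variance z-test. Across countries the
package pools:

- the **Mantel–Haenszel odds ratio** `OR_MH = Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i)`
  with the Robins–Breslow–Greenland variance;
- **heterogeneity** via Cochran's Q on log ORs (Breslow–Day as an option)
  and `I² = 100·max(0, (Q − df)/Q)`;
- a **DerSimonian–Laird random-effects meta-analysis** of the RDs
  (moment estimator of τ², weights `1/(v_i + τ²)`).

The male–female gap in death probability is decomposed with the nonlinear
(Fairlie-type) extension of Blinder–Oaxaca. With logistic F and group
coefficient vectors β̂:

```
Ȳ_A − Ȳ_B = [ mean F(X_A β̂_A) − mean F(X_B β̂_A) ]   explained (composition)
          + [ mean F(X_B β̂_A) − mean F(X_B β̂_B) ]   unexplained (structure)
```

Per-variable contributions substitute covariates record by record: the
larger group is randomly subsampled to the smaller group's size, records are
paired rank-to-rank on predicted probability under pooled coefficients, and
each variable's contribution is the change in mean predicted probability
when its paired group-B values are replaced by group-A values along a
(optionally randomized) ordering. Contributions telescope exactly to the
matched explained term; replication over D subsample draws gives standard
errors. With the identity link the procedure collapses to classical
Blinder–Oaxaca, which serves as an exact oracle in the tests.

## Worked example

```python
from u5dgap import SimConfig, generate, fairlie_decompose, true_decomposition

cfg = SimConfig(seed=1)                 # 10 countries x 50 clusters x 30 children
records, truth = generate(cfg)          # canonical child table + generator truth
names = [c.name for c in cfg.covariates]
res = fairlie_decompose(records, names, D=100, seed=8)
print(f"gap {1000*res.total_gap:.2f}/1000, explained {1000*res.explained:.2f}/1000")
print(res.table[["variable", "contribution", "se", "pct_of_gap"]].round(5))
```

Output:

```
gap 13.54/1000, explained 2.43/1000
             variable  contribution       se  pct_of_gap
0  maternal_education      -0.00016  0.00088    -1.18381
1  maternal_age_group      -0.00009  0.00064    -0.63647
2         birth_order      -0.00001  0.00075    -0.04002
3        birth_weight       0.00273  0.00319    20.16759
4                twin       0.00008  0.00270     0.62222
5           residence      -0.00013  0.00020    -0.95428
```

The scenario's only sex difference in composition is birth weight (males
drawn slightly more often into the `small` / `very small` categories), plus
a direct sex effect on the log-odds. Accordingly the decomposition
attributes essentially all of the explained part to birth weight — 0.00273
probability points, i.e. 2.7 deaths per 1000 — while the other covariates
hover near zero; the remainder is the unexplained (structural) part. The
generator-truth value of the birth-weight contribution,
`true_decomposition(cfg, method="matched").contributions["birth_weight"]`,
is 2.75 per 1000, and the population gap is 7.0 per 1000 — this particular
draw of 15,000 children happens to show a larger observed gap (13.5), a
reminder that a single desk-scale replicate is noisy; averaging replicates
recovers the truth (see the tests).

The same machinery runs from the shell:

```sh
u5dgap simulate --seed 1 --out children.csv
u5dgap run-all --out run1 --seed 1          # recode -> SES -> RD/MH/meta -> VIF -> decomposition
u5dgap fixture-check                        # verify the packaged country table
```

## The packaged country summary table

`load_table1_fixture()` ships the published 59-country summary (sample
sizes, percent male, sex-specific U5D per 1000, 2010–2018 surveys,
856,987 children in 66,495 clusters) with regional subtotal rows flagged.
`reconstruct_country_table()` rebuilds each country's sex-by-death table
from these printed numbers, which is what the summary-only pipeline mode
(`input_path="fixture"`) and the acceptance script consume.

## Layout

| module | role |
|---|---|
| `data_model` | canonical child schema, codebook recoding, readers/writers, packaged country table |
| `synthetic_data` | clustered two-level survey generator + population truth oracles |
| `ses_index` | neighborhood disadvantage index (PCA on cluster proportions, quintile cut) |
| `inequality_stats` | prevalence, RD, z-test, MH OR, heterogeneity, DL meta-analysis, quadrants |
| `collinearity` | iterative VIF screening (threshold 2.5) |
| `fairlie` | the decomposition core: fits, matching, sequential substitution, replication |
| `pipeline` / `cli` | end-to-end orchestration and the `u5dgap` command |

See `docs/methods.md` for the modelling choices, conventions and known
limitations.
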