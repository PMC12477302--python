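# reciprostat

Statistical toolkit for analysing how a disturbance (here: fire) affects the
functioning of **distyly**, the floral polymorphism in which a population
carries long-styled (L) and short-styled (S) morphs with reciprocally placed
sexual organs. It was built around a field design that compares a burned and
an adjacent unburned patch of a single distylous *Palicourea rigida*
(Rubiaceae) population in the Brazilian Cerrado, but all components work on
any tidy trait table with `area x morph x individual` structure.

The package is aimed at pollination ecologists and biostatisticians who want
a tested, reproducible implementation of:

1. **Between-morph reciprocity via adaptive inaccuracy.** For one organ
   level, with anther-height mean and variance $(\bar A, V_A)$ and
   stigma-height mean and variance $(\bar S, V_S)$,

   $$\text{inaccuracy} = \underbrace{(\bar A - \bar S)^2}_{\text{maladaptive bias}}
     + \underbrace{V_A + V_S}_{\text{imprecision}},$$

   and the total inaccuracy of a morph pairing is the sum of its high-organ
   (S-anther vs L-stigma) and low-organ (L-anther vs S-stigma) inaccuracies.
   Lower values mean tighter reciprocal herkogamy. With two areas there are
   four legitimate pairings (within each area plus the two cross-area ones);
   the package computes the full decomposition for each, with seeded
   bootstrap percentile intervals.

2. **Factorial trait models** `trait ~ area * morph` with the family each
   trait calls for — gaussian/identity, gamma/log, NB1 negative binomial
   ($\mathrm{Var} = \mu(1+\alpha)$, log link, optional structural zero
   inflation), beta/logit, binomial/logit — with plant individual as a
   repeated-measures cluster, **type-II Wald chi-square tests** per term,
   back-transformed **marginal means** (factor-grid averaged on the link
   scale, delta-method SEs) and fire-vs-no-fire **contrasts conditioned on
   morph**.

3. **Percent effect sizes** between group marginal means,
   $100\,(\bar y_{\text{focal}} - \bar y_{\text{ref}})/\bar y_{\text{ref}}$,
   and **nectar energetics** (refractometer % w/w -> ug sucrose per uL via
   sucrose-solution density -> calories at 4 cal/mg sugar).

4. A **synthetic-data generator** that emulates the study's hierarchical
   sampling design (individuals in area x morph cells; inflorescences,
   flowers, nectar and pollen-scored stigmas nested in individuals), so the
   whole pipeline is testable end-to-end without the undeposited field data.

## Worked example

```python
from reciprostat import PopulationConfig, generate_dataset, ReciprocityAnalysis
from reciprostat.models import fit_trait_model, default_registry, \
    wald_type2_tests, marginal_means

cfg = PopulationConfig(seed=11)          # defaults = the emulated study design
table = generate_dataset(cfg)            # tidy trait table, 2908 rows

rec = ReciprocityAnalysis(bootstrap_B=1000, seed=11).fit(table)
print(rec.table_[["combination", "maladaptive_bias_high", "imprecision_high",
                  "total_inaccuracy"]].round(3))
```

```
          combination  maladaptive_bias_high  imprecision_high  total_inaccuracy
no_fire_L x no_fire_S                  0.011             2.050             4.356
      fire_L x fire_S                  0.029             2.487             5.372
   no_fire_S x fire_L                  0.013             2.381             5.326
   no_fire_L x fire_S                  0.026             2.155             4.334
```

Maladaptive bias (squared mean mismatch of paired organs, mm^2) is tiny in
all four pairings and the totals are dominated by imprecision (organ-height
variances) — i.e. organ placement is reciprocal within and across the burned
and unburned areas, the hallmark of an intact distylous system.

```python
spec = next(s for s in default_registry() if s.trait == "n_fruits")
fit = fit_trait_model(table, spec)       # NB1/log, cluster-robust by individual
print(wald_type2_tests(fit).round(4))
```

```
      term    chi2  df  p_value
      area  3.2912   1   0.0697
     morph  5.0681   1   0.0244
area:morph 11.5024   1   0.0007
```

The significant `area:morph` interaction for fruit counts reflects the
generator's morph-specific fire effect: the S-morph fire cell mean (118.5
fruits per infructescence) sits well above its no-fire counterpart (91.6),
while the L morph barely moves — the same pattern the percent-effect module
then quantifies (`fire vs no_fire | morph S` gives a ~+35% increase under
the default configuration).

The same analysis is available from the shell:

```
reciprostat run --out report/ --seed 11 --bootstrap-b 1000
```

which writes CSV tables (tests, marginal means, contrasts, inaccuracy with
CIs, percent effects), a JSON summary and a text report, all reproducible
byte-for-byte for a given seed.

## Layout

```
src/reciprostat/
  config.py       population / sampling-design configuration (YAML I/O)
  synth.py        seeded generator: NB1, zero-inflated NB1, trait tables
  reciprocity.py  organ summaries, inaccuracy decomposition, bootstrap
  models.py       factorial GLM/GLMM fits, type-II Wald, marginal means
  effects.py      percent effects, Brix -> sucrose -> calories
  published.py    published marginal means used as worked-example inputs
  pipeline.py     seeded end-to-end run + report serialisation
  cli.py          `reciprostat simulate|reciprocity|fit|effects|run`
```

See `docs/methods.md` for the statistical methodology, default parameter
choices and known limitations.
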