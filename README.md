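# qtgtest

Statistical machinery for proving that a candidate gene is a **quantitative
trait gene (QTG)** — the causal gene behind a QTL. The package implements,
as a tested pipeline over simulated mouse cohorts, the three analyses that
make that argument:

1. **Quantitative complementation test.** In a four-way cross segregating a
   knockout (KO) allele and a QTL allele on a uniform background, a
   significant KO×QTL interaction in a two-way ANOVA
   (`trait ~ KO * QTL`) is *failure to complement*: the knocked-out locus
   and the QTL behave as one. Traits are first residualized on parity,
   litter size and a litter random intercept with a REML mixed model, and a
   MANOVA screen (Wilks, Pillai, Hotelling–Lawley, Roy) decides per trait
   group whether sexes can be pooled.
2. **F2 qualitative analyses.** One-way ANOVA across the three F2
   genotypes, Tukey HSD with compact letter display, and per-group MANOVA.
3. **Causal inference test (CIT).** With genotype *G*, expression *E*
   (from triplicate qPCR via the 2^−ΔΔCT method) and trait *T*, four
   component regressions decide whether *G → E → T*: *G* associated with
   *T*; *G* with *E* given *T*; *E* with *T* given *G*; and *G*
   independent of *T* given *E*. All three significant plus the last
   non-significant ⇒ `causal` (test 3 in (0.05, 0.10] ⇒ `causal_marginal`).

Because no per-animal data are published for the motivating study, a
synthetic-data module is part of the deliverable: four-way and F2 cohorts
with Mendelian segregation, litter/parity/sex structure, and a configurable
mediation model (`causal`, `reactive`, `independent`, `null`), plus a Ct
panel simulator that inverts the 2^−ΔΔCT transform. See
[docs/methods.md](docs/methods.md) for the model and all numerical choices.

## Worked example

```python
from qtgtest import RunConfig, run_cit_study

bundle = run_cit_study(RunConfig(seed=2029, outdir="results/cit"))
print(bundle["expression_summary"].round(3))
```

```
                 mean    sem   n
genotype_group
B6J/B6J         2.023  0.139  10
KO/B6J          1.000  0.091  12
```

The heterozygote calibrator group's mean relative liver expression is
exactly 1 (the group-mean 2^−ΔΔCT convention), and the wildtype group sits
near 2-fold, reflecting its extra functional allele copy. The CIT table in
`bundle["table"]` holds, per trait, the group means ± SE, the four
component P values, the unconditional expression-association P, R² and the
causal label. At the study's n = 12 + 12 the full four-test conjunction is
a low-power instrument — the calibration harness puts the causal-call power
near 0.23 in this effect-size regime (expression ratio ≈ 2, population
R² ≈ 0.29) with a false-causal rate ≈ 0.04 under a non-mediated model:

```bash
$ python analysis/04_expression_cit.py
...
calibration over 300 replicates at n = 12 + 12: false-causal rate 0.040
(independent model), causal-call power 0.233 (mediated model, expression
ratio ~2, population R^2 ~0.29)
```

The numbered scripts under `analysis/` run the three studies end to end
(`01` simulate + segregation checks, `02` complementation, `03` F2 group
analysis, `04` expression + CIT) and write tidy TSVs plus a manifest under
`results/`. The same stages are available as subcommands of the `qtgtest`
CLI (`simulate`, `adjust`, `complement`, `intercross`, `qpcr`, `cit`,
`run-all`).

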