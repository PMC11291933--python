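# deconfound

Confounder-aware association testing for multi-omics cohort studies.

In small clinical cohorts, features of the gut or airway microbiome, the
plasma metabolome, and the immune response are rarely associated with
disease alone: antibiotic therapy, length of hospitalization, comorbidity
burden and other clinical variables travel together with disease severity
and can fully account for an apparent disease signal. `deconfound`
implements a two-step framework to separate the two:

1. **Naive screen.** Every (feature, clinical variable) pair within a
   disease contrast is scored with a standardized non-parametric effect
   size — Cliff's delta with a two-sided Mann–Whitney rank-sum test for
   binary variables, Spearman's ρ for continuous ones — and
   Benjamini–Hochberg adjusted.
2. **Nested mixed-model deconfounding.** For each naively significant
   feature–label pair (Y, D) and each competing covariate C that is also
   naively significant for Y, three random-intercept models are fitted by
   maximum likelihood:

   ```
   rank(Y) ~ D     + (1 | subject)
   rank(Y) ~ C     + (1 | subject)
   rank(Y) ~ D + C + (1 | subject)
   ```

   Two likelihood-ratio tests follow: **Test 1** (full vs D-only) asks
   whether C explains variation beyond D; **Test 2** (full vs C-only)
   asks whether D retains explanatory power given C. If only Test 1 is
   significant, the Y–D association is statistically reducible to C
   ("confounded by C"); a significant Test 2 means it passes C. A feature
   that passes every competitor is labeled robust (`D`); otherwise it is
   `confounded: [...]`, `ambiguous`, or `NS`. The random intercept
   absorbs the correlation between repeated samples of one subject.

A third stage recycles the robust features of each omics space as
candidate explanatory variables for the features of the other spaces,
yielding a cross-omics association map (e.g. a cytokine–severity
association reducible to a metabolite) with the same two-test rule.

Because suitable cohort data are rarely shareable, the package ships a
first-class synthetic cohort generator with a *known confounding graph*:
repeated-measures metadata with severity-coupled clinical covariates,
zero-inflated compositional taxa counts, log-normal metabolite/cytokine
panels, and planted `direct`, `confounded`, `mediated` and `null`
effects, recorded in a ground-truth ledger so that recovery of the
classification can be scored.

## Worked example

```python
import numpy as np
from deconfound import (CohortSpec, CovariateSpec, EffectPlan,
                        ConfounderAnalysis, generate_metadata,
                        generate_features)

covs = (CovariateSpec("antibiotics", "binary", strength=0.625, base=0.2,
                      zero_in_controls=True, exact_counts=True),)
meta = generate_metadata(CohortSpec(n_controls=0, n_mild=22, n_severe=23,
                                    covariates=covs, seed=7))
plans = [EffectPlan("y_conf", "cytokine", "confounded", "antibiotics", 0.8),
         EffectPlan("y_dir",  "cytokine", "direct",     "severity",    0.8)]
tables, truth = generate_features(meta, plans, seed=7)

model = ConfounderAnalysis.from_tables(tables["cytokine"], meta,
                                       contrast="severity")
res = model.fit(fdr=0.05)
print(res.records[res.records["X_ind.var"] == "severity"])
```

prints

```
  Y_dep.var X_ind.var  XY_eff.size      XY_p.adj              AssocStatus
0    y_conf  severity     0.417984  8.652493e-04  confounded: antibiotics
2     y_dir  severity     0.673913  7.558897e-08                        D
```

Both cytokines are strongly severity-associated in the naive screen
(delta 0.42 and 0.67, adjusted p < 0.001). The nested-model stage then
separates them: `y_conf`, generated solely from antibiotic use (which is
coupled to severity at a point-biserial of ≈0.5), is reclassified as
confounded by antibiotics, while `y_dir`, generated from severity
itself, keeps its explanatory power in the presence of antibiotics and
is labeled robust (`D`).

## Command line

```bash
deconf run-all --outdir run --seed 1          # simulate -> ... -> integrate
deconf simulate --outdir sim
deconf preprocess --counts sim/gut_taxa_raw.tsv --depth 10000 --seed 1 \
    --out gut_log.tsv
deconf screen --features gut_log.tsv --metadata sim/metadata.tsv \
    --contrast severity --out screen.tsv
deconf deconfound --features gut_log.tsv --metadata sim/metadata.tsv \
    --contrast severity --out-prefix gut
deconf integrate --rundir run --contrast severity
```

`run-all` writes per-stage TSVs (metadata, raw and processed feature
tables, naive screens, association records, cross-omics edges, status
summaries) plus a `manifest.json` with output hashes and every numeric
decision in effect, and is byte-reproducible given the seed.

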