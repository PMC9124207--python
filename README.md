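# metsom

Metabolic subgrouping of cohort data with a self-organizing map (SOM),
subgroup-wise disease contrasts, and a permutation-null **enrichment
ratio** for cardiometabolic multimorbidity.

## The problem

Population cohorts carry dozens of correlated anthropometric and
biochemical measures per participant. Epidemiologists often want to go
beyond one-biomarker-at-a-time regression and ask: *which recognizable
metabolic phenotypes exist in this population, and how do whole phenotypes
relate to disease burden?* This package implements that workflow for
tabular cohort data (a participant table, a biomarker matrix and a long
event table of ICD-10-style diagnoses):

1. **Reduce** the biomarker panel: adjust for age and sex, compute
   pairwise-complete Spearman correlations, merge collinear variables
   (ρ² > 50%) into modules via connected components, and collapse each
   module to its first principal-component score.
2. **Map**: train a SOM — blinded to all health outcomes — that projects
   each participant's multivariable profile onto a two-dimensional canvas
   of districts, where proximity means similar profiles.
3. **Subgroup**: merge districts into mutually exclusive subgroups (an
   explicit, human-editable labeling; a seeded k-medoids proposer drafts
   one automatically).
4. **Contrast**: prevalent disease by logistic regression (odds ratios)
   and incident disease by Cox regression (hazard ratios, Efron ties),
   each subgroup versus a reference, adjusted for age, sex and assessment
   center; crude incidence per 1,000 person-years.
5. **Enrichment**: for the four cardiometabolic conditions (IHD, stroke,
   diabetes, hypertension), multimorbidity is a disease tally ≥ 2. The
   enrichment ratio is

   ER = P(tally ≥ 2, observed) / E[P(tally ≥ 2) under column shuffles],

   where the null shuffles each disease column independently, preserving
   every disease's frequency exactly. ER separates *co-occurrence beyond
   chance* from the mechanical rise in co-occurrence that follows from
   higher disease frequencies alone. One-sided permutation P-values and
   row-bootstrap confidence intervals are attached, overall and within
   strata (subgroups, or age split at the median). NCEP ATP III metabolic
   syndrome scoring (≥ 3 of 5 points) is included.

A fully seeded synthetic cohort generator (correlated biomarker blocks,
latent metabolic subgroups, logistic prevalence, exponential incidence
with a shared per-person frailty inducing co-occurrence) makes the whole
pipeline testable end-to-end without access-restricted data.

## Worked example

```bash
metsom run --out demo --seed 1
```

runs simulate → reduce → train → label → associate → enrich on the default
synthetic cohort (20,000 participants, 45 biomarkers in 12 blocks) and
writes CSV artifacts into `demo/`. The reduction collapses the panel to 28
SOM inputs (6 collinearity modules + 22 singletons, recorded in
`modules.json`). `enrichment.csv` then contains, for this cohort and seed:

```
stratum      kind  observed_prop       er  p_value   ci_low  ci_high
overall prevalent        0.03315 1.342966   0.0001 1.268886 1.414918
overall  incident        0.02345 1.311389   0.0001 1.223838 1.408430
```

Read: 3.3% of participants had ≥ 2 of the four cardiometabolic conditions
at baseline, 1.34× more than the 2.5% expected if the diseases co-occurred
by chance alone given their frequencies (permutation P = 1e-4, bootstrap
95% CI 1.27–1.42). The excess is the fingerprint of the shared frailty the
generator plants; per-subgroup and per-age-stratum rows of the same file
show how enrichment varies across the map. `contrasts_incident.csv` holds
the Cox hazard ratios of each subgroup versus the auto-selected
least-burdened reference subgroup, e.g. a strongly elevated diabetes
hazard in the liver/triglyceride-like subgroup.

Each stage is also callable on its own (`metsom simulate|reduce|train|
label|associate|enrich`, see `--help`) or from Python:

```python
from metsom import default_config, generate_cohort, enrichment_ratio
from metsom.outcomes import derive_disease_status, default_definitions, binary_panel

cohort = generate_cohort(default_config(10_000, seed=7))
dt = derive_disease_status(cohort.events, cohort.participants, default_definitions())
res = enrichment_ratio(binary_panel(dt, "prevalent"), n_perm=10_000, seed=7)
print(f"ER = {res.er:.2f}, P = {res.p_value:.2g}")   # ER = 1.27, P = 0.0001
```

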