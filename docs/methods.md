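# Methods

This note documents the statistical models and procedures implemented in
`metsom`, the design choices made where the design was genuinely open, and
what the synthetic cohort generator does and does not emulate.

## Analysis overview

The pipeline reproduces a metabolic-subgrouping workflow for prospective
cohort data:

1. **Panel reduction** (`preprocess`). Each biomarker is adjusted for age
   and sex, centered and unit-scaled. Pairwise-complete Spearman
   correlations are computed among the adjusted columns; variables whose
   squared rank correlation exceeds 50% are connected in a network, and
   each connected component with at least two members becomes a
   *collinearity module* that is collapsed to its first
   principal-component score. Module scores plus the remaining singleton
   variables form the training matrix (all columns mean 0, SD 1).
2. **Self-organizing map** (`som`). Batch Kohonen training on a circular
   district canvas, blinded to all health outcomes. Participants are
   assigned to best-matching districts; colorings show the smoothed mean
   Z-score of any variable per district.
3. **Subgrouping** (`subgroups`). Districts are grouped into mutually
   exclusive subgroups by an explicit district-to-subgroup labeling, which
   is an *input artifact* mirroring a human-consensus step. A seeded
   k-medoids proposer on the prototypes drafts a labeling for automated
   runs but is not the canonical procedure.
4. **Outcome contrasts** (`outcomes`). Events are matched to diseases by
   three-character ICD-10-style code prefixes. A first matching event at
   or before baseline is prevalent; after baseline, incident. Prevalent
   cases leave the incident risk set. Contrasts versus a reference
   subgroup are fitted one subgroup at a time: logistic regression (odds
   ratios) for prevalent disease, Cox proportional hazards (hazard ratios)
   for incident disease, both adjusted for age, sex and assessment center.
5. **Multimorbidity enrichment** (`multimorbidity`). Cardiometabolic
   multimorbidity is having ≥ 2 of {IHD, stroke, diabetes, hypertension}.
   The *enrichment ratio* (ER) is the observed multimorbid proportion
   divided by the proportion expected under a permutation null that
   shuffles each disease column independently (preserving every marginal
   exactly). P-values are one-sided permutation tail probabilities with an
   add-one correction; confidence intervals come from bootstrapping rows.
   NCEP ATP III metabolic-syndrome scoring (five components, positive at
   ≥ 3 points) is also provided.

## The permutation null and its sampler

A null replicate shuffles every disease column independently and records
the fraction of rows with tally ≥ 2. Because every column shuffle places
the column's `m_j` positives on a uniformly random subset of rows, the
statistic depends on the shuffled table only through the histogram of row
tallies, and that histogram evolves by a multivariate-hypergeometric split
when columns are added one at a time. The default sampler
(`method="tally"`) draws from exactly this chain, costing O(k²) per
replicate regardless of cohort size; `method="shuffle"` performs the
literal column permutation. The two routes are distributionally identical;
the test suite verifies their agreement and checks both against exhaustive
enumeration on small panels and against the closed-form independence
probability `1 − Π(1−p_j) − Σ_j p_j Π_{k≠j}(1−p_k)` at large n.

Conventions, chosen where the procedure admits variants:

- the "predicted" multimorbid count is the **mean** of the null
  distribution (the natural expectation; a median variant is a one-line
  change);
- the P-value is one-sided for enrichment, `(1 + #{null ≥ obs}) / (1 + B)`;
- stratified analyses (per subgroup, or age split at the median) compute
  each stratum's null from that stratum's own marginals, because
  subgroup-level ERs are only interpretable against subgroup-level
  frequencies;
- bootstrap CIs are percentile intervals, 1,000 replicates by default,
  each replicate with a 1,000-replicate inner null (both configurable);
  degenerate replicates (zero null mean) are dropped with a warning when
  they exceed 10%.

## SOM details

- **Topology**: concentric rings, ring k holding 6k districts, so radius r
  gives 1 + 3r(r−1) districts (default radius 5 → 61 districts). A
  rectangular grid is available as an alternative.
- **Training**: batch updates. Each epoch assigns rows to the
  best-matching district and replaces every prototype with the
  Gaussian-neighborhood-weighted mean of the rows. The kernel width
  shrinks linearly from radius/2 to the `smoothness` floor (default 2.0);
  smoothness is the *floor* of the neighborhood width, so larger values
  give a smoother, more conservative map. Prototypes are initialized from
  a seeded sample of distinct data rows. Batch training (rather than
  online) makes runs deterministic for a given seed.
- **Missing data**: distances rescale observed squared deviations by
  D/d_observed so sparse rows remain comparable; prototype updates average
  per input over observed entries only. Rows with zero observed inputs are
  excluded and reported.
- **Quantization error** is logged per epoch; on realistic inputs it is
  non-increasing from first to last epoch (asserted as ≤ in tests, since
  batch updates do not guarantee strict monotonicity step by step).
- **Coloring amplitude**: the across-map SD of district values is recorded
  as the color-intensity scale. This is a pragmatic stand-in for
  "contribution to map structure", which has no published formula.

## Outcome modelling conventions

- Cox fits use Efron tie handling and Wald intervals (lifelines);
  logistic fits use maximum likelihood with Wald intervals (statsmodels),
  with a BFGS retry if Newton iterations fail to converge.
- Assessment center enters as a categorical fixed effect
  (dummy-encoded); the adjustment model is linear in age plus a sex
  indicator, with no quadratic age term.
- Each non-reference subgroup is compared to the reference in its own
  two-group model rather than one joint model with all indicators.
- Default disease code lists (IHD I20–I25, stroke I60–I64, diabetes
  E10–E14, hypertension I10–I15, dementia F00–F03 + G30, rheumatoid
  arthritis M05–M06, cancer C00–C97) are editable YAML configuration and
  deliberately approximate; curated register phenotypes should replace
  them in real analyses.
- Follow-up ends at the earliest of the administrative censor date, the
  participant's own follow-up end and death; death is treated as
  independent censoring, not a competing risk, since each endpoint is
  modelled separately.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable without
restricted data. It emulates the *structural* features the analysis relies
on, with defaults fixed once:

- n = 20,000 participants by default; ages truncated-normal N(57, 8²) on
  [37, 73]; 53% women; 10 assessment centers; baseline dates 2006–2010.
- 45 biomarkers in 12 equicorrelated blocks: six tight blocks (within-
  block ρ = 0.85; 23 markers) that the ρ² > 0.5 rule collapses into six
  modules, and six loose blocks (ρ = 0.30; 22 markers) that remain
  singletons — 28 SOM inputs, emulating the reduction of a ~51-marker
  panel to ~33 inputs. Two blocks pass through a log-normal transform to
  mimic skewed biochemistry; the pipeline consumes ranks and Z-scores, so
  Spearman structure is transform-invariant.
- Six latent subgroups with block-level mean shifts echoing recognizable
  metabolic phenotypes (high apoB + blood pressure; liver/triglyceride;
  adiposity + inflammation + kidney stress; favorable high-HDL reference;
  hormonal; high urinary excretion).
- Prevalent disease from a logistic model and incident disease from
  exponential hazards, both with per-subgroup effects (including a very
  large diabetes hazard in the liver-like subgroup) and a shared
  per-person normal log-frailty (SD 0.5 by default) multiplying all odds
  and hazards — the mechanism that produces co-occurrence beyond
  independence.
- Follow-up uniform on (9.8, 11.8) years, giving a mean administrative
  follow-up of 10.8 years; independent exponential death process with
  hazard 0.0058/year (~6% deaths over follow-up); 3%
  missing-completely-at-random biomarker mask to exercise the missing-data
  paths.
- Physical-unit measures for MetS scoring (waist, triglycerides, HDL,
  blood pressures, glucose, antihypertensive-use flag) are derived from
  the latent block factors and written as a separate table so the SOM
  panel keeps its 45-marker structure.

What the generator does **not** emulate: real marginal distributions of
any specific assay panel, center-level geography, medication effects on
biomarkers, competing risks, or informative missingness. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not epidemiological validity on any particular
cohort.

## Numerical choices and degenerate inputs

- Spearman coefficients use average ranks for ties and per-pair
  re-ranking on pairwise-complete rows; pairs with < 3 complete rows are
  excluded from the network with a warning.
- The ρ² > 0.5 edge rule is strict; ρ² is rounded to 12 decimals first so
  a correlation of exactly √0.5 sits on the boundary and is excluded.
  Connected components at a single fixed threshold coincide with
  single-linkage agglomeration, which is the minimal reading of
  "agglomerative module detection".
- PC scores are oriented so they correlate positively with the member
  carrying the largest absolute loading (ties alphabetical); partially
  observed rows project observed loadings rescaled by √(m/m_obs);
  all-missing members are dropped with a warning.
- Zero-variance columns, unlabeled occupied districts, empty subgroups,
  outcomes with no cases, and strata with no events are reported as named
  errors or non-estimable rows rather than silent results.
- All randomness flows from one integer seed; pipeline stages derive
  independent substreams via SHA-256 of (seed, stage name). Two runs with
  the same configuration and seed produce byte-identical artifacts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use simulation sizes chosen to
make the statistical assertions sharp while keeping a full run of either
well under a quarter of an hour on one CPU: cohorts of 2,000–20,000
participants, 50,000-row panels for independence checks, 50 replicates for
CI-coverage checks, 10,000 permutation replicates where an enumeration
oracle is compared, and 1,000–2,000 otherwise.

## Known limitations

- The district labeling proposer is a convenience; the canonical subgroup
  boundaries are a human decision and the package treats them as input.
- The enrichment bootstrap resamples rows only; it does not propagate
  uncertainty in the subgroup assignment itself.
- The color-intensity "amplitude" is a recorded scale, not a claim about
  any particular visualization package's internal weighting.
- Logistic/Cox contrasts assume the usual large-sample Wald behavior;
  sparse strata are reported as non-estimable rather than penalized.
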