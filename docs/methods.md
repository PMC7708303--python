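# Methods

## Overview

`phenochron` analyses longitudinal EMR diagnosis data for time-resolved
gene–phenotype associations. The analysis chain is: ontology-based
harmonization of provider diagnosis codes, ancestor propagation, age
binning conditioned on per-individual EMR-usage windows, per-bin Fisher
exact contingency testing per (gene, phenotype term) pair,
max-over-time selection, and Benjamini–Hochberg (BH) FDR control. This
note records the model, the choices made where the design was open, the
synthetic-data generator's assumptions, and known limitations.

## Ontology handling

Only `is_a` edges of the OBO input are traversed; all other relationship
types are ignored, treating the ontology as a subsumption DAG. Obsolete
terms are dropped at load time; `alt_id` accessions resolve silently to
their primary id (logged at debug level). The loader requires a single
root and rejects cycles and `is_a` references to undeclared terms.

*Root handling.* Ancestor closure and propagation exclude the ontology
root ("All"): it would be present for every individual with any mapped
encounter and carries no information. High-level sub-roots such as
"Phenotypic abnormality" are retained — high-level terms are part of the
analysis vocabulary, and their near-universal presence makes them
effectively untestable rather than misleading.

*Modifier branches.* Terms under "Clinical modifier" (HP:0012823) and
"Clinical course" (HP:0031797) describe severity, quality, or onset of a
phenotype rather than a phenotype, and are excluded from association
testing. The branch roots are configuration; these two are the default.

## ICD-prefix neurology filter

Rows are restricted to neurological diagnoses before mapping using only
the ICD string: closed letter ranges F00–F99, G00–G99, Q00–Q07, R25–R29,
R40–R49 evaluated on the letter plus first two digits, stem codes P90,
R56, R62, R90 matching themselves or any dotted extension, and R94.01
matching exactly. This reproduces the inclusion list without an external
ICD table. ICD9 or site-specific codes can be supplied as an extra stem
list. Unparseable codes are excluded (logged).

## Usage windows and binning

An individual's EMR-usage window is the closed interval between their
first and last documented encounter of any kind — administrative contacts
count, since any contact demonstrates usage — and usage is assumed
uninterrupted within it. Ages are binned on half-open intervals
`[k·w, (k+1)·w)`; the default grid is w = 0.25 years over 0–25 years,
i.e. 100 bins. Bin width is configurable (the grid must divide evenly).

Numerical conventions:

- A window touching a bin only at the bin's left edge counts as
  intersecting, so a single-encounter individual is informative in
  exactly one bin.
- Encounter ages ≥ 25 years are excluded from binning but still extend
  the window, which is clipped to the grid for intersection. (Whether to
  clip or to drop such individuals entirely was open; clipping retains
  their earlier observation time.)
- Presence states: per (individual, bin), the union of the propagated
  term sets of all encounters in the bin, deduplicated. Bins inside the
  window with no mapped encounter are `absent` for every term; bins not
  intersecting the window are `not applicable` for every term. The tensor
  is closed under ancestor propagation by construction.

## Association testing

At bin b, for gene g and term t, the 2×2 table counts carriers of g
(causative-gene column equals g) versus all other informative individuals
— including those with no genetic diagnosis — split by presence of t.
Counts are restricted to individuals informative at b.

- *Two-sided Fisher exact test*, minimum-likelihood convention: the
  p-value sums hypergeometric point probabilities of all tables at most
  as probable as the observed one (relative tolerance 1 + 1e−7), as
  implemented by `scipy.stats.fisher_exact`. The test suite verifies
  agreement with exhaustive enumeration to 1e−12 on 500 random tables.
  Any zero margin admits a single table and yields p = 1.
- *Max-over-time selection*: `p_gxp_max` is the minimum p over bins with
  at least one informative carrier. Bins with no informative carrier are
  undefined (not p = 1), so they do not dilute the selection. Ties break
  to the earliest bin, for determinism.
- *FDR control*: BH step-up at q = 0.05 (statsmodels `fdr_bh`) over the
  family of all tested pairs' `p_gxp_max` values — genes with ≥ 2
  carriers × non-modifier terms present in the tensor, including pairs
  with `p_gxp_max` = 1 (conservative for rejections). Applying BH after
  per-pair max-selection makes the nominal per-pair p anticonservative;
  the procedure controls FDR over the max-selected family as specified,
  and no selection adjustment beyond BH is attempted.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
calibrated to published childhood-epilepsy cohort characteristics. It is
the basis of all tests; no patient data are used anywhere.

**Usage windows.** First-encounter age ~ Uniform(0, 5) years; follow-up
duration ~ lognormal with median 6.9 years (σ = 0.6), truncated so
windows end by age 25. The realized window equals the drawn one: the
first and last encounters sit at its edges.

**Encounters.** Poisson numbers of encounters at 19 per patient-year —
the rate implied by ~62,000 encounters over ~3,250 patient-years in
EMR cohorts of this kind — plus extra contacts below age 2 (total ≈ 32
per patient-year in infancy), matching pediatric contact schedules.
Encounters with no emitted diagnosis are retained as administrative rows
so windows stay faithful.

**Diagnosis emission.** The ~50-code codebook distinguishes two modes,
mirroring how problem lists behave:

- *Event codes* (status epilepticus, febrile convulsions, infantile
  spasms, abnormal EEG …): independent Bernoulli per encounter with an
  age-windowed baseline probability.
- *Chronic codes* (epilepsy problem-list entries, intellectual
  disability, ADHD, motor disorders …): a per-encounter onset hazard
  active in a bounded onset window — chronic diagnoses are established
  within a few years of symptom emergence — after which the code is
  re-documented at each visit with probability 0.9 (0.35 for the
  near-universal "Seizure disorder" entry) while its age range remains
  active. Ranges encode natural history: absence seizures remit by 14,
  global developmental delay hands over to intellectual disability at 5,
  ADHD is coded at school age.

An earlier fully independent per-encounter model was rejected during
design: without the temporal persistence that real problem lists
exhibit, the 100 per-pair tests behave as ~100 quasi-independent looks,
and BH applied after max-selection cascades — null cohorts produce
wholesale spurious rejections that real EMR analyses of this design do
not show. Persistence restores the strong bin-to-bin correlation of real
data; the event/chronic split keeps acute diagnoses time-localized.

**Genotypes.** 36 causative genes: the five most common etiologies at
their published cohort shares (SCN1A 29/658 … KCNT1 6/658), a tail of 31
rarer genes at ~5/658 each, and ~65% of individuals without a genetic
diagnosis.

**Planted effects.** A planted effect multiplies the odds of one code's
per-encounter probability (event) or onset hazard (chronic) for carriers
of one gene within an age interval. The truth record (per-individual
genotype and window, effect definitions) is written alongside the tables.

**Reproducibility.** All randomness flows from one seed through a single
`numpy` Generator in documented draw order; identical seeds give
byte-identical outputs.

**Recovery scenario.** The standard parameter-recovery experiment
(`recovery_config`) plants OR = 20 on "Status epilepticus" in SCN1A
carriers over ages 0.5–1.25 years (bins 2–4) in a 300-individual cohort,
with the planted gene enriched to 25% of individuals. The enrichment is a
designed choice, not a claim about cohort composition: with uniform
first-encounter ages only ~25% of carriers are informative in infancy
bins, and the BH family of ~1,100 pairs puts the rank-1 rejection
threshold near 4e−5, so ~15 informative carriers are needed for the
planted association to be reliably detectable. Measured over 90 seeds,
the planted pair is the study's unique FDR-significant association with
its most significant bin inside/adjacent to the planted window in ~90%
of runs; failures split between under-powered draws and a second pair
crossing the step-up threshold by chance.

**What passing tests do and do not show.** The generator reproduces the
pipeline's assumed structure — windows, binning, propagation closure,
carrier/non-carrier exchangeability under the null — but not real-data
features such as provider coding bias, informative presence/absence of
care (sicker children are seen more), comorbidity correlations between
codes, gaps in usage windows, or negated diagnoses. Passing recovery and
null tests therefore validate the statistical machinery, not robustness
to those biases.

## Problem sizes

Default test and acceptance runs use 300-individual cohorts (~40,000
encounter rows), 100 bins, ~50 ontology terms and ~20–25 testable genes
(~1,100 pairs, ~70,000 Fisher tests per study, memoized across repeated
tables). Twenty seeded recovery runs plus twenty null runs complete in a
few minutes on one CPU.

## Known limitations

- EMR usage is assumed uninterrupted between first and last encounter;
  no gap detection.
- Negated phenotypes ("no seizures since …") are not modeled; absence is
  inferred only from non-documentation inside the usage window.
- The BH family treats max-selected p-values as ordinary p-values; no
  max-selection adjustment is attempted beyond the family-level FDR.
- The ICD filter is prefix-based and ICD10-shaped; ICD9 support is via a
  user-supplied stem list only.
- Dates of birth and calendar time are out of scope; ages are inputs.
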