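# Methods

This note records the modelling and design choices behind `adscreen`: what
each component computes, which parameters matter, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely open.

## Screening algorithms

### Base algorithm

The base algorithm operates on the ML-flagged T2D members of a cohort and
excludes on six criteria, evaluated as a joint predicate with every violated
criterion recorded per patient: HDL ever below 50 mg/dL, triglycerides ever
above 150 mg/dL, BMI ever above 30 kg/m², fewer than three normal-range BMI
records, cystic fibrosis codes (ICD-9 `277.0x`, ICD-10 `E84.*`, prefix
match, configurable), and any positive islet antibody.

Choices worth making explicit:

- **Strict comparisons.** All thresholds use strict inequality, matching the
  "less than"/"greater than" phrasing of the criteria; a triglyceride value
  of exactly 150 survives. Tests pin this boundary behaviour.
- **"Normal BMI" = ≤ 30 kg/m².** The engagement criterion counts BMI records
  at or below 30 rather than inside the 18.5–24.9 normal-weight band. The
  criterion's purpose is to ensure reliable engagement with the healthcare
  system, not anthropometric normality, and the > 30 exclusion already
  removes obese-range evidence. A stricter band is available via
  `bmi_normal_floor`/`bmi_normal_ceiling`.
- **Missing labs pass.** A patient with no HDL or TG measurements is not
  excluded by the metabolic criteria — absence of evidence is not evidence
  of metabolic syndrome. Only the BMI-count criterion enforces data
  sufficiency.
- **Joint predicate, sequential reporting.** Whether the original filters
  were applied sequentially or jointly is not recoverable; the joint
  predicate with per-criterion tagging subsumes both readings, and
  `FilterResult.attrition_rows()` derives a sequential CONSORT-style view by
  charging each patient to the first criterion (in the fixed order
  metabolic-HDL, metabolic-TG, metabolic-BMI, engagement, CF, antibody) that
  excludes it.

### Branch algorithms

The six branches run independently over the same base-kept input (they are
alternative T1D filters producing overlapping cohorts, not a chain).
Branch 1 keeps patients with at least one antibody test on record and no
positive result; whether the full three-antibody panel should be required is
not specified anywhere, so the default is "any ≥ 1 documented negative,
zero positives". Branches 3 and 4 read a small drug-name → class vocabulary
(unknown names map to class `other` with a warning, never an error) and
accept an optional exposure-cutoff date because GLP-1 RA and SGLT2i became
common outside T2D after early 2020; the default is no cutoff.

### Chart-review rule engine

The expert review being approximated is inherently a consensus judgement;
the engine is a deterministic, data-driven approximation whose rule order is
an explicit choice (callers can reorder or edit the `ClassifierRules` list
without code changes):

1. positive MODY genetic test → MODY;
2. positive antibody with youth onset (< 20 y) and insulin dependence from
   onset → typical T1D, otherwise → LADA/autoimmune;
3. pancreatic disease before diagnosis → pancreatic-secondary;
4. chronic steroid exposure **at diagnosis** → steroid-induced (current
   steroid use alone does not fire the rule; one roster case is on
   prednisone yet remains AD/MARD under this reading);
5. metabolic features at diagnosis → typical T2D;
6. youth onset + insulin from onset + low C-peptide → typical T1D;
7. MODY-suspicious (onset < 35 **and** multigenerational family history)
   without genetic testing → NMI requiring MODY testing;
8. any required chart field undocumented → NMI with the missing fields
   listed; required by default: (antibody **or** C-peptide status
   documented), age at diagnosis, metabolic-features-at-diagnosis;
9. default → AD.

Because positive rules only fire on documented-true facts, removing
documentation can never move a case from AD to a not-atypical category —
only to NMI. This monotonicity is property-tested. The required-field set
in rule 8 is a documented choice: the source material lists examples of
NMI-triggering gaps, not an exhaustive set.

`metabolic_features_at_dx` is derived from the documented BMI at diagnosis
(> 30 → true, ≤ 30 → false, undocumented → null); the chart model carries
no separate metabolic-syndrome-at-onset field.

### Subtype classifier

KPD takes precedence: documented adult ketosis without positive antibodies
and without long-term insulin need. MARD requires onset strictly after 60
(the "soft cutoff" is implemented as strict `>` because the roster case
diagnosed at exactly 60 carries the ISNM label; softness is exposed via
`mard_age_cutoff`), maximum recorded HbA1c strictly below 8%, at most two
non-insulin glucose-lowering drug classes, no long-term insulin, and at
least five years of observed course. "Consistent HbA1c < 8%" is read as the
maximum over all recorded values; a windowed variant is configurable. Ages
recorded only as "X or earlier" are evaluated at the bound X and flagged.
The non-insulin medication count is distinct drug *classes*, not
prescriptions; steroids and non-diabetes drugs never count.

## The roster fixture

`data/case_roster.csv` transcribes the sixteen confirmed atypical cases
(sex, current age, age at diagnosis with two upper-bound entries, BMI and
HbA1c ranges, regimen, family history) plus the adult-ketosis indicator,
true only for the case documented as ketosis-prone. Conventions the source
table does not state, chosen once and fixed:

- all sixteen carry documented negative antibody testing (their confirmation
  as atypical required antibody evidence); C-peptide is documented
  normal-or-high only for the β-cell-positive KPD case;
- metabolic features at diagnosis are documented absent (every BMI range is
  non-obese);
- observation span = current age − age at diagnosis;
- a family history naming a parent or uncle is coded multigenerational; a
  sibling-only history is not.

The published pattern labels ride along in a separate column and are held
out of the classifier path; tests compare against them.

## Synthetic cohort generator

The generator is the package's test bed: a seeded population of latent
archetypes (non-diabetic 92.97%, typical T2D 5.86%, typical T1D 0.63%, LADA
0.40%, MODY-like 0.10%, and the three AD phenotypes at 0.014% each) with
longitudinal labs, BMI trajectories, medication exposures, antibody-testing
behaviour, diagnosis codes, chart facts, and curated-phenotype flags. With
the default flag parameters the ML-T2D flag rate lands near 6.2% of the
cohort, the composition the screen was designed against. AD prevalence can
be raised for statistical power; every distributional detail is an artifact
choice (the underlying biobank's lab distributions are not public) and lives
in `default_archetypes()` where it can be overridden wholesale.

Deliberate simplifications:

- **i.i.d. lab draws.** Trajectories are independent draws around archetype
  means with no autocorrelation or secular trend: the filters read only
  extrema and counts, so temporal structure would change nothing they see.
- **Constructive base-pass guarantee.** AD archetypes draw HDL clipped to
  ≥ 50, TG ≤ 150, BMI ≤ 30 with at least three records, no CF codes, and
  never a positive antibody, so every AD patient with favourable ML flags
  survives the base algorithm by construction. This is what makes planted
  recovery a sharp test: a planted case that fails the funnel indicates a
  filter bug, not generator noise.
- **Flag noise via confusion-structure inversion.** Flags are drawn by
  inverting the stated (sensitivity, PPV/NPV) against latent truth; the
  algebra is in the `synthetic_cohort` module docstring. The T2D flag's
  reference population is the whole cohort. The two T1D flags are
  calibrated **within the diabetic subpopulation**: at a whole-cohort T1D
  prevalence of 0.63%, a rule-out NPV of 0.99 would sit *below* the
  no-skill baseline of 99.37% and is unattainable, whereas among patients
  with diabetes (T1D share ≈ 9%) it is a meaningful target — matching how
  such flags are validated in practice, on charts of patients known to have
  diabetes. Non-diabetic patients trivially receive the rule-out flag.
  A side effect of hitting NPV = 0.99 exactly is that roughly half of
  unflagged true-T1D patients are also "ruled out"; that is what the stated
  operating point implies at this prevalence.
- **Chart-fact missingness** is injected independently per field at a
  default rate of 0.13, chosen once to put the NMI fraction among reviewed
  candidates near the ~13% reported for real chart review.

What passing tests on this generator do **not** show: robustness to
correlated missingness, to coding-practice drift over time, to unmapped
medication names at scale, or to ML flags whose errors correlate with the
very phenotype being screened — all properties of real EHRs that the
generator does not emulate.

Planted cases (`plant_cases`) are materialised from a requested chart-review
summary and verified by re-deriving the summary from the built record;
unsatisfiable requests (e.g. an HDL of 49 on a record that must survive the
base algorithm) raise instead of silently degrading.

## Polygenic scoring

Raw score = Σ dosage × weight over the weight set; every weight variant must
be present in the matrix. Missing dosages contribute the cohort-mean dosage
for their variant (standard scoring-software behaviour; `"zero"` is
available). The minimum-to-zero shift for T2D genome-wide scores is exactly
`x − min(x)` — idempotent and rank-preserving. Centiles count the fraction
of the reference strictly below the score, rounded to 0–100; ties count none
of themselves, so the reference maximum maps to `round(100·(n−1)/n)`.

Variant QC thresholds default to: missing call rate > 0.05, MAF < 0.01, HWE
exact-test p < 1e-6, case/control missingness difference > 0.02. The source
method names these filters without numbers; the defaults are the field's
conventional values and sit in `VariantQCConfig`. The HWE test is the exact
conditional test on hard-called genotypes (dosages rounded for the test
only), implemented in-package because no installed dependency provides it;
tests check it against an independent factorial-form computation of the
conditional pmf. Ancestry restriction is honoured as a metadata filter;
inferring ancestry (PCA or otherwise), phasing, imputation, and posterior
weight estimation are out of scope — published weights are consumed as
input.

## Statistics

Quantiles use linear interpolation at positions 1 + (n−1)p (numpy `linear`,
R type 7) — the convention under which the sixteen roster cases' current
ages reproduce the published age summary exactly. The Wilcoxon rank-sum
test enumerates the full combination null distribution (midranks for ties)
when n₁+n₂ ≤ 12 and otherwise uses the normal approximation with tie and
continuity corrections; Kruskal-Wallis is tie-corrected H against
chi-square(k−1). Categorical variables are integer-coded and compared with
the rank test by default — unconventional, but it mirrors the comparison
tables this module reproduces; a chi-square alternative sits behind a flag.
No multiple-testing correction is applied by default, again mirroring the
reproduced analysis; a flag exists.

One derived check is deliberately soft: the published diagnosis-age IQR
(46.5–66.0) is reproduced only under the reading that keeps the "62 or
earlier" entry and drops the "70 or earlier" one, while the median of 58 is
stable under either handling of bounded ages. The handling of upper-bound
ages in the source summary is ambiguous, so the IQR check is documented as
an interpretation, not a hard target.

## Problem sizes and numerical conventions

Default test problem sizes — 10,000-patient cohorts for oracle-equivalence
checks, 20,000 for flag-calibration checks, 1,000 random mini-cohorts for
the branch subset laws, 10,000 permutations for the Kruskal-Wallis null
check — were chosen to keep the full suite under a minute of generator time
while leaving binomial confidence intervals tight enough to be meaningful.
Dates are handled at day resolution; year-only dates map to July 1 (only
ordering matters downstream). Same-day ties in "most recent" extraction
break toward the larger value so reports are reproducible. Entity-table
writes sort rows by (patient_id, date, …), making repeated writes
byte-identical.

## Known limitations

- The rule engine cannot reproduce expert-consensus nuance; it is a
  transparent approximation whose disagreements with human review
  concentrate in the NMI boundary.
- Drug-class resolution covers common generics/brands only; production use
  against a real formulary requires extending the vocabulary table.
- The comparison module always reports full median/IQR per group even where
  a source table printed a bare median.
- No HL7/FHIR/OMOP ingestion, no NLP over notes, no VCF parsing: entity
  tables and dosage matrices are the interchange surface.
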