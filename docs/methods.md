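# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable reading existed.

## Terminology and code lists

A code list is the curated unit of a phenotype: codes from one of five
terminologies (Read, ICD-9, ICD-10, OPCS-4, drug codes), each classified
into one of three non-overlapping ascertainment categories — *prevalent*
(condition pre-dates the record), *possible* (suggestive, non-diagnostic)
and *incident* (new diagnosis, optionally sub-typed).  Subtypes are carried
as free text rather than a taxonomy.  Search over a term dictionary is
case-insensitive substring matching by default with an optional whole-word
mode; synonym strategies are modelled as pattern lists, not as thesaurus
lookups.  Results are ordered by (terminology, code) so that search is
invariant to dictionary order.

Two independent annotations over the same term set are merged into a
consensus mapping plus a disagreement list for third-party adjudication;
the two outputs always partition the term set.

The on-disk format is UTF-8 text: `#key: value` header lines for five
mandatory metadata keys (name, version, authors, timestamp, terminology)
followed by a tab-delimited table (code, description, category, subtype).
The format is line-oriented and diff-friendly, so lists version cleanly in
git; write→read is the identity (property-tested with randomized lists).

## Synthetic linked extracts

The generator emulates the *statistical structure* the validation suite
depends on, not disease natural history:

* **Capture patterns.** Each true case draws, per event, a subset of
  {primary, hospital, registry, death} from a configurable multinomial.
  Per-event (rather than per-lifetime) drawing keeps concordance analysis
  well-defined.  The default multinomial is (primary-only 0.26,
  primary+hospital 0.27, hospital-only 0.34, death-only 0.13) — a
  heart-failure-like recording profile in which a substantial share of
  disease is visible only in hospital data or only at death.
* **Date offsets.** Each captured source records the event at the case's
  event date plus a discretized normal offset (default mean 0, sd 10 days,
  truncated at ±365), so 30/90-day concordance windows are straddled by a
  realistic minority of records.
* **Miscoding.** With configurable probability a recorded diagnosis is
  replaced by a look-alike non-case code, so single-source cases can be
  missed by a definition; the default is 0 (clean recording).
* **Structure fidelity.** Hospital episodes carry up to 20 diagnosis
  positions (the case code lands in position 1 with probability 0.8, else a
  random later position) and sparse OPCS-4 procedures; death records carry
  an underlying cause plus up to 14 secondary causes, ICD-9-coded before
  2000-01-01 via a shipped ICD-10↔ICD-9 equivalence for the toy codes;
  background mortality follows age-band annual rates (defaults 0.002 /
  0.01 / 0.05 for ages <50 / 50–70 / 70+).
* **Pathologies on demand.** Practice recording gaps, practice death
  under-recording, GP-vs-certificate death-date discrepancies, patient-level
  acceptability defects (assigned to disjoint patient subsets so detectors
  can be checked against bookkeeping), and measurement contamination
  (wrong-scale ×10 values under the canonical unit label, alternative-unit
  and unknown-unit fractions, zero inflation, malformed date strings).

All randomness flows from one `numpy.random.Generator(seed)`; a config+seed
pair reproduces the extract byte for byte.  Toy dictionaries (~50 codes per
terminology) stand in for licensed Read/ICD dictionaries; they are synthetic
and shaped for desk-scale testing.  Ground truth (case status, drawn
pattern, injected defects, discrepancy days) is recorded in a `truth` table
so tests compare pipeline output against what was planted.  The generator
does **not** model comorbidity structure, seasonality, practice-level
geography, or informative censoring — so passing tests demonstrate that the
pipeline recovers planted structure, not that it would be accurate on any
particular real population.

All date columns are ISO-8601 strings end to end; malformed dates are data,
not errors, until a quality rule classifies them.

## Data quality

**Acceptability.** Each patient gets one result listing every violated rule:
missing registration, registration before birth, invalid gender, malformed
date, date after the last collection date, and non-continuous follow-up
(operationalized as a later registration period starting after the previous
one ended).  A patient is accepted iff no rule fires.

**UTS date.** Practice recording quality is judged by two detectors on the
daily event-count series: gap analysis (a pause longer than `gap_days`,
default 90; the gap date is the day after the last such pause ends) and
death-recording analysis (a rolling `window_days`, default 365, window in
which observed deaths fall below `death_ratio_min`, default 0.5, of the
expected count `reference_death_rate × person-time`; the death date is the
end of the last flagged window).  The UTS date is the latest of the two
detector dates, else the first recording date.  The real registry's
algorithm is unpublished; these parameters are exposed in config rather than
fixed, and the defaults make both detectors transparent and testable.  Note
the death detector's date is the end of the last *window* that still looks
under-recorded, which trails the end of the under-recording itself by up to
half a window — conservative in the right direction.

**Measurement harmonization.** Per value: (1) convert the recorded unit to
the canonical unit when a factor is configured, else status `unit_unknown`;
(2) zero semantics per analyte — an impossible zero (e.g. ferritin) becomes
`zero_missing`, a plausible zero (e.g. basophils) is a true value; (3) if
the value is outside the valid range and scale correction is enabled, try
÷10 and ×10 — exactly one candidate in range is adopted with status
`rescaled` (the g/L-vs-g/dL pathology); (4) anything still outside the range
is kept with status `out_of_range`, never dropped.  With a two-sided valid
range the two factor-10 candidates can never both be in range for an
out-of-range value, so the `ambiguous` flag column is a structural guard
that stays False; it is retained because custom policies may later allow
asymmetric correction.  Harmonization is idempotent on its own clean output,
and no value with status valid/rescaled/converted ever lies outside its
range (property-tested).

## Phenotyping engine

A definition is a set of named components — per-source code sets (with a
diagnosis-position rule for hospital data and an underlying-vs-any cause
rule for death certificates), measurement threshold rules (`≥ k` qualifying
values, optionally within a day window), prescription count rules — combined
by a boolean expression with AND/OR/NOT, parentheses and `at_least(k, …)`.
There are deliberately no temporal sequencing operators beyond the
within-window counts: the exemplar composite definitions (e.g. hypertension
from blood-pressure values, coded diagnoses and antihypertensive
prescriptions) do not need them, and a full temporal logic would multiply
the audit surface.

Execution rules:

* a coded component is satisfied only by at least one event whose category
  is not *possible*; possible-coded events are recorded as supporting
  evidence but never make a case on their own;
* the index date is the earliest non-supporting qualifying event across
  satisfied components; for count rules the qualifying date is when the
  count completes (the k-th occasion), since the criterion is not satisfied
  before then;
* category is assigned by precedence over qualifying events' categories
  (default incident > prevalent > possible, reflecting ascertainment
  strength);
* subtype comes from the highest-precedence source carrying a label
  (source precedence is per-definition; primary care usually carries the
  most clinically resolved labels);
* equal dates across sources: all tied sources are listed, subtype falls
  back to source precedence;
* death dates are reconciled with the certificate as gold standard; the
  GP-recorded date is used only when no certificate exists, and the
  discrepancy in days is reported when both are present.

Adding events can never turn a case into a non-case (monotonicity — the
grammar applies NOT only to component satisfaction, and satisfaction itself
is monotone in events; property-tested).

The dissemination document renders metadata, per-source logic, a pseudocode
block and attached validation evidence; the logic line parses back to an
AST equal to the definition's (parse→render→parse identity).

## Validation suite

* **Concordance** anchors the window at each case's earliest record — a
  deterministic, order-independent choice — and reports pattern counts
  (which partition the case set), per-source counts, and k-or-more-source
  counts, each as one-decimal percentages.
* **Diagnostic accuracy** uses Wilson score intervals by default: at the
  study sizes involved Wilson and Wald agree to one-decimal percent, and
  Wilson degrades gracefully near 0/1 where specificity estimates live.
  Zero-denominator metrics are reported absent with a reason.
* **Kaplan–Meier** and **Cox** (Breslow ties, Newton-type maximization of
  the partial likelihood) are fronted by lifelines; the test suite checks
  them against independent hand-written oracles (risk-set products; grid
  search of the Breslow partial likelihood) and simulation (CI coverage for
  a true HR of 2, null-covariate false-positive rate).  Complete separation
  is detected heuristically (|coef| or se blowing past 50) and raised as a
  convergence error with diagnostics.  Age/sex adjustment is by covariates,
  not stratification.
* **Etiology** emits a comparison table of fitted HRs against user-supplied
  reference estimates with CI-overlap flags; it does not auto-judge
  consistency.
* **Genetic replication** takes a table of signed effects and replication
  p-values (association testing itself is out of scope), applies the
  Bonferroni threshold α/m and the direction-concordance requirement, and
  flags zero effects as direction-undefined.
* **External populations** re-runs generate→phenotype→concordance/accuracy/
  survival on two generator configs under one definition and reports side by
  side; supplying different definitions is an error.

## Problem sizes and determinism

The test suite uses cohorts of 500–50,000 patients, chosen so each check has
the statistical resolution it needs (law-of-large-numbers checks at 50,000;
pattern-recovery at the full 89,554-case scale in the acceptance path) while
the whole suite stays quick on one CPU.  Simulation-based checks fix their
seeds; statistical assertions use 3-standard-error bands (binomial) or
explicit coverage bounds with documented binomial slack.

## Known limitations

Free-text extraction, probabilistic/ML phenotyping, OMOP/FHIR export and
true GWAS computation are out of scope.  The generator's independence
assumptions (sources independent given the pattern; offsets i.i.d.) are
idealizations; real inter-source dependence would move windowed concordance
in ways the toolkit measures but the generator does not reproduce.
Cohort-scale published quantities (e.g. mortality HRs near 7 for heart
failure) require restricted real data and are not reproduced here; the
estimators that would compute them are validated against oracles instead.
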