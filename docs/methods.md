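# Methods

## Design

`pvsignal` implements a cross-sectional case/non-case disproportionality
analysis over a spontaneous-report database restricted to serious
reports carrying at least one anticancer (ATC L01) drug in any role
(suspect, concomitant or interacting). For each event definition — a
Standardised MedDRA Query (SMQ) applied at narrow scope — a report is a
*case* when at least one of its preferred terms is in the query's
narrow set, and a *non-case* otherwise, including reports matching other
cardiovascular queries. For each index drug (one of the five CML TKIs,
or the pooled TKI class), the comparator is every anticancer report not
exposed to that index drug; a report exposed both to the index drug and
to other anticancer drugs counts once, in the index margin.

The analysis set is produced by an order-fixed funnel:

1. **Seriousness** — keep reports with ≥ 1 recorded outcome
   (death, life-threatening, hospitalization, disability, required
   intervention, congenital anomaly, other serious); a report is
   serious exactly when this set is nonempty.
2. **Deduplication** — first keep the highest version per case
   (follow-ups supersede), then collapse reports identical on the
   five-field key (sorted set of case-folded event terms, earliest event
   date, age in years, sex, country). Missing dates match only missing.
   The representative kept is the lexicographically smallest report id —
   an arbitrary but deterministic tie-break, since nothing distinguishes
   the copies on the key.
3. **Aberrant chronology** — drop a report only when at least one drug
   has a full-precision therapy start date, a full-precision event onset
   exists, and *every* dated drug starts strictly after the earliest
   onset. Same-day start is retained ("after" is strict), and partial or
   missing dates are insufficient evidence, so those reports are
   retained — the conservative reading.

Each stage is idempotent and the removal counts satisfy
`retained = input − nonserious − duplicates − aberrant` by construction
(violations raise).

## Estimation

Crude ROR: `(a·d)/(b·c)` with the Woolf interval
`exp(ln ROR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d))`. No continuity correction is
applied; a zero in any needed cell yields "not computed" with a reason
rather than a corrected estimate, because the ≥ 3-exposed-case
eligibility rule already removes the worst sparsity and corrected
estimates are not comparable across pairs.

Adjusted ROR: maximum-likelihood logistic regression of case status on
exposure plus categorical age class (≤25, 26–50, 51–75, ≥76, unknown)
and sex (female, male, unknown), fitted over the index-plus-comparator
set; aROR = exp(exposure coefficient) with its Wald 95% interval.
Age enters as the class variable rather than continuous years because
roughly a third of reports lack age entirely; "unknown" is kept as an
explicit level for both covariates since dropping incomplete reports
would discard the bulk of the data. Reference levels are the first
observed age class and "female"; the exposure coefficient is invariant
to that choice. Separation, singular designs and non-convergence are
caught and reported as "not computed" with a diagnostic string.

SDR definition: a pair is a Signal of Disproportionate Reporting when it
is eligible (≥ 3 exposed cases) and the lower 95% bound of the aROR
exceeds 1 — the standard one-sided criterion at the 2.5% level.

Wald intervals are used throughout (no exact or profile intervals):
intended cell counts are in the hundreds, where the three agree and
Wald is the convention in disproportionality screening. In the
simulation studies below the empirical coverage of the 95% interval at
n = 50,000 is ≈ 94–96%.

## Time-to-onset

TTO = event onset − therapy start, in whole days, using the earliest
full-precision onset among qualifying events and the earliest
full-precision start among the index drug's lines. Records lacking
day-precision dates on either side (or with onset before start) are
flagged non-informative rather than dropped, and summaries report the
informative count. Quantiles use linear interpolation between order
statistics. Observations are *capped* at 365 days, not excluded:
late-onset-heavy pairs then show quartiles pinned at 365 instead of a
shrunken sample, which matches how one-year-truncated quartiles behave
in published screens. The CDF table gives the fraction ≤ t for integer
t in [0, cap].

## Drug-name normalization

Lookup into a user-supplied archive (brand/generic token → INN, INN →
ATC codes) after case-folding, punctuation stripping and whitespace
collapse; then retry after stripping trailing dose/formulation tokens
("400MG", "TABLET", ...); then an *opt-in* rescue that accepts a unique
archive neighbour within edit distance 1, only for tokens of ≥ 6
characters — uniqueness and length gates guard against false merges.
Multi-ingredient strings split on `+`/`;` and resolve per component;
report-level exposure flags union the components. Unresolved tokens are
counted and exported as a curation worklist (manual completion of the
residual fraction is out of scope for a library).

## Synthetic data generator

The generator emulates the structure of a FAERS quarterly extract —
DEMO/DRUG/REAC/OUTC/INDI/THER tables, `$`-separated, with partial dates
(YYYY / YYYYMM / YYYYMMDD), age-unit codes, free-text drug names as a
mix of brand, generic, dose-suffixed and single-edit misspelled
variants, follow-up versions, duplicate submissions, aberrant
chronologies and nonserious reports — with a ground-truth sidecar that
records exactly what was planted.

Structural model (`mode="logistic"`): per report, age class and sex are
drawn from marginal tables (with explicit unknowns); TKI-group exposure
follows a logistic link with covariate log-odds shifts; one anticancer
primary drug is drawn within the group; each SMQ's case indicator
follows a second logistic link whose exposure effect is
`log(true_or[drug, smq])` plus covariate shifts. Planted odds ratios
are therefore *conditional on age class and sex* — precisely the
estimand of the adjusted analysis, making parameter recovery a
well-posed check. Because confounding acts through the same categorical
age classes the model adjusts for, the adjusted fit is correctly
specified; residual within-class confounding is deliberately absent
(it would probe a limitation of the study design itself, not the
estimator).

A `mode="stratified"` variant draws covariates from per-exposure-group
tables and case status from per-drug any-case probabilities, with the
any-case probability split across the eight queries as
`p(d,s) = 1 − (1 − p_d)^{w_s}` so that the union over independent
queries reproduces `p_d` exactly. The `reference_cohort_preset` uses
this mode with margins taken from the published CML-TKI cohort (drug
report mix, per-drug case fractions, per-group sex/age tables), so its
expected case mix is exact by arithmetic — e.g. the expected nilotinib
share of TKI cases is 2319/3930 = 59.0%.

Injection rules that make funnel ground truth exact rather than
approximate: follow-up and duplicate clones are created only for
serious, non-aberrant base reports (mutually exclusively); duplicate
clones differ from their source only in identifiers; aberrant reports
keep full-precision dates (a partial date would mask the aberrance);
and base-report duplicate keys are uniquified by appending a synthetic
marker term on collision. Removal counts at each funnel stage then
equal injected counts exactly, which the tests assert.

Default nuisance rates, chosen once as plausible for a spontaneous-report
corpus: 10% nonserious, 5% follow-ups, 5% duplicates, 2% aberrant, 25%
missing/partial dates, 2% misspelled primary names, and a 20%
unresolvable-concomitant rate that puts designed name-archive coverage
at ≈ 90%. Demographic and outcome marginals follow the reference
cohort's totals. TTO draws are exponential with mean 100 days by
default, configurable per drug.

What the generator does **not** emulate: free-text narratives, real
MedDRA hierarchies (terms are fictional and flat), multi-drug anticancer
regimens (one anticancer drug per report, so exposure ground truth is
unambiguous), reporting-rate drift over calendar time, and
within-age-class confounding. Passing tests therefore demonstrate that
the estimators and the funnel do what they claim under the stated model,
not that real FAERS signals are reproduced — reproducing the published
adjusted RORs would require the real corpus with per-report age/sex.

## Simulation studies and problem sizes

- *Parameter recovery*: 100 replicates of n = 50,000 with a planted
  conditional OR of 12 (nilotinib / QT prolongation) under age/sex
  confounding; the scenario uses a 5% index-drug share and 1% event
  baseline so that cell counts sit in the Wald-asymptotic regime — the
  check targets estimator calibration, not sparse-cell behaviour.
  Empirical CI coverage is ≈ 94–96% (a fixed-seed run is asserted
  ≥ 90%), with the crude ROR visibly inflated (≈ 14 on average).
- *Type-I error*: one n = 50,000 cohort with all true ORs 1; SDR flags
  across the 40 drug × SMQ pairs are asserted ≤ 10% (expected rate
  2.5% among eligible pairs).
- *Funnel exactness*: full raw-table round trip at n = 4,000 base
  reports with all injections enabled.
- The preset-margin check pools ten n = 100,000 cohorts because TKI
  cases are only ~0.5% of reports; a single draw's Monte-Carlo error
  would be the size of the 2-point tolerance.

These sizes keep the full suite under a minute of simulation time while
leaving each check's Monte-Carlo error well inside its tolerance.

## Numerical and format choices

- `$`-delimited, unquoted ASCII tables (the FAERS convention); a CSV
  dialect is accepted for fixtures. Rows lacking the report key are
  dropped and counted in a load report; unknown column layouts raise a
  schema error naming the file.
- FAERS age-unit codes normalized to years (DEC ×10, MON ÷12, WK and DY
  by the Julian year, blank = years); unconvertible units become
  missing. Age-class bounds are inclusive as printed: ≤25 / 26–50 /
  51–75 / ≥76, with fractional ages falling in the surrounding bin.
- Partial dates carry an explicit precision marker; impossible calendar
  values (month 13, February 30) parse to missing with a warning rather
  than aborting a load.
- Display percentages and display RORs round half-up to one decimal via
  decimal arithmetic (so 59.0076 → 59.0, 3.0534 → 3.1, immune to binary
  float ties); machine-readable outputs keep full precision. The forest
  renderer copies the fitted numbers verbatim — it never recomputes.
- Determinism: every stochastic component takes a `numpy` Generator
  seeded from the scenario seed; identical config + seed reproduces the
  emitted files byte for byte.

## Known limitations

- The duplicate key treats the report's event list as a set; a true
  duplicate reported with a strict subset of terms is not collapsed.
- The aberrant rule considers any drug line with a dated start, not only
  suspect lines; with typical FAERS sparsity (therapy dates mostly on
  the suspect drug) the two readings coincide.
- Event onset is carried at report level (the REAC table has no
  per-event date in this dialect), so multi-event reports share one
  onset.
- No multiplicity correction is applied across the 40+ screened pairs,
  matching standard screening practice; interpret isolated SDRs
  accordingly.
- The study window (default 2008-04-01 to 2018-12-31) is configuration,
  not enforcement: reports outside it are not filtered unless the caller
  does so.
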