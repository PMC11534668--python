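# Methods

## The analysis

`faerspv` implements the standard disproportionality workflow for a single
target drug in a spontaneous-report database distributed as FAERS-style
quarterly tables (DEMO, DRUG, REAC, OUTC, THER; `$`-delimited, one header
row, no quoting).

**Deduplication.** A case accumulates report versions; analyses must count
it once. Per `caseid` the pipeline keeps the version with the latest
received date (`fda_dt`), breaking ties by the numerically largest
`primaryid`. Received date is the primary key because a FAERS `primaryid`
is the case id plus a version suffix: the most recently received report is
the current version of the case. An absent received date sorts below any
real date. Selection is a maximum under a total ordering, so it is
idempotent and independent of input order.

**Case selection and assembly.** A case enters the target cohort when its
selected version carries at least one drug row with role `PS` (primary
suspect) whose free-text name matches a configurable pattern list
(default: semaglutide, ozempic, wegovy, rybelsus; case-insensitive
substring). All five tables are joined on the selected `primaryid`. Ages
are normalized to years with the FAERS unit factors (DEC×10, YR×1,
MON÷12, WK÷52, DY÷365.25, HR÷8766); an unknown unit leaves age absent.
Cases with no reactions are dropped with a warning — a report without an
adverse event is not analyzable. All remaining deduplicated cases form
the background comparator ("all other drugs in the database").

**Terminology mapping.** Reactions are MedDRA Preferred Terms (PTs)
rolled up to System Organ Classes (SOCs) through a single-SOC dictionary
(primary-SOC style; the multiaxial hierarchy is out of scope). The
counting unit for frequency tables is the *event*: one distinct
(case, PT) pair. A term listed twice in one case counts once; a case with
three terms contributes three events. Terms missing from the dictionary
are returned to the caller, never silently dropped. The packaged
mini-dictionary (~80 terms) is a stand-in with the same file contract as
a licensed MedDRA export (2-column TSV), which can be dropped in.

**Route classification.** Semaglutide ships as a daily oral tablet
(Rybelsus) and once-weekly subcutaneous injections (Ozempic, Wegovy).
FAERS identifies the formulation inconsistently across four fields, so
keyword rules are applied in a fixed precedence: explicit `route`, then
`dose_form`, then trade name in `drugname`, then `dose_freq` — structured
fields outrank the trade name, which outranks dosing frequency, because
explicit route is least ambiguous. The first field level with exactly one
matching formulation decides and is recorded as evidence; a level whose
keywords fire for *both* formulations marks the case as a conflict.
Cases with no match anywhere are excluded from the route comparison.
Keywords are matched at word boundaries (so "sc" cannot fire inside
"intramuscular") and live in a YAML rulebook rather than code, because
FAERS free text drifts.

**Disproportionality.** For each term the 2×2 four-grid table counts
cases: `a`/`b` target cohort with/without the term, `c`/`d` comparator
likewise. The reporting odds ratio is ROR = (a/c)/(b/d) with the Woolf
(log-normal) 95% confidence interval
exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); a term is a signal when the
lower bound exceeds 1.0. Tables with any zero cell, or with
`a < min_count` (default 3, a common pharmacovigilance convention), are
reported as non-evaluable rather than corrected: the default engine never
manufactures a signal the formula itself cannot produce. An optional
Haldane–Anscombe +0.5 correction exists behind a flag. No
multiple-testing adjustment is applied; the outputs annotate how many
terms were tested. Results sort by descending ROR, ties broken
lexicographically, for deterministic output.

**Formulation comparison.** The PTs observed in the oral and subcutaneous
cohorts are partitioned (unique-left / shared / unique-right); each
cohort's unique PTs are then tested for that cohort against the shared
all-other-drugs background. A direct head-to-head ROR (oral as target,
subcutaneous as comparator) is computed for chosen terms or SOCs; its
lower bound is reported as the ROR_025 statistic.

**Time to onset.** Onset is event date minus the earliest therapy start
date among rows pointing at a target-drug entry, both at day precision;
partial dates (YYYYMM, YYYY) are unusable and excluded. Negative
intervals are excluded and counted, not clipped — whether published
analyses excluded or clipped them is generally unstated, so the choice is
made explicit and auditable. PT-specific onset is approximated at case
level because the tables do not date individual reactions. Summaries are
median and quartiles by linear interpolation between order statistics.

**Percentages.** All table percentages are round-half-up to two decimals,
computed as exact rationals (`Decimal`) before quantizing. Published
semaglutide tables mix conventions across rows; one convention is used
throughout and each emitted table recomputes its percentages from its own
counts, so every table is self-consistent.

## The synthetic-report generator

Spontaneous-report data has no ground truth, so the generator
manufactures it. Target-arm and background-arm cases receive each catalog
term with probabilities chosen so the *population* odds ratio equals the
configured value exactly: holding the background probability `p_b` fixed
(default 0.01, overridable per term), the target probability solves
p_t = r·odds_b / (1 + r·odds_b). Terms may be restricted to one
formulation, which makes them formulation-unique signals; rare strong
signals use a smaller per-term baseline (0.0008–0.002) so they surface
with few reports and wide intervals, the pattern extreme published terms
show.

Defaults represent the study conditions the package validates under:

| parameter | default | rationale |
| --- | --- | --- |
| cases per arm | 5,000 | enough for stable cell counts at `p_b` = 0.01 |
| duplicate_fraction | 0.2 | two report versions for 20% of cases |
| route_mix | 0.13 / 0.85 / 0.02 | oral / subcutaneous / unidentifiable, the published cohort proportions |
| onset | log-normal, median 4 d, σ = 2.0 | skewed onset with median 4 days; σ chosen so Q1 ≈ 1 day |
| age | Normal(62, 15), clipped 18–95 | published median age 62 |
| missingness | age 45%, event date 25% (10% partial), therapy start 25% | FAERS-like missingness |
| serious outcome codes | DE 0.8%, LT 0.5%, HO 2%, DS 0.3%, CA 0.05%, RI 0.2%, OT 5% | ~3.8% of cases carry a serious code |

Duplicated cases are emitted as two versions sharing a `caseid` with
increasing `primaryid` and non-decreasing received date; by default only
those two fields differ, which isolates the deduplication contract (an
option injects demographic noise into the earlier version). Every case
has ≥1 drug and ≥1 reaction; a case whose catalog draws all miss receives
one of six catch-all filler terms spread across organ classes (kept
disjoint from the catalog so embedded probabilities stay exact). A
classified oral/subcutaneous case always retains at least one
identifying drug field, so only the configured unidentifiable share is
excluded downstream. One seeded generator drives the whole run; identical
config and seed give byte-identical files.

What the generator does **not** emulate: drug-name misspellings, free-text
review prose, correlated term co-occurrence within a case, secular trends
in report volume, cross-`caseid` duplicates, and dose-strength
information. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under clean FAERS-like
structure — not robustness to the full messiness of real FAERS text.

## Validation studies and problem sizes

The package validates itself with three seeded studies, run both in the
test suite and by `scripts/acceptance.py`:

- **Null calibration** — 2,000 term-arms with embedded ROR 1 at 2,500
  cases/arm and baseline 0.02 (expected cell ≈ 50, large enough for the
  Woolf normal approximation). The fraction of arms flagged estimates the
  one-sided false-positive rate of the 95% criterion, expected ≈ 2.5%
  within Monte-Carlo error.
- **Parameter recovery** — embedded RORs {0.5, 1, 2, 5, 36}, 40 terms per
  level, 5,000 cases/arm. Measured: 95% CI coverage of the embedded value
  (expected ≈ 95%, required ≥ 90%; 200 terms keep the Monte-Carlo
  standard error of measured coverage near 1.5 points) and the fraction
  of ROR-36 terms flagged (expected 100%).
- **Deduplication** — 1,000 cases, 20% duplicated: recovered unique-case
  count must equal ground truth exactly, idempotently and independent of
  input order.

Calibration and recovery studies set `duplicate_fraction` to 0 so they
measure the statistical property in isolation; deduplication has its own
study and end-to-end runs exercise both together.

## Numerical and design choices

- z = 1.96 exactly (the conventional value), not Φ⁻¹(0.975); the two
  differ in the fifth significant digit.
- Quantiles: linear interpolation between order statistics (the common
  default; no convention is standard in this literature).
- Report year is taken from the received date, not the event date,
  because yearly tables bucket report volume.
- The serious-outcome set defaults to {DE, LT, HO, DS, CA, RI}; a
  stricter {DE, LT} set is available by configuration, since "serious"
  is often left unenumerated in published work.
- Country is the `reporter_country` field; reporter occupation tables use
  the raw FAERS occupation codes without an interpretive health-care
  grouping.
- Dates are kept as integers with a precision tag (day/month/year) rather
  than coerced; each consumer decides what precision it needs.
- Age-band tables keep "unknown" as its own band with percentages of the
  full case count, so bands need not sum to 100% of known ages.

## Known limitations

- Duplicate detection is exact on `caseid` only; probabilistic linkage of
  re-entered cases under different ids is out of scope.
- The single-SOC dictionary ignores MedDRA multiaxiality; counts for
  multiaxial PTs follow whatever primary SOC the dictionary assigns.
- The route rulebook resolves cross-field conflicts by surfacing them,
  not guessing; real-world conflict rates are unknown.
- Published headline quantities from full-scale FAERS extractions
  (total case counts, the specific published RORs) require the complete
  multi-year download plus licensed MedDRA and are out of scope; the
  package demonstrates the method's properties on synthetic data with
  known truth instead.
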