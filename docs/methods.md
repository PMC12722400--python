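# Methods

## Design

The package implements the case/non-case design for spontaneous-report
databases. The unit of analysis is one deduplicated report. Reports in
which the target drug appears as primary or secondary suspect — and
whose indication for the target drug is psychiatric — are *cases*;
reports that mention the target drug in any other way (concomitant-only
role, or an anaesthesia/sedation/pain indication) are removed from the
analysis entirely; everything else is a *non-case*. The three-way split
matters: treating excluded reports as non-cases would slightly deflate
every ROR denominator, and the published case/non-case totals only
reconcile when the excluded reports are dropped from both populations.

## Cleaning

Order of operations: (1) keep one report version per case identifier —
latest FDA receipt date, ties broken by highest report identifier; (2)
remove cases named in the deleted-case lists; (3) collapse reports
identical on the 7-field key (sex, age, country, event date, sorted PT
set, sorted ingredient set, sorted indication set), keeping the highest
report identifier. Deleted-case removal precedes the field-match pass so
that a deleted report can never survive as the tiebreak winner of a
duplicate group.

Field-match details that were genuinely open and are fixed here: missing
values participate in the key as a distinct value (two missing ages
match); event dates match at their stored precision, so a year-only date
matches only another year-only date. Both choices read "same values"
literally and are the conservative options. On sparse synthetic data the
7-field key occasionally collapses genuinely distinct reports that
happen to agree on all seven fields; this mirrors what the rule does on
real data and is why cleaning counters are always reported.

## Disproportionality

ROR and its Woolf CI as in the README. Numerical choices:

- The normal critical value is taken from the quantile at the requested
  level and rounded to two decimals (1.96 at 95%), the convention under
  which published tables are computed. Other CI levels are supported.
- No continuity correction: a zero cell marks the result non-estimable
  and it is carried with a flag, never silently dropped. The ≥5-report
  floor already excludes the unstable tables from screening.
- No multiple-testing adjustment; the run manifest records how many PTs
  were tested so readers can judge the multiplicity burden.
- Published-table outputs are rendered at two decimals with ties rounded
  away from zero; all internal computation is at full precision.
  Relative RORs are computed from unrounded stratum RORs (rounding the
  inputs first produces visible discrepancies at two decimals).

The comparator ("active comparator") sensitivity analysis restricts the
non-case population to reports carrying the comparator drug in the same
eligible roles without the target. Reports co-exposed to target and
comparator count as cases by default (configurable), since the case
definition takes precedence.

## Stratified contrasts

Sex strata are F vs M with missing excluded from the stratified analysis
only. Age strata are adults (18–64 inclusive) and older adults (≥65);
by default only reports whose age is recorded in years enter the age
analysis, because unit-converted ages (months, weeks, days, decades)
are disproportionately data-entry artifacts. The conversion factors,
when the toggle is off, are months/12, weeks/52.14, days/365.25,
decades×10.

Classification uses the dual rule (stratum ROR CI > 1 and
relative-ROR CI > 1 toward that stratum) with no interaction p-value.
Both strata must have at least five target reports. The combined CI is
exact under the same log-normal approximation as the Woolf interval; a
parametric-bootstrap check (log-normal resampling of both stratum RORs)
agrees within Monte-Carlo error, and the suite asserts it. Under a null
stratum effect the dual criterion's empirical false-difference rate is
well under 10%, reflecting its conjunctive form.

## Time-to-onset and seriousness

Only day-precision therapy-start and event dates yield a TTO; the
earliest day-precision start among the target drug's therapy rows is
used when several exist. Same-day onset is 0; negative differences are
excluded and counted as data errors rather than clamped. Seriousness
follows the regulatory outcome-code definition; reports with no outcome
row are non-serious. Contrasts use the tie-corrected asymptotic
Mann-Whitney U (it matches exact enumeration to ~0.06 in p for groups of
≤8) and Pearson's χ² without continuity correction.

## Drug–drug interaction scoring

Eligibility: the AE must already be a screened signal and must not
belong to the indication-overlap exclusion set (defaults: anxiety,
depression, panic attack, completed suicide, suicidal ideation, suicide
attempt); drug B must appear with a suspect or interacting role — never
concomitant-only — in at least three case reports carrying that AE.

Counting conventions, which the source formulas leave open:

- Confidence is P(A ∩ AE | B): the rule's antecedent denominator is the
  total number of B-exposed reports (B-with-A plus B-without-A).
- The association-rule universe (the support denominator) defaults to
  case reports, where confidence reduces to P(AE | A ∩ B) and support to
  P(AE | A); an all-reports universe is available as a config choice.
- The risk-scale scores (AI, MI, CRR) always use the four bundle-wide
  exposure cells (A∩B / A-only / B-only / neither), because a case-only
  universe leaves two cells empty and risk contrasts undefined.
- CRR components: each PRR treats its exposure set as exposed and every
  other report as comparator. Note the measure is not centred at 1 under
  a null drug B when exposure prevalence is high — the combination PRR's
  comparator then contains many single-exposed reports — which is one
  reason the CRR>2 rule is conjunctive with the other scores.
- Verdicts use strict inequalities on unrounded values; a conviction
  printed as 1.00 can therefore still pass, being marginally above 1
  before rounding. Any non-estimable score (zero denominator) fails its
  verdict but the triple is still reported.

## Synthetic-report generator

The generator emulates the *structure* of the real database, not its
marginal drug/PT distributions: multi-table reports with 1..k PTs, 1..m
drugs with role codes, partial dates, missing demographics, injected
duplicates of both kinds and deleted cases. Defaults are chosen to match
the reporting environment of an intranasal antidepressant: 58.5% female
/ 32.5% male / 9% missing sex, onset age ~N(48, 16) years with 30%
missing, 78% US reports, log-normal TTO with medians 60 days (serious)
and 2 days (non-serious) and σ=1.2, event dates within the 2014–2024
window, 2% same-case duplicates, 1% field-match duplicates, 1% deleted
cases, and a 2% rate of non-psychiatric target indications.

Single-drug signals and sex effects are planted on the odds scale, so at
low baseline the pipeline's ROR estimate approximates the planted
multiplier; drug-pair interactions are planted on the risk scale
(additive: p₁₁ = p₁₀+p₀₁−p₀₀+s; multiplicative: p₁₁ = s·p₁₀·p₀₁/p₀₀)
because AI and MI are risk-scale quantities. PT draws are independent
within a report; a report that draws no PT receives a neutral filler
term, which slightly inflates that term's marginal (the calibration
tests therefore exempt it).

What passing tests on this generator do **not** show: robustness to the
real database's correlated PT co-reporting, era-varying column quality,
name-variant noise ahead of ingredient mapping, or reporting-rate
secular trends. They do show that every estimator recovers what was
planted under the structural assumptions the statistics themselves make.

## Problem sizes in the test and acceptance suites

Worked examples run on printed 2×2 counts and are exact. Simulation
checks use 20,000-report null bundles, a 50,000-report signal-recovery
bundle, 2,500 simulated tables for CI coverage, 100 replicates of
50,000-report count universes for the ARM/MI properties, and 60
replicates of 5,000-report bundles for end-to-end interaction recovery —
sizes at which the asserted tolerances (CI coverage 94–96%, |mean−1| <
0.1, relative bias < 15%) are comfortably inside sampling error.

## Known limitations

- Only the modern (post-2014) column dialect ships as a default; older
  era spellings need a user-supplied dialect map.
- The ingredient dictionary is an input; no drug-name dictionary is
  bundled, and unmapped verbatim names pass through unchanged.
- Dates are validated permissively (Feb 29 accepted without leap-year
  checks), matching upstream data entry.
- No Bayesian shrinkage measures (IC, EBGM) and no record linkage beyond
  the two deterministic duplicate rules.
- The published interaction-score table cannot be reproduced from its
  printed counts alone (the underlying count definitions are not in the
  main text); the package's conventions are documented above instead.
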