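# Methods

## The analysis problem

Outpatient dispensing databases record who filled what, when, and how much —
but not why, nor what was actually swallowed. Assessing prescribing practice
for antidepressants in 6–17-year-olds therefore rests on three derived
constructs: an *incident-user cohort* (the first antidepressant a patient ever
fills, given enough lookback to trust "first"), a *dose* normalised to WHO
defined daily doses (DDD) so different substances are comparable, and a
*maintenance episode* reconstructed from refill timing. This note documents
how each is operationalised, the defaults, and what the synthetic evaluation
does and does not show.

## Cohort selection

- **Index event.** The earliest fill of any N06AA/N06AB/N06AX drug. MAOIs
  (N06AF/N06AG) never qualify. When several antidepressant products are
  filled that first day, the patient is excluded (dual start) because no
  single starting regimen is identifiable. Only the first episode per patient
  is analysed; no re-eligibility logic is attempted.
- **History.** "Six months in the database" is operationalised as 183 days
  (half of 366, so a leap half-year still passes); configurable
  (`history_days`).
- **Age.** Computed from exact birth and index dates as days/365.25; the
  whole-year part decides the 6–17 inclusion and the child (6–9),
  preteen (10–13), teen (14–17) bands. A `age_from_year_only` flag falls back
  to calendar-year subtraction for sources that store only birth year.
- **Non-psychiatric indications.** Bed-wetting: amitriptyline or imipramine
  start plus desmopressin (H01BA02) at *any* time. Pain: tricyclic start plus
  ≥2 dispensings with ATC M01 or N02 prefix, or exactly N03AX12/N03AX16, in
  the window [index−183 d, index−1 d]. The index day itself is not counted as
  "prior"; this is a documented reading, configurable via
  `pain_window_days`/`pain_min_count`.
- **Rule order.** window → age → history → dual start → bed-wetting → pain;
  each excluded patient is reported once under the first rule that fired.
  Counts under a different order could differ at the margin for patients
  matching several rules.

## Dose arithmetic

`days supply = units_total / units_per_day`; `dose = total_ddd / days supply`,
fractional days kept. For liquid-concentrate citalopram/escitalopram the
recorded daily dose is in drops and is divided by exactly 20 (1 drop ≈
0.05 ml) before the division — a fixed constant, since it defines the method.
Consequences, used as algebraic test identities: the correction multiplies
days supply by exactly 20 and divides the computed dose by exactly 20.

Degenerate inputs: `units_per_day = 0` (the classic data-entry error) yields
dose 0, flagged `too_low`; a missing `units_per_day` or `total_ddd` yields an
uncomputable dose, flagged `missing`; `total_ddd = 0` yields dose 0. Starting
doses above 3 DDD/day and maintenance doses above 4 DDD/day are `too_high`;
the boundaries 3.0/4.0 are valid.

Same-day duplicates of the index drug: the record with the lowest dose is
taken. The comparison is on DDD/day — not raw units/day — so that it is
meaningful across tablet strengths; ties break on lowest `units_total`, then
input order.

## Maintenance episodes and titration

Per-record doses are computed with missing set to 0. Fills of the index drug
are sorted by (date, dose, units); a run extends while the next record has
the same dose (|Δ| ≤ 1e-9 DDD/day) *and* the previous record's supply,
stretched by 25 %, covers its fill date. A dose change ends a run even when
supplies still overlap, because a maintenance period is defined by a constant
dose. Runs with ≥2 fills and ≥60 days total supply at a dose in (0, 4] are
episodes; each fill belongs to at most one. The tolerance only has to absorb
float division noise — real dose grids are far coarser than 1e-9.

The primary episode is the longest; "duration" defaults to total days supply
(`duration_mode="supply"`, calendar span available), with the highest dose
breaking duration ties and the earliest start breaking any remainder.
Titration compares the primary maintenance dose with the valid starting dose
(±1e-9). Only the index drug is scanned; a switch to another antidepressant
ends eligibility.

The detector is verified against an independent brute-force oracle that
enumerates every contiguous subsequence of ≤12 fills and keeps the maximal
qualifying ones.

## Guideline rulesets

Shipped as a CSV (`ruleset, atc_code, min_age, max_age, max_start_ddd,
maint_low_ddd, maint_high_ddd`), thresholds in DDD/day via the shipped DDD
table (20 mg fluoxetine/citalopram/paroxetine, 50 mg sertraline, 100 mg
fluvoxamine/imipramine/clomipramine/venlafaxine, 75 mg amitriptyline, 30 mg
mirtazapine per DDD, plus the other substances the generator emits).
Compliance is a closed comparison (dose ≤ threshold); the adult-dose flag
(dose ≥ 1 DDD/day) is computed for every drug independently of compliance.
The lenient sertraline threshold of 1 DDD applies from the 13th birthday.
Maintenance compliance checks a closed [low, high] range per drug/age;
published guidance rarely prints explicit maintenance bounds, so the shipped
defaults — [guideline starting dose, 1 DDD/day] — are this package's
convention and should be overridden where a formulary states ranges.

## Synthetic study conditions

`default_config()` fixes the conditions the pipeline is evaluated under:

- 59 % female, 40 % male, 1 % missing; 11 % children, 19 % preteens, 70 %
  teens (ages uniform within each band, 0.05-year margins so whole-year ages
  are unambiguous), giving a mean initiation age ≈ 14.3 y.
- Period weights 0.406/0.277/0.317 across 1994–2003/2004–2009/2010–2014;
  prescriber mix shifting from 62 % GP early to 69 % specialist late.
- Per-period first-drug mixtures over 15 ATC codes: paroxetine-dominant
  early, citalopram-dominant from 2004, fluoxetine rising 10 % → 19.7 %,
  escitalopram absent before the 2000s.
- Starting doses on tablet-strength grids per drug (e.g. fluoxetine almost
  only at 0.5/1 DDD because only 20 mg tablets are marketed; citalopram with
  a 0.25/0.4/0.5 low tail reflecting its oral solution, 15 % of
  citalopram/escitalopram fills being liquid).
- Planted scenarios per patient: bed-wetting 2 %, pain 2 %, dual start 0.2 %,
  short history 2 %, out-of-range age 1 %, no antidepressant at all 4 %;
  index data-entry errors: zero daily dose 8.7 %, missing 0.1 %, >3 DDD/day
  0.2 %; same-day duplicate prescriptions 3 %.
- Refill chains: 53 % of initiators get a maintenance chain of 2–4 monthly
  (30-day) fills with gaps of 20–37 days (within the 25 % grace of a 30-day
  supply); maintenance dose equals the start dose with probability 0.60, one
  grid level up 0.35, down 0.05. Non-maintainers get either nothing or one
  late refill (gap 39–90 days, beyond grace).
- Co-medication noise (analgesics, desmopressin) is emitted only where it
  cannot flip a planted label — e.g. tricyclic starters receive at most
  post-index analgesics — so the ground truth stays exact by construction.

All dispensings carry a 30-day supply; supply-length variation is covered by
unit tests rather than the generator. Each patient draws from an independent
child stream of one `SeedSequence`, so datasets are reproducible byte-for-byte
and one patient's records never depend on another's draws.

**What passing shows — and does not.** Exact ground-truth recovery shows the
pipeline implements the stated rules correctly, and parameter recovery (3
binomial SE at n=1000) shows the estimators are consistent under these
conditions. It does not show the rules are robust to real-data features the
generator omits: variable pack sizes and supply lengths, dose changes within
an episode's grace window, stockpiling, transfers between pharmacies,
inpatient gaps, or drugs switching mid-episode. Headline percentages from the
restricted source database are out of reach by construction and are not
targets.

## Problem sizes

Test and acceptance runs use 1000 and 3000 simulated patients respectively —
large enough that every planted scenario occurs hundreds of times and
binomial recovery bands are tight, while the whole suite runs in seconds.
The brute-force oracle comparison uses 400 random instances of ≤12
prescriptions, the regime where exhaustive enumeration is exact and cheap.

## Known limitations

- Exclusion counts are first-rule-triggered; sources reporting overlapping
  rule counts will not match at the margin.
- The "lowest daily dose" tie-break on same-day duplicates (DDD/day, then
  units) is one defensible reading of an under-specified rule.
- The 25 % grace is applied to the covering prescription's own supply, not to
  cumulative carry-over from earlier fills.
- Maintenance guideline ranges are package defaults, not published bounds.
- No inferential statistics: the pipeline is descriptive, as the underlying
  method is.
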