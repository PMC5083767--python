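# rxcohort

Drug-utilization analysis of antidepressant initiation in children and
adolescents, built from outpatient pharmacy dispensing records.

Community-pharmacy databases record *dispensings*, not diagnoses or intended
regimens, so questions like "do physicians start children on fluoxetine, at
the recommended low dose?" must be answered from refill arithmetic alone.
`rxcohort` implements that method as a tested, reusable pipeline:

* **Incident-user cohort construction** — a patient enters at the first-ever
  antidepressant dispensing (ATC N06AA tricyclics, N06AB SSRIs, N06AX others;
  MAOIs excluded), if aged 6–17 with ≥183 days of database history. Likely
  non-psychiatric indications are filtered out: amitriptyline/imipramine
  starters who ever received desmopressin (bed-wetting), tricyclic starters
  with ≥2 pain-related dispensings (M01, N02, gabapentin, pregabalin) in the
  prior 6 months, and same-day dual starts. Every exclusion is logged with
  its rule.
* **DDD dose arithmetic** — each dispensing's dose in defined daily doses per
  day: `days supply = units / units-per-day`, `dose = total DDDs / days
  supply`, with the daily dose of concentrated liquid citalopram/escitalopram
  divided by 20 (1 drop ≈ 0.05 ml), the lowest dose taken when one drug is
  dispensed twice on the index day, and plausibility filters (0 < starting
  dose ≤ 3 DDD/day, 0 < maintenance dose ≤ 4 DDD/day, missing flagged).
* **Maintenance-episode detection** — maximal chains of ≥2 same-dose refills,
  each supply (plus a 25 % non-compliance grace) covering the next fill date,
  totalling ≥60 days' supply; the primary episode is the longest, highest
  dose on ties. Titration compares maintenance vs. starting dose (up / same /
  down).
* **Guideline compliance** — starting doses at or below the pediatric
  thresholds (fluoxetine/citalopram 5 mg = 0.25 DDD, fluvoxamine 25 mg =
  0.25 DDD, sertraline 25 mg = 0.5 DDD under 13 and 50 mg = 1 DDD from 13 in
  the lenient ruleset; a strict variant and the UK ≤10 mg fluoxetine check
  are included), plus an independent adult-dose flag (≥1 DDD/day).
* **Trend tables** — first-drug shares per period (1994–2003 / 2004–2009 /
  2010–2014), stratified by prescriber or age group with top-10 drugs and an
  "others" pool; dose distributions; compliance tables with per-age-group
  totals; titration and demographics summaries.
* **Synthetic data** — real dispensing databases of this kind are
  access-restricted, so `rxcohort.simulate` generates datasets with the same
  statistical structure (per-period drug mixtures, tablet-quantized dose
  grids, refill chains, planted exclusions and data-entry errors) and exports
  per-patient ground truth, giving every pipeline stage a known answer.

## Worked example

```python
import rxcohort as rx

cfg = rx.default_config(seed=1, n_patients=3000)
dataset, truth = rx.simulate(cfg)
res = rx.run_pipeline(dataset)

print(len(res.cohort))                      # 2657 included patients
print(rx.exclusion_counts(res.exclusions))  # {'history': 56, 'pain': 58,
                                            #  'bedwetting': 59, 'age': 34,
                                            #  'same_day_dual': 10}

shares = rx.report.initiation_shares(res.cohort)
print(shares[(shares.period == "2010-2014")
             & (shares.atc_code == "N06AB03")].pct_display.item())  # 19.8

print({k: round(v, 1) for k, v in res.titration_summary().items()})
# {'same': 62.0, 'up': 32.7, 'down': 5.3}
```

2657 of 3000 simulated patients survive selection; 19.8 % of 2010–2014
initiators start on fluoxetine (the generator's planted share is 19.7 %); of
patients with both a valid starting dose and a maintenance episode, 62 % stay
at their starting dose, 33 % titrate up and 5 % titrate down (planted
60/35/5). The same stages run from the shell:

```bash
rxcohort simulate --seed 1 --n-patients 3000 --out-dir data/
rxcohort cohort --patients data/patients.csv \
    --prescriptions data/prescriptions.csv \
    --out-cohort cohort.tsv --out-exclusions exclusions.tsv
rxcohort report --patients data/patients.csv \
    --prescriptions data/prescriptions.csv --out-dir tables/
```

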