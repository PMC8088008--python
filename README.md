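# gestage

First-trimester gestational-age (GA) dating toolkit: crown-rump-length
(CRL) dating formulae, cohort I/O, synthetic cohort simulation,
data-driven denoising, fractional-polynomial model development,
Bland-Altman method agreement and preterm-birth (PTB) classification
analytics.

## What it does

- **`gestage.formulae`** — registry of CRL (cm) → GA (weeks) formulae:
  the Garbhini-GA1 quadratic
  (`GA = −0.02294·CRL² + 1.15018·CRL + 6.73526`) plus six published
  comparators (Hadlock, Robinson-Fleming, McLennan-Schluter, Sahota,
  Verburg, INTERGROWTH-21st), with unit normalisation, monotonicity
  checks, numeric inversion and a YAML override path. Comparator
  coefficients are transcribed from their original publications and are
  provisional.
- **`gestage.cohort`** — scan-level cohort CSV schema with
  collect-and-report validation and an exclusion log (JSON lines); GA is
  decimal weeks (days/7), dates are ISO-8601.
- **`gestage.synthetic`** — seeded synthetic cohort generator: a true
  CRL-GA growth law, LMP recall error (bias + noise + gross ±1-cycle
  errors), CRL measurement noise, CRL truncation at 14 weeks, optional
  11–14-week second scan, delivery-GA mixture with exact preterm
  fraction, and per-row ground truth for parameter-recovery tests.
- **`gestage.denoise`** — clinical-criteria filtering and a
  deterministic classic DBSCAN (eps=0.5, min_points=20 defaults) on the
  raw (CRL, GA) plane.
- **`gestage.fpreg`** — truncation supplementation with simulated
  reference-formula observations (15–18 wk) and exhaustive
  fractional-polynomial search (powers {−2,−1,−0.5,0,0.5,1,2,3}),
  selected by R².
- **`gestage.feature_select`** — Boruta-style shadow-feature
  random-forest selection, L1/stepwise GLM selection, union, and
  candidate multivariate equation enumeration.
- **`gestage.compare`** — Bland-Altman analysis (mean ± 1.96 SD limits
  of agreement, % outside, optional trend) and all-pairs formula
  matrices.
- **`gestage.ptb`** — PTB classification (< 37.0 weeks), rates per 100
  with Wilson/Clopper-Pearson CIs, pairwise Fisher's exact tests with
  Bonferroni correction, Jaccard agreement, and
  sensitivity/specificity/balanced accuracy against an explicit
  reference.

## CLI

```bash
gestage simulate --n 2000 --seed 1 --out cohort.csv --truth truth.csv
gestage formulae list
gestage formulae eval --id garbhini_ga1 --crl 3.2
gestage filter --in cohort.csv --method dbscan --eps 0.5 --min-points 20 \
    --out denoised.csv --log removed.csv
gestage fit --in cohort.csv --denoise dbscan --supplement hadlock:15:18 \
    --out model.yaml
gestage compare --in cohort.csv --a hadlock --b lmp
gestage compare --in cohort.csv --matrix garbhini_ga1,hadlock,intergrowth
gestage ptb --in cohort.csv --formulae garbhini_ga1,hadlock,lmp \
    --reference lmp --out report.json
gestage select --in cohort.csv --method union --out features.json
```

## Notes

- The generator's reproducibility contract: one fixed-width random
  block per participant from a single seeded stream, so a given seed is
  byte-stable and adding participants never changes existing rows.
- Two scans of a participant enter as independent observation rows; the
  non-independence caveat is documented, not modelled.
- DBSCAN runs on raw units by default (eps is in cm/weeks); a
  standardisation flag is available and the choice is recorded in the
  output metadata.
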