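# faerspv

Signal detection and time-to-onset analysis for FAERS-style spontaneous
adverse-event reports.

Spontaneous reporting databases such as the FDA Adverse Event Reporting
System (FAERS) are the main post-marketing source for detecting drug safety
signals — for example drugs associated with venous thromboembolism (VTE,
i.e. deep vein thrombosis and pulmonary embolism). `faerspv` implements the
standard screening pipeline as a tested, reusable library for
pharmacoepidemiologists:

* **Ingestion** of the quarterly `$`-delimited ASCII tables (DEMO, DRUG,
  REAC, THER, OUTC, RPSR) and the FDA deduplication rule: per CASEID keep
  the report with the latest FDA_DT, ties broken by the highest PRIMARYID.
* **Cohort construction**: event-positive cases via a MedDRA preferred-term
  (PT) list, restriction to primary-suspect (PS) drug mentions, and
  synonym-to-ingredient mapping with ATC codes.
* **Disproportionality analysis** on per-drug 2×2 tables
  (a = drug∧event, b = drug only, c = event only, d = neither):

  | algorithm | statistic | signal criterion |
  |---|---|---|
  | ROR | ad/(bc), Wald 95% CI | a ≥ 3 and CI lower bound > 1 |
  | PRR | [a/(a+b)]/[c/(c+d)], Yates χ² | a ≥ 3, PRR ≥ 2, χ² ≥ 4 |
  | BCPNN | information component IC = log₂(aN/((a+b)(a+c))), shrunk | IC025 > 0 |
  | MGPS | EBGM (empirical-Bayes gamma–Poisson shrinkage) | EBGM05 > 2 |

  A drug is a **positive signal only when all four criteria hold**, and
  positives are stratified into risk levels A/B/C/D at the top 5%, 6–20%,
  21–50% and 51–100% of ROR values (floor-of-cumulative-rank boundaries).
* **Time-to-onset (TTO)**: days from therapy start to event onset plus 0.5,
  with exclusion bookkeeping for partial/invalid dates; two-parameter
  Weibull MLE (scale α in days, shape β) with failure-mode classification —
  β < 1 "early failure" (decreasing hazard), β ≈ 1 "random", β > 1
  "wear-out" — plus Kaplan–Meier cumulative incidence and log-rank group
  comparison.
* **Descriptives**: demographic/outcome summary table and the annual trend
  of reports and deaths.
* **Synthetic FAERS generator**: seeded quarters with known ground truth
  (injected drug–event associations, duplicates, synonyms, Weibull onset
  times) so every stage is testable without any download.

## Worked example

Run the whole pipeline on a bundled synthetic cohort (20 000 cases, two
drugs with injected associations — dienogest at true reporting ratio 8,
rivaroxaban at 4 — and three null drugs):

```python
from faerspv.pipeline import RunConfig, run
from faerspv.synthetic import SyntheticConfig

out = run(RunConfig(synthetic=SyntheticConfig(n_cases=20000),
                    out_dir="demo_out", seed=42))
```

`demo_out/signals.csv` then contains (abridged):

```
       drug   a    b  ROR  ROR_L  PRR   CHI2  IC025  EBGM05  combined level
  dienogest 138 1566 6.11   4.94 5.70 352.96   1.73    3.40      True     D
rivaroxaban  97 2503 2.20   1.74 2.16  45.41   0.58    1.54     False
  metformin  55 5185 0.45   0.33 0.45  31.54  -1.34    0.41     False
```

dienogest passes all four criteria (ROR 6.11 with CI lower bound 4.94,
PRR 5.70 with χ² 353, IC025 1.73, EBGM05 3.40) and is a combined-positive
signal; rivaroxaban's weaker association (diluted by the other injected
drug in the comparator) fails the PRR ≥ 2 and EBGM05 > 2 criteria; the
null drugs sit below 1 on every scale. `tto_by_drug.csv` reports, e.g.,
dienogest onset median 162 days (IQR 78–457) with Weibull β = 0.85
(95% CI 0.73–1.00, "random"), and the run manifest records the stage
counts (21 000 DEMO rows → 20 000 deduplicated cases → 398 event-positive
reports) and a log-rank comparison across drug classes (χ² = 38.7,
p = 8×10⁻⁸).

The same analysis is available from the shell:

```bash
faerspv simulate --out quarter/ --seed 42 --n-cases 20000
faerspv run-all --config run.yaml
```

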