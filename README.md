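# mcrval — cross-field validation of hospital minimum-caseload reports

Health-services researchers who study hospital compliance with German
minimum caseload requirements (MCR, *Mindestmengenregelungen*) depend on
the hospitals' own annual quality reports (GHQR) as their data source.
Those self-reports are incomplete and error-prone: sites — especially
ones performing few cases — often leave the caseload field empty, copy
last year's number, enter the association total instead of the site
value, or mistype 30 as 300. `mcrval` implements an internal
cross-field validation of such data: it never discards a record, but
detects implausible caseload statements, corrects them from redundant
information elsewhere in the same reports, quantifies completeness and
error sources, and checks the aggregate outcome against an external
caseload oracle.

The package targets four procedures with constant thresholds since
2006: complex oesophageal interventions (10 cases/year/site), complex
pancreatic interventions (10), allogeneic stem cell transplantation
(25) and total knee replacement (50).

## Method

For every (site, year, procedure) record three *key variables* are
comparable:

* **target** — the MCR caseload the site states (report part C),
* **reference 1** — the frequency of the MCR-defining OPS procedure
  codes, summed over the site's medical departments (part B); counts of
  1–3 are privacy-masked and imputed as 1.5,
* **reference 2** — for the knee only, the external quality indicator
  "indication for elective knee endoprosthesis – primary implantation"
  (ID 54020).

A value of zero means "not reported". Records are classified by
**availability**: level I (target and ≥1 reference), level II (only one
side reported), level III (nothing — the site is irrelevant to the
procedure). Level-I records are graded by the deviation `d = |target −
ref|`, `r = d / max(target, ref)` against a tolerance of **5 cases
absolute and 20% relative**:

| consistency | rule |
|---|---|
| 1 | no deviation |
| 2 | d ≤ 5 and r ≤ 20% |
| 3 | exactly one bound satisfied |
| 4 | d > 5 and r > 20% (suspicious) |

Levels 1–3 are acceptable. Suspicious records (level 4) and level-II
records enter correction: support criteria (practicability of a
competent department, probability from other years, agreement of the
two knee references) and seven rejection criteria (no competent
department, duplicated OPS rows, previous-year and sibling-site
duplicates, mis-aggregated knee indicator, association-level entry,
digit shifts / gross implausibility / wrong-field entries). A rejected
statement is replaced by the surviving reference value; if no
preference can be made the original is kept. Original and validated
caseloads are then banded 0 / S (positive, sub-threshold) / G
(≥ threshold) and the eight before/after band pairs (0–S, 0–G, …)
attribute each correction to an error source. Finally validated
caseloads are aggregated to hospital-association (IIC) level and
compared with an external oracle — in the shipped synthetic setting,
the generator's ground truth.

Because the real report datasets are access-restricted, `mcrval` ships
a first-class synthetic generator (`mcrval.simulate`) that renders a
ground-truth hospital landscape into clean reports, injects the
documented error taxonomy at configurable rates with a replayable error
log, and applies privacy masking — so every pipeline stage is testable
by parameter recovery.

## Worked example

```sh
python examples/01_validate_reports.py
```

builds three single-department sites — one that performed 7 oesophageal
interventions but reported no caseload, one that typed 120 instead of
12, one consistent — and prints:

```
      iic availability  consistency  original  validated fired_criteria    provenance
260000001           II          NaN         0        7.0             P1          ref1
260000002            I          4.0       120       12.0 R7_digit_shift          ref1
260000003            I          1.0        25       25.0                original_kept
```

The unreported caseload is resurrected from the OPS frequency in the
competent department (criterion P1), the tenfold typo is recognised and
replaced (R7 digit shift), and the consistent statement passes through
untouched. The other example scripts simulate a full landscape and
summarise it (`02`), run a parameter-recovery experiment (`03`) and
recompute the published federal summary percentages (`04`).

The same pipeline is available as a CLI:

```sh
mcrval run-all --simulate --seed 7 --out-dir run/
mcrval detect --input run/input --out detection.csv
```

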