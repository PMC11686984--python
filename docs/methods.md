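# Methods

## The validation model

`mcrval` treats a hospital site's annual report as a bundle of
redundant statements about the same quantity: the number of cases of a
minimum-caseload (MCR) procedure the site performed in a year. The
caseload statement (the *target*) is checked against the summed
frequency of the MCR-defining OPS codes across the site's departments
(*reference 1*) and, for total knee replacement, against the external
quality indicator 54020 (*reference 2*). Three further context sources
feed the correction rules: the association report (the sum of all
sites sharing one institution identification code, IIC), the same
site's statements in other years, and the general medical plausibility
of the site (does any department competent for the procedure exist?).

Two sources of benign discrepancy between statement and OPS frequency
are expected rather than erroneous: multiple MCR-relevant codes may be
documented for one operation (double-coding), and department counts of
1–3 are privacy-suppressed and only recoverable as an imputed constant.
The tolerance range — **5 cases absolute, 20% relative, either bound
sufficient** — exists to absorb exactly these; values agreeing within
it are treated as indistinguishable, and the method deliberately never
"corrects" inside it. This makes the tolerance the *resolution limit*
of the whole validation: errors smaller than the tolerance are neither
detectable nor worth detecting.

Assumptions worth making explicit:

* absence equals zero — an empty caseload or indicator field is read as
  0, and files need no null token for these fields;
* a site is identified by exact (IIC, site code) string equality across
  years; hospital mergers or IIC changes are out of scope;
* OPS masking applies only to department-level frequencies, never to
  caseload statements or indicator counts;
* corrections read only the *original* database (no cascading), so the
  audit trail is order-independent and re-validating a validated
  database is a no-op — a property the test suite verifies rather than
  assumes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| thresholds | 10 / 10 / 25 / 50 | cases per year and site (oesophagus, pancreas, stem cells, knee) |
| `Tolerance.abs_max` | 5 cases | absolute deviation bound |
| `Tolerance.rel_max` | 0.20 | relative deviation bound |
| `Tolerance.denominator` | `max` | base of the relative deviation (`max`, `ref`, `target`) |
| imputation constant | 1.5 | contribution of a masked OPS cell to an aggregate |
| `gross_factor` | 10 | statement > 10 × best reference is "much too high" (R7) |

The relative-deviation denominator is nowhere fixed by the source
method; `max(target, ref)` was chosen because it is symmetric in the
two values and bounded in [0, 1], and it is exposed as a switch so the
sensitivity of results to this choice can be examined. Note that under
the `max` denominator the consistency level is monotone in the
deviation only for references on a fixed side of the target (a
reference far *above* can grade better than one moderately *below*);
the property tests check the one-sided statement.

## Correction rules and their fixed points

Availability-II records run a support ladder (first hit wins): K2
(knee: both references agree within tolerance → their value stands in),
P1 (practicability: OPS frequency in a competent department, with a
competent department somewhere in the association), the flagged
only-indicator analogue of P1, P2 (probability: a lone statement backed
by a positive statement in another year is kept), PED (pediatric-only
sites are exempt for oesophagus and stem cells → statement zeroed), and
a final rejection of lone statements with no competent department
anywhere and no support from any year. Anything else keeps the
original value.

Consistency-4 records evaluate all seven rejection criteria; fired
criteria combine under a fixed precedence (digit-shift before
association-entry before duplicates before indicator/frequency
rejections) so that corrections carrying an explicit replacement value
win over bare rejections. Duplicate detection (R2, R3, R4) demands
*exact* equality: duplicates are copy errors, and tolerance-band
matching would swallow genuine year-to-year stability. Criteria that
compare counts of different fields (R5, R6, the digit-shift arm of R7)
use the acceptable tolerance region (consistency ≤ 3); the digit-shift
comparison rescales the absolute bound along with the value (0.5
instead of 5 after division by ten), because otherwise any small
statement would trivially "match" a tenth of itself. R6 corrects only
the offending site to its own OPS frequency; whether the association
total should be redistributed across sibling sites is left open by the
source method and not attempted.

Validated values are kept fractional internally (imputed 1.5-steps);
rounding half away from zero happens only at report output. Compliance
(caseload ≥ threshold) is evaluated on the fractional values, and the
summary asserts that output rounding never moves a value across its
0/S/G band.

## What the synthetic generator emulates

The generator draws hospital associations (80% one site, 15% two,
5% three), assigns each site per-procedure participation (site-level
Bernoulli: 0.15 oesophagus, 0.25 pancreas, 0.04 stem cells, 0.44 knee)
and, for participating sites, i.i.d. annual caseloads from discretised
lognormals — medians 10 / 15 / 56 / 113, log-sigmas 0.75 / 0.90 /
0.90 / 0.70. These values were calibrated once so that the share of
inactive sites per procedure (≈ 85 / 75 / 96 / 56%), the mean positive
caseload (≈ 13 / 22 / 84 / 144) and the compliant share of reporting
sites (≈ 50 / 68 / 81 / 88%) match the published six-year federal
summary tables. Clean rendering places the full caseload under one MCR
code in the competent department, sets statement and knee indicator
equal to truth, and adds unicondylar/revision knee confounder codes
(Poisson, mean 0.3 × caseload).

Two noise layers sit on top:

* **double-coding** (`ops_overcount_rate`): each true case carries one
  extra MCR-relevant code with this probability, inflating reference 1.
  Corrupted-landscape experiments use 0.02. A substantially higher rate
  is not a plausible study condition: corrections adopt the OPS
  frequency, so a rate of q biases every corrected site by +q, and at
  q = 0.05 the validated federal totals would already drift beyond the
  ≈1% agreement with the external oracle that the validated data are
  known to show.
* the **error taxonomy**, injected with at most one class per record
  (rate-proportional choice, replayable log): non-reporting (0.25 for
  sub-threshold sites, 0.03 at or above threshold — under-reporting by
  small-caseload sites is the dominant documented error source),
  previous-year duplicate (0.02, copying the statement as *published*,
  i.e. possibly itself corrupted), sibling-site duplicate (0.01),
  association-level entry (0.02), digit shift (0.002 — "only a few
  hospitals", but with outsized caseload impact), wrong-field swap
  (0.005) and knee-indicator mis-aggregation (0.02). Masking is applied
  *after* injection: suppression is a property of publication, not a
  reporting error.

Features of real report data the generator does **not** model: year-to-
year autocorrelation of caseloads (draws are i.i.d. given
participation, which makes previous-year duplicates *detectable*; in
real data a copied stable caseload is typically also nearly correct),
hospital mergers and IIC changes, richer OPS vocabularies and
department structures, sites splitting one procedure across several
departments, systematic per-site coding styles (double-coding here is
i.i.d. per case, so exact statement–frequency agreement is rarer for
large sites than the published consistency-level-1 shares suggest), and
pandemic-era exceptional circumstances. Pediatric-only sites are
generated inactive in the exempt procedures; the pediatric rejection
rule is exercised by hand-built fixtures. Passing tests therefore show
that the rules do what they claim under controlled conditions — not
that real reports contain no error type outside the modelled taxonomy.

## Recovery metric

Recovery experiments inject a single error class (others zero, no
double-coding, masking off) and ask whether each affected record's
validated value returns to truth. For non-reporting and digit shifts
the claim is *exact* recovery: the uncorrupted OPS frequency equals
truth, and the responsible rules (P1/K2, R7 digit-shift) restore it
verbatim. For duplicate-style classes (previous-year, sibling,
association-entry, indicator mis-aggregation) a record counts as
recovered when the validated value agrees with truth within the
acceptable tolerance region (consistency ≤ 3): an injected value inside
the tolerance of the true caseload is, by the method's own design,
indistinguishable from counting noise and is correctly left alone.
Demanding exact recovery there would fault the method for honouring its
stated resolution limit.

## Problem sizes and experiment design

Unit fixtures use handfuls of sites. Recovery experiments use 250
associations (≈ 310 sites, ≈ 7 500 records) with elevated single-class
rates so that ≥ 500 records per class are affected; the association-
structure classes (sibling duplicate, association entry) use 1 300
associations because only multi-site associations are eligible. The
external-oracle comparison runs the full default taxonomy on 2 000
associations (≈ 2 500 sites), matching the scale of the real landscape
(2 275–2 538 site reports per year): the ≈1% federal-agreement claim
concerns aggregate totals, and in a small stratum such as stem cell
transplantation the tolerance-band residue of a single large site does
not average out. The whole acceptance script completes in well under a
minute on one CPU.

## Published-table arithmetic

The six-year per-procedure category tallies of the 2016–2021 federal
validation (site counts per availability/consistency category,
correction frequencies, caseload totals before and after) are shipped
as reference inputs, and the assessment formulas recompute the
published percentages from them — share of possibly-relevant sites,
rounding half away from zero to one decimal. The published per-
procedure *site-level completeness* figures rest on a formula that the
printed tallies do not determine (they are reproducible from the
relevant-site ratio for one procedure but not the others); the package
therefore reports original/validated relevant-site counts and their
ratio labelled as such, and does not claim to reproduce those four
figures.

## Known limitations

* Errors within the tolerance band are invisible by design; aggregate
  results inherit a corresponding residue (bounded by the band itself).
* The only-indicator availability-II branch (knee statement and OPS
  frequency both absent, indicator present) has no counterpart in the
  source method; it is handled like practicability with reference 2 and
  flagged `only_ref2_available` in the audit.
* A wrong-field swap into a procedure the site does not perform leaves
  a lone implausible statement that P2/R1 cannot always reject; such
  records are kept, mirroring the conservative keep-when-unsure stance.
* Compliance is site-level throughout; IIC-level totals exist only for
  comparison with association-level external data.
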