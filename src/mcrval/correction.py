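"""Rule-based correction of suspicious caseload statements.

Only two detection outcomes enter correction: availability level II
(exactly one side of the comparison is reported) and availability level
I with consistency level 4 (statement and references contradict each
other beyond the tolerance).  No record is ever deleted; when no rule
can establish a preference the original statement is accepted as valid.

Availability level II uses *support* criteria::

    K2   knee only: both references agree within tolerance, so their
         value is plausible as the missing caseload,
    P1   practicability: the OPS frequency sits in a competent
         department and the association has a competent department, so
         the frequency is more plausible than a caseload of zero,
    P2   probability: a lone caseload statement is supported when the
         same site reported a positive caseload in another year,
    PED  pediatric exemption: sites treating only children are not
         bound by the MCR, so a statement is rejected to zero,
    R1   (analog) a lone statement with no competent department
         anywhere in the association and no support from other years
         is rejected to zero.

Availability I / consistency 4 evaluates seven *rejection* criteria
(R1–R7 below); a rejected statement is replaced by the surviving
reference value, a rejected reference confirms the statement.

Corrections read only the ORIGINAL database, never each other's output,
so the audit is order-independent and re-validating a validated
database is a no-op (verified property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .detection import (
    AVAILABILITY_I,
    AVAILABILITY_II,
    DetectionResult,
    Tolerance,
    consistency_level,
    detect_record,
    deviation,
)
from .model import (
    DEFAULT_IMPUTE,
    KeyVariables,
    KeyVariablesIndex,
    ProcedureSpec,
    ReportDatabase,
    SiteReport,
)

#: Criteria that reject the target (statement); the rest reject references.
TARGET_REJECTING = frozenset(
    {"R3", "R4", "R6", "R7_digit_shift", "R7_gross", "R7_wrong_field"}
)

#: Fixed precedence for multiply-fired rejection criteria: corrections
#: carrying an explicit replacement value win over bare rejections.
PRECEDENCE = (
    "R7_digit_shift",
    "R6",
    "R4",
    "R3",
    "R5",
    "R2",
    "R1",
    "R7_gross",
    "R7_wrong_field",
)

ALL_CRITERIA = frozenset(PRECEDENCE) | {"K2", "P1", "P2", "PED"}


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for report output)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CriterionContext:
    """Everything a correction criterion may read: pure view of one record."""

    kv: KeyVariables
    spec: ProcedureSpec
    tol: Tolerance = Tolerance()
    #: multiplier for the "value is much too high" rejection (R7).
    gross_factor: float = 10.0


@dataclass
class CorrectionResult:
    iic: str
    site_code: str
    year: int
    procedure_id: str
    original: int
    validated: float
    changed: bool
    fired_criteria: set[str] = field(default_factory=set)
    provenance: str = "original_kept"
    note: str = ""

    def __post_init__(self) -> None:
        if self.validated < 0:
            raise ValueError("validated caseload must be >= 0")
        assert self.changed == (self.validated != self.original)
        if not self.fired_criteria:
            assert self.provenance == "original_kept"
        assert self.fired_criteria <= ALL_CRITERIA


def _result(kv: KeyVariables, validated: float, criteria: set[str], provenance: str,
            note: str = "") -> CorrectionResult:
    return CorrectionResult(
        iic=kv.iic,
        site_code=kv.site_code,
        year=kv.year,
        procedure_id=kv.procedure_id,
        original=kv.target,
        validated=float(validated),
        changed=float(validated) != kv.target,
        fired_criteria=criteria,
        provenance=provenance,
        note=note,
    )


def _within(tol: Tolerance, a: float, b: float) -> bool:
    """Whether two positive values are consistent within the tolerance
    range, i.e. at consistency level 1–3 (within at least one bound)."""
    if a <= 0 or b <= 0:
        return False
    abs_dev, rel_dev = deviation(a, b, tol.denominator)
    return consistency_level(abs_dev, rel_dev, tol) <= 3


def _inconsistent_with_ref1(ctx: CriterionContext) -> bool:
    """Target is level-4 inconsistent with the site's own OPS frequency."""
    kv, tol = ctx.kv, ctx.tol
    if kv.target <= 0:
        return False
    if kv.ref1 <= 0:
        return True  # no OPS support at all
    a, r = deviation(kv.target, kv.ref1, tol.denominator)
    return consistency_level(a, r, tol) == 4


def correct_availability_ii(ctx: CriterionContext) -> CorrectionResult:
    """Support/reject ladder for records where only one side is reported.

    The first applicable rule wins; with no applicable rule the original
    statement is accepted as valid.
    """
    kv, spec, tol = ctx.kv, ctx.spec, ctx.tol
    from .detection import classify_availability

    if classify_availability(kv) != AVAILABILITY_II:
        raise ValueError("correct_availability_ii requires availability level II")

    ref2 = kv.ref2 if kv.ref2 is not None else 0
    # (a) K2 -- both references agree, their value stands in for the caseload.
    if spec.qi_id is not None and kv.target == 0 and kv.ref1 > 0 and ref2 > 0:
        if _within(tol, kv.ref1, float(ref2)):
            return _result(kv, kv.ref1, {"K2"}, "ref1")
    # (b) P1 -- practicability: OPS frequency in a competent department.
    if kv.target == 0 and kv.ref1 > 0 and kv.ref1_competent_only > 0 and kv.assoc_has_competent:
        return _result(kv, kv.ref1, {"P1"}, "ref1")
    # (b') only the QI is available; treated like P1 with reference 2.
    #      The source method leaves this case open -- flagged in the audit.
    if kv.target == 0 and kv.ref1 == 0 and ref2 > 0:
        return _result(kv, float(ref2), {"P1"}, "ref2", note="only_ref2_available")
    # (c) P2 -- probability: supported by a positive caseload in another year.
    if kv.target > 0 and any(t > 0 for t in kv.other_years_targets.values()):
        return _result(kv, kv.target, {"P2"}, "original_kept")
    # (d) PED -- pediatric exemption rejects any non-zero statement.
    if spec.pediatric_exempt and kv.pediatric_only and kv.target > 0:
        return _result(kv, 0.0, {"PED"}, "zeroed")
    # (e) R1 analog -- lone statement, no competent department anywhere in
    #     the association, never a positive caseload in any other year.
    if (
        kv.target > 0
        and not kv.assoc_has_competent
        and all(t == 0 for t in kv.other_years_targets.values())
    ):
        return _result(kv, 0.0, {"R1"}, "zeroed")
    # (f) no preference possible: the original caseload is accepted.
    return _result(kv, kv.target, set(), "original_kept")


def apply_rejection_criteria(ctx: CriterionContext) -> set[str]:
    """Evaluate the seven rejection criteria for a consistency-4 record.

    Returns every criterion that fires::

        R1  no competent department carries the OPS frequency
        R2  identical OPS count duplicated in a competent and an
            incompetent department (rejects the duplicate share of ref1)
        R3  statement repeats the site's previous-year statement exactly
        R4  statement repeats a sibling site's statement or OPS frequency
        R5  knee QI was mis-aggregated to include confounder procedures
        R6  statement matches the association-level OPS total (value
            reported at association rather than site level)
        R7  other mistakes: a tenfold digit shift (``R7_digit_shift``),
            a grossly implausible value (``R7_gross``), or a value filled
            into the wrong procedure's field (``R7_wrong_field``)

    Duplicate criteria (R2, R3, R4) require exact equality -- duplicates
    are copy errors; tolerance matching would swallow genuine
    year-to-year stability.
    """
    kv, spec, tol = ctx.kv, ctx.spec, ctx.tol
    fired: set[str] = set()

    if kv.ref1 > 0 and kv.ref1_competent_only == 0:
        fired.add("R1")
    if kv.mcr_dup_competent_incompetent:
        fired.add("R2")
    prev = kv.other_years_targets.get(kv.year - 1)
    if prev is not None and kv.target > 0 and kv.target == prev and _inconsistent_with_ref1(ctx):
        fired.add("R3")
    if kv.target > 0 and any(
        kv.target == sib_t or float(kv.target) == sib_r1
        for sib_t, sib_r1 in kv.sibling_values.values()
    ):
        fired.add("R4")
    if (
        spec.qi_id is not None
        and kv.ref2 is not None
        and kv.ref2 > 0
        and kv.confounder_freq > 0
        and _within(tol, float(kv.ref2), kv.ref1 + kv.confounder_freq)
    ):
        fired.add("R5")
    if (
        kv.sibling_values
        and kv.target > 0
        and _within(tol, float(kv.target), kv.assoc_ref1)
        and _inconsistent_with_ref1(ctx)
    ):
        fired.add("R6")
    # R7: digit shift (e.g. 30 entered as 300).  The rescaled pair is
    # compared under a rescaled absolute bound: dividing by ten shrinks
    # absolute deviations tenfold, so the plain 5-case bound would let
    # any small statement pass as a "shift".
    rescaled_tol = Tolerance(tol.abs_max / 10.0, tol.rel_max, tol.denominator)
    if kv.target > 0 and kv.ref1 > 0 and kv.target > kv.ref1 and _within(
        rescaled_tol, kv.target / 10.0, kv.ref1
    ):
        fired.add("R7_digit_shift")
    # ... grossly implausible value ...
    ref_max = max(kv.ref1, float(kv.ref2 or 0))
    if ref_max > 0 and kv.target > ctx.gross_factor * ref_max:
        fired.add("R7_gross")
    # ... or the caseload of another procedure entered in this field.
    if kv.target > 0 and any(
        other_r1 > 0 and _within(tol, float(kv.target), other_r1)
        for _t, other_r1 in kv.other_procedures.values()
    ):
        fired.add("R7_wrong_field")
    return fired


def correct_consistency_4(ctx: CriterionContext) -> CorrectionResult:
    """Resolve a consistency-4 record from its fired rejection criteria.

    A rejected statement is replaced by the surviving reference (ref1
    after the R2 duplicate correction; ref2 only when ref1 is also
    rejected; zero when nothing survives).  If only references are
    rejected, the statement is confirmed.  Pediatric-exempt sites
    treating only children are zeroed outright.
    """
    kv, spec = ctx.kv, ctx.spec
    if spec.pediatric_exempt and kv.pediatric_only and kv.target > 0:
        return _result(kv, 0.0, {"PED"}, "zeroed")
    fired = apply_rejection_criteria(ctx)
    if not fired:
        return _result(kv, kv.target, set(), "original_kept")

    ref1_value = kv.ref1_competent_only if "R2" in fired else kv.ref1
    ref1_ok = "R1" not in fired and ref1_value > 0
    ref2 = float(kv.ref2 or 0)
    ref2_ok = "R5" not in fired and ref2 > 0

    if fired & TARGET_REJECTING:
        if ref1_ok:
            return _result(kv, ref1_value, fired, "ref1")
        if ref2_ok:
            return _result(kv, ref2, fired, "ref2")
        return _result(kv, 0.0, fired, "zeroed")
    # only reference values were rejected: the statement is confirmed.
    return _result(kv, kv.target, fired, "original_kept")


AUDIT_COLUMNS = [
    "year",
    "iic",
    "site_code",
    "procedure_id",
    "availability",
    "consistency",
    "chosen_ref",
    "abs_dev",
    "rel_dev",
    "target_available",
    "ref1_available",
    "ref2_available",
    "original",
    "validated",
    "changed",
    "fired_criteria",
    "provenance",
    "note",
    "threshold",
]


def correct_record(
    kv: KeyVariables,
    spec: ProcedureSpec,
    detection: DetectionResult,
    tol: Tolerance,
    gross_factor: float = 10.0,
) -> CorrectionResult:
    """Dispatch one record to its correction branch (pass-through otherwise)."""
    ctx = CriterionContext(kv=kv, spec=spec, tol=tol, gross_factor=gross_factor)
    if detection.availability == AVAILABILITY_II:
        return correct_availability_ii(ctx)
    if detection.availability == AVAILABILITY_I and detection.consistency == 4:
        return correct_consistency_4(ctx)
    return _result(kv, kv.target, set(), "original_kept")


def validate_all(
    db: ReportDatabase,
    specs: Iterable[ProcedureSpec],
    tol: Tolerance = Tolerance(),
    impute: float = DEFAULT_IMPUTE,
    gross_factor: float = 10.0,
) -> tuple[ReportDatabase, pd.DataFrame]:
    """Validate every record of a database.

    Returns the validated database (statements replaced by validated
    caseloads, rounded half away from zero for the integer report
    format) and the audit table with one row per record: detection
    outcome, original and validated value, fired criteria and value
    provenance.  Availability-III and consistency-1..3 records pass
    through unchanged; no record is deleted.
    """
    specs = list(specs)
    spec_map = {s.procedure_id: s for s in specs}
    index = KeyVariablesIndex(db, specs, impute)
    rows = []
    validated_db = ReportDatabase()
    for iic, site_code, year in db.sorted_keys():
        src = db.reports[(iic, site_code, year)]
        new_report = SiteReport(
            year=year,
            iic=iic,
            site_code=site_code,
            pediatric_only=src.pediatric_only,
            departments=[
                # departments are reference data; carried over verbatim
                d
                for d in src.departments
            ],
            mcr_statements=dict(src.mcr_statements),
            qi_statements=dict(src.qi_statements),
        )
        for pid, spec in spec_map.items():
            kv = index.extract(iic, site_code, year, pid)
            det = detect_record(kv, tol)
            res = correct_record(kv, spec, det, tol, gross_factor)
            validated_int = int(round_half_away(res.validated))
            if validated_int > 0:
                new_report.mcr_statements[pid] = validated_int
            else:
                new_report.mcr_statements.pop(pid, None)
            rows.append(
                {
                    "year": year,
                    "iic": iic,
                    "site_code": site_code,
                    "procedure_id": pid,
                    "availability": det.availability,
                    "consistency": det.consistency,
                    "chosen_ref": det.chosen_ref,
                    "abs_dev": det.abs_dev,
                    "rel_dev": det.rel_dev,
                    "target_available": det.target_available,
                    "ref1_available": det.ref1_available,
                    "ref2_available": det.ref2_available,
                    "original": res.original,
                    "validated": res.validated,
                    "changed": res.changed,
                    "fired_criteria": ";".join(sorted(res.fired_criteria)),
                    "provenance": res.provenance,
                    "note": res.note,
                    "threshold": spec.threshold,
                }
            )
        validated_db.add(new_report)
    audit = pd.DataFrame(rows, columns=AUDIT_COLUMNS)
    return validated_db, audit
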