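"""Availability and consistency classification of caseload records.

Every (site, year, procedure) record is first classified by *data
availability* — which of the key variables are non-zero ("data not
available refers to key variables with a value of zero"):

* level I   — the caseload statement and at least one reference variable
              are available; their consistency is then measured,
* level II  — only the statement, or only reference variable(s), are
              available (the typical under-reporting signature),
* level III — nothing is available; the site is probably irrelevant to
              the procedure.

Level-I records are graded by the deviation between the statement and
the closest reference under a combined tolerance of 5 cases absolute and
20% relative:

* consistency 1 — no deviation,
* consistency 2 — within both bounds,
* consistency 3 — within exactly one bound,
* consistency 4 — outside both bounds (suspicious, enters correction).

Levels 1–3 are acceptable; boundary values are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .model import (
    DEFAULT_IMPUTE,
    KeyVariables,
    KeyVariablesIndex,
    ProcedureSpec,
    ReportDatabase,
)

AVAILABILITY_I = "I"
AVAILABILITY_II = "II"
AVAILABILITY_III = "III"


@dataclass(frozen=True)
class Tolerance:
    """Combined deviation tolerance for cross-field comparisons.

    ``abs_max`` is in cases (default 5), ``rel_max`` a fraction (default
    0.20).  ``denominator`` selects the base of the relative deviation;
    the default ``"max"`` divides by the larger of the two values, which
    is symmetric and bounded in [0, 1].
    """

    abs_max: float = 5.0
    rel_max: float = 0.20
    denominator: str = "max"

    def __post_init__(self) -> None:
        if self.abs_max < 0:
            raise ValueError("abs_max must be >= 0")
        if not 0.0 <= self.rel_max <= 1.0:
            raise ValueError("rel_max must be in [0, 1]")
        if self.denominator not in ("max", "ref", "target"):
            raise ValueError(f"unknown denominator {self.denominator!r}")

    def within(self, abs_dev: float, rel_dev: float) -> bool:
        """Both bounds satisfied (the acceptable band used by correction rules)."""
        return abs_dev <= self.abs_max and rel_dev <= self.rel_max


@dataclass(frozen=True)
class DetectionResult:
    iic: str
    site_code: str
    year: int
    procedure_id: str
    availability: str
    consistency: Optional[int]
    chosen_ref: Optional[str]
    abs_dev: Optional[float]
    rel_dev: Optional[float]
    target_available: bool
    ref1_available: bool
    ref2_available: bool


def classify_availability(kv: KeyVariables) -> str:
    """Assign availability level I, II or III; the levels partition all records."""
    target = kv.target > 0
    ref = kv.ref1 > 0 or (kv.ref2 is not None and kv.ref2 > 0)
    if target and ref:
        return AVAILABILITY_I
    if target or ref:
        return AVAILABILITY_II
    return AVAILABILITY_III


def deviation(
    target: float, ref: float, denominator: str = "max"
) -> tuple[float, float]:
    """Absolute and relative deviation between two available values.

    Only meaningful inside availability level I, hence both inputs must
    be positive.
    """
    if target <= 0 or ref <= 0:
        raise ValueError(
            f"deviation requires positive values (got target={target}, ref={ref}); "
            "outside availability level I it is undefined"
        )
    abs_dev = abs(target - ref)
    if denominator == "max":
        base = max(target, ref)
    elif denominator == "ref":
        base = ref
    else:
        base = target
    return abs_dev, abs_dev / base


def consistency_level(abs_dev: float, rel_dev: float, tol: Tolerance) -> int:
    if abs_dev == 0:
        return 1
    abs_ok = abs_dev <= tol.abs_max
    rel_ok = rel_dev <= tol.rel_max
    if abs_ok and rel_ok:
        return 2
    if abs_ok or rel_ok:
        return 3
    return 4


def classify_consistency(kv: KeyVariables, tol: Tolerance) -> DetectionResult:
    """Grade an availability-I record by its closest reference variable.

    When both references are available the smaller absolute deviation is
    used; ties break on the smaller relative deviation and then prefer
    reference variable 1 (the OPS frequency, which exists for every
    procedure).
    """
    availability = classify_availability(kv)
    if availability != AVAILABILITY_I:
        raise ValueError(f"classify_consistency requires availability I, got {availability}")
    chosen = None
    abs_dev = rel_dev = None
    if kv.ref1 > 0:
        abs_dev, rel_dev = deviation(kv.target, kv.ref1, tol.denominator)
        chosen = "ref1"
    if kv.ref2 is not None and kv.ref2 > 0:
        a2, r2 = deviation(kv.target, kv.ref2, tol.denominator)
        if chosen is None or a2 < abs_dev or (a2 == abs_dev and r2 < rel_dev):
            abs_dev, rel_dev, chosen = a2, r2, "ref2"
    assert chosen is not None
    return DetectionResult(
        iic=kv.iic,
        site_code=kv.site_code,
        year=kv.year,
        procedure_id=kv.procedure_id,
        availability=AVAILABILITY_I,
        consistency=consistency_level(abs_dev, rel_dev, tol),
        chosen_ref=chosen,
        abs_dev=abs_dev,
        rel_dev=rel_dev,
        target_available=True,
        ref1_available=kv.ref1 > 0,
        ref2_available=kv.ref2 is not None and kv.ref2 > 0,
    )


def detect_record(kv: KeyVariables, tol: Tolerance) -> DetectionResult:
    """Full detection for one record: availability, plus consistency at level I."""
    availability = classify_availability(kv)
    if availability == AVAILABILITY_I:
        return classify_consistency(kv, tol)
    return DetectionResult(
        iic=kv.iic,
        site_code=kv.site_code,
        year=kv.year,
        procedure_id=kv.procedure_id,
        availability=availability,
        consistency=None,
        chosen_ref=None,
        abs_dev=None,
        rel_dev=None,
        target_available=kv.target > 0,
        ref1_available=kv.ref1 > 0,
        ref2_available=kv.ref2 is not None and kv.ref2 > 0,
    )


DETECTION_COLUMNS = [
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
]


def detect_all(
    db: ReportDatabase,
    specs: Iterable[ProcedureSpec],
    tol: Tolerance = Tolerance(),
    impute: float = DEFAULT_IMPUTE,
    index: Optional[KeyVariablesIndex] = None,
) -> pd.DataFrame:
    """Detection table with one row per (site, year, procedure) record."""
    specs = list(specs)
    if index is None:
        index = KeyVariablesIndex(db, specs, impute)
    rows = []
    for iic, site_code, year, pid in index.keys():
        kv = index.extract(iic, site_code, year, pid)
        r = detect_record(kv, tol)
        rows.append(
            {
                "year": r.year,
                "iic": r.iic,
                "site_code": r.site_code,
                "procedure_id": r.procedure_id,
                "availability": r.availability,
                "consistency": r.consistency,
                "chosen_ref": r.chosen_ref,
                "abs_dev": r.abs_dev,
                "rel_dev": r.rel_dev,
                "target_available": r.target_available,
                "ref1_available": r.ref1_available,
                "ref2_available": r.ref2_available,
            }
        )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)
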