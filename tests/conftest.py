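"""Shared fixtures: hand-built report databases and a reusable simulation."""

from __future__ import annotations

import pytest

from mcrval import DEFAULT_PROCEDURES, ReportDatabase, SiteReport
from mcrval.model import DepartmentRecord
from mcrval.simulate import SimulationConfig, simulate, with_default_errors

SPEC = {s.procedure_id: s for s in DEFAULT_PROCEDURES}

#: competent department codes of the shipped config, for fixture building
DEPT_SURGERY = "1500"  # oesophagus / pancreas
DEPT_HAEMATOLOGY = "0500"  # stem cells
DEPT_ORTHO = "2300"  # knee
DEPT_OTHER = "0100"  # competent for nothing


def make_report(
    iic: str,
    site_code: str,
    year: int,
    mcr: dict | None = None,
    ops: list[tuple[str, str, object]] | None = None,
    qi: dict | None = None,
    pediatric: bool = False,
    depts: list[str] | None = None,
) -> SiteReport:
    """Build one site report; departments are inferred from OPS rows
    unless given explicitly."""
    dept_codes = list(depts) if depts else []
    for dept_code, _code, _count in ops or []:
        if dept_code not in dept_codes:
            dept_codes.append(dept_code)
    if DEPT_OTHER not in dept_codes:
        dept_codes.append(DEPT_OTHER)
    departments = {c: DepartmentRecord(c) for c in dept_codes}
    for dept_code, code, count in ops or []:
        departments[dept_code].ops_counts[code] = count
    return SiteReport(
        year=year,
        iic=iic,
        site_code=site_code,
        pediatric_only=pediatric,
        departments=list(departments.values()),
        mcr_statements=dict(mcr or {}),
        qi_statements=dict(qi or {}),
    )


def make_db(*reports: SiteReport) -> ReportDatabase:
    db = ReportDatabase()
    for r in reports:
        db.add(r)
    return db


@pytest.fixture(scope="session")
def specs():
    return DEFAULT_PROCEDURES


@pytest.fixture(scope="session")
def corrupted_sim():
    """A mid-sized landscape with the full default error taxonomy."""
    cfg = with_default_errors(
        SimulationConfig(seed=202, n_associations=150, ops_overcount_rate=0.02)
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """A landscape with no errors, no OPS noise and no masking."""
    return simulate(SimulationConfig(seed=303, n_associations=80, masking_enabled=False))
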