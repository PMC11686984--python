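"""Synthetic hospital landscape with injected reporting errors.

The generator emulates the structure of the GHQR-derived study data:
hospital associations (shared IIC) of one to a few sites, per-site
per-year true caseloads for the four MCR procedures, department-level
OPS frequencies with privacy masking of counts 1–3, and the knee
quality indicator.  The ground truth plays the role of the external
caseload oracle (the reimbursement statistic), and the error log makes
detection and correction testable by parameter recovery.

The documented reporting-error taxonomy is injected with per-class
rates; at most one error class strikes a record, so every residual
discrepancy is attributable:

* ``nonreport``      the caseload statement is left empty (dominant for
                     sub-threshold sites, hence two rates),
* ``dup_prev_year``  the previous year's published statement is copied,
* ``dup_sibling``    another site of the association is copied,
* ``assoc_entry``    the association total is entered at site level,
* ``digit_shift``    a tenfold typo (30 entered as 300),
* ``wrong_field``    two procedures' statements are swapped,
* ``qi_misaggregate`` the knee QI wrongly includes unicondylar/revision
                     replacements (the confounder frequency).

Masking is applied *after* error injection: suppression is a property
of publication, not a reporting error.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    MASKED,
    DepartmentRecord,
    ProcedureSpec,
    ReportDatabase,
    SiteReport,
)
from .procedures import DEFAULT_PROCEDURES

#: department code present at every site but competent for no procedure.
GENERIC_DEPARTMENT = "0100"
EXTRA_DEPARTMENT = "2000"

ERROR_CLASSES = (
    "nonreport",
    "dup_prev_year",
    "dup_sibling",
    "assoc_entry",
    "digit_shift",
    "wrong_field",
    "qi_misaggregate",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic landscape.

    Participation shares and caseload distributions are calibrated so
    that the per-procedure share of inactive sites and the mean and
    compliant-share of positive caseloads match the federal summary
    tables of the 2016–2021 validation study (see ``docs/methods.md``).
    """

    seed: int = 0
    n_associations: int = 100
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021)
    #: distribution of association size (number of sites).
    sites_per_association: tuple[tuple[int, float], ...] = ((1, 0.80), (2, 0.15), (3, 0.05))
    p_pediatric_only: float = 0.01
    #: probability that an extra incompetent department exists at a site.
    p_extra_department: float = 0.30
    #: per-procedure probability that a site performs the procedure at all
    #: (the zero-inflation weight of the caseload mixture).
    participation: tuple[tuple[str, float], ...] = (
        ("oesophagus", 0.15),
        ("pancreas", 0.25),
        ("stem_cells", 0.04),
        ("knee", 0.44),
    )
    #: per-procedure (log-median, log-sigma) of the discretised lognormal
    #: annual caseload of a performing site.
    caseload_lognormal: tuple[tuple[str, tuple[float, float]], ...] = (
        ("oesophagus", (math.log(10.0), 0.75)),
        ("pancreas", (math.log(15.0), 0.90)),
        ("stem_cells", (math.log(56.0), 0.90)),
        ("knee", (math.log(113.0), 0.70)),
    )
    #: probability that a true case carries one extra MCR-relevant code,
    #: inflating the OPS frequency relative to the caseload.
    ops_overcount_rate: float = 0.0
    #: mean confounder caseload (knee) as a fraction of the true caseload.
    confounder_mean_fraction: float = 0.30
    # error-class rates
    p_nonreport_small: float = 0.0
    p_nonreport_large: float = 0.0
    p_dup_prev_year: float = 0.0
    p_dup_sibling: float = 0.0
    p_assoc_level_entry: float = 0.0
    p_digit_shift: float = 0.0
    p_wrong_field: float = 0.0
    p_qi_misaggregate: float = 0.0
    masking_enabled: bool = True
    procedures: tuple[ProcedureSpec, ...] = DEFAULT_PROCEDURES

    def __post_init__(self) -> None:
        for name in (
            "p_pediatric_only",
            "p_extra_department",
            "ops_overcount_rate",
            "p_nonreport_small",
            "p_nonreport_large",
            "p_dup_prev_year",
            "p_dup_sibling",
            "p_assoc_level_entry",
            "p_digit_shift",
            "p_wrong_field",
            "p_qi_misaggregate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        weights = [w for _, w in self.sites_per_association]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("sites_per_association weights must be a distribution")
        if any(k < 1 for k, _ in self.sites_per_association):
            raise ValueError("associations have at least one site")
        pids = {s.procedure_id for s in self.procedures}
        if {p for p, _ in self.participation} != pids or {
            p for p, _ in self.caseload_lognormal
        } != pids:
            raise ValueError("participation/caseload settings must cover all procedures")

    @property
    def participation_map(self) -> dict[str, float]:
        return dict(self.participation)

    @property
    def caseload_map(self) -> dict[str, tuple[float, float]]:
        return dict(self.caseload_lognormal)


def default_error_rates() -> dict[str, float]:
    """Default full-taxonomy rates: non-reporting by small-caseload sites
    dominates, matching the study's error-source ranking."""
    return dict(
        p_nonreport_small=0.25,
        p_nonreport_large=0.03,
        p_dup_prev_year=0.02,
        p_dup_sibling=0.01,
        p_assoc_level_entry=0.02,
        p_digit_shift=0.002,
        p_wrong_field=0.005,
        p_qi_misaggregate=0.02,
    )


def with_default_errors(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Copy of ``config`` with the default error taxonomy switched on."""
    rates = default_error_rates()
    rates.update(overrides)
    return replace(config, **rates)


@dataclass
class GroundTruth:
    """True caseloads per (iic, site_code, year, procedure_id)."""

    caseloads: dict[tuple[str, str, int, str], int] = field(default_factory=dict)
    pediatric_only: dict[tuple[str, str], bool] = field(default_factory=dict)

    def get(self, iic: str, site_code: str, year: int, procedure_id: str) -> int:
        return self.caseloads[(iic, site_code, year, procedure_id)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "iic": i, "site_code": s, "procedure_id": p, "caseload": c}
            for (i, s, y, p), c in sorted(self.caseloads.items())
        ]
        return pd.DataFrame(
            rows, columns=["year", "iic", "site_code", "procedure_id", "caseload"]
        )

    def iic_totals(self) -> pd.DataFrame:
        """Ground-truth caseloads aggregated to association (IIC) level —
        the synthetic analogue of the external reimbursement oracle."""
        df = self.to_frame()
        return (
            df.groupby(["iic", "year", "procedure_id"], as_index=False)["caseload"]
            .sum()
            .rename(columns={"caseload": "total_caseload"})
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        truth = cls()
        for row in df.itertuples(index=False):
            truth.caseloads[(row.iic, row.site_code, int(row.year), row.procedure_id)] = int(
                row.caseload
            )
        return truth


@dataclass(frozen=True)
class ErrorEvent:
    iic: str
    site_code: str
    year: int
    procedure_id: str
    error_class: str
    field_affected: str  # "mcr" or "qi"
    value_before: int
    value_after: int


def write_error_log(events: Iterable[ErrorEvent], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(e.__dict__, sort_keys=True) + "\n")


def read_error_log(path: Union[str, Path]) -> list[ErrorEvent]:
    events = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                events.append(ErrorEvent(**json.loads(line)))
    return events


def _site_departments(
    config: SimulationConfig, participates: dict[str, bool], extra: bool
) -> list[str]:
    codes = {GENERIC_DEPARTMENT}
    for spec in config.procedures:
        if participates[spec.procedure_id] and spec.competent_departments:
            codes.add(sorted(spec.competent_departments)[0])
    if extra:
        codes.add(EXTRA_DEPARTMENT)
    return sorted(codes)


def generate_truth(config: SimulationConfig) -> tuple[GroundTruth, ReportDatabase]:
    """Draw the ground-truth landscape and render it into clean reports.

    In the clean database the statement, the OPS frequency (up to the
    configured overcounting) and the knee QI all equal the true
    caseload; no masking and no errors are applied yet.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = GroundTruth()
    db = ReportDatabase()
    sizes = [k for k, _ in config.sites_per_association]
    size_w = [w for _, w in config.sites_per_association]
    part = config.participation_map
    dists = config.caseload_map
    for a in range(config.n_associations):
        iic = f"26{a:07d}"
        n_sites = int(rng.choice(sizes, p=size_w))
        for s in range(n_sites):
            site_code = f"{s:02d}"
            pediatric = bool(rng.random() < config.p_pediatric_only)
            truth.pediatric_only[(iic, site_code)] = pediatric
            participates: dict[str, bool] = {}
            for spec in config.procedures:
                if pediatric and spec.pediatric_exempt:
                    participates[spec.procedure_id] = False
                else:
                    participates[spec.procedure_id] = bool(
                        rng.random() < part[spec.procedure_id]
                    )
            extra_dept = bool(rng.random() < config.p_extra_department)
            dept_codes = _site_departments(config, participates, extra_dept)
            for year in config.years:
                report = SiteReport(
                    year=year,
                    iic=iic,
                    site_code=site_code,
                    pediatric_only=pediatric,
                    departments=[DepartmentRecord(c) for c in dept_codes],
                )
                depts = {d.dept_code: d for d in report.departments}
                for spec in config.procedures:
                    pid = spec.procedure_id
                    if not participates[pid]:
                        truth.caseloads[(iic, site_code, year, pid)] = 0
                        continue
                    mu, sigma = dists[pid]
                    caseload = max(1, int(round(rng.lognormal(mu, sigma))))
                    truth.caseloads[(iic, site_code, year, pid)] = caseload
                    report.mcr_statements[pid] = caseload
                    extra = (
                        int(rng.binomial(caseload, config.ops_overcount_rate))
                        if config.ops_overcount_rate > 0
                        else 0
                    )
                    comp = sorted(spec.competent_departments)[0]
                    code = sorted(spec.mcr_ops_codes)[0]
                    depts[comp].ops_counts[code] = caseload + extra
                    if spec.confounder_ops_codes:
                        conf = int(
                            rng.poisson(config.confounder_mean_fraction * caseload)
                        )
                        if conf > 0:
                            ccode = sorted(spec.confounder_ops_codes)[0]
                            depts[comp].ops_counts[ccode] = conf
                    if spec.qi_id is not None:
                        report.qi_statements[spec.qi_id] = caseload
                db.add(report)
    return truth, db


def mask_small_counts(db: ReportDatabase) -> ReportDatabase:
    """Privacy masking: every OPS count in {1, 2, 3} becomes MASKED.

    Caseload statements and QI counts are never masked.
    """
    masked = copy.deepcopy(db)
    for report in masked.reports.values():
        for dept in report.departments:
            for code, count in dept.ops_counts.items():
                if isinstance(count, int) and 1 <= count <= 3:
                    dept.ops_counts[code] = MASKED
    return masked


def _confounder_total(report: SiteReport, spec: ProcedureSpec) -> int:
    total = 0
    for dept in report.departments:
        for code in spec.confounder_ops_codes:
            c = dept.ops_counts.get(code, 0)
            if isinstance(c, int):
                total += c
    return total


def inject_errors(
    db_clean: ReportDatabase,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ReportDatabase, list[ErrorEvent]]:
    """Corrupt the clean database with the configured error taxonomy.

    Records are visited in year order; at most one error class strikes a
    record, sampled rate-proportionally.  The previous-year duplicate
    copies the statement as *published* (possibly itself corrupted),
    mirroring a hospital copying from the report it actually filed; all
    other classes read the clean database.  Replaying the returned log
    on the clean database reproduces the corrupted one exactly.
    """
    rng = np.random.default_rng([config.seed, 1])
    db = copy.deepcopy(db_clean)
    events: list[ErrorEvent] = []
    handled: set[tuple[str, str, int, str]] = set()
    years = sorted(config.years)
    spec_map = {s.procedure_id: s for s in config.procedures}
    members_map: dict[tuple[str, int], list[str]] = {}
    for iic, site_code, year in db_clean.reports:
        members_map.setdefault((iic, year), []).append(site_code)
    for m in members_map.values():
        m.sort()

    def clean_stmt(iic: str, sc: str, year: int, pid: str) -> int:
        return db_clean.reports[(iic, sc, year)].mcr_statement(pid)

    def set_stmt(report: SiteReport, pid: str, value: int) -> None:
        if value > 0:
            report.mcr_statements[pid] = value
        else:
            report.mcr_statements.pop(pid, None)

    for year in years:
        site_keys = sorted(k for k in db.reports if k[2] == year)
        for iic, site_code, _y in site_keys:
            report = db.reports[(iic, site_code, year)]
            clean_report = db_clean.reports[(iic, site_code, year)]
            members = members_map[(iic, year)]
            for spec in config.procedures:
                pid = spec.procedure_id
                key = (iic, site_code, year, pid)
                if key in handled:
                    continue
                stmt = report.mcr_statement(pid)
                tv = truth.get(iic, site_code, year, pid)
                choices: list[tuple[str, float]] = []
                if stmt > 0:
                    rate = (
                        config.p_nonreport_small
                        if tv < spec.threshold
                        else config.p_nonreport_large
                    )
                    if rate > 0:
                        choices.append(("nonreport", rate))
                prev_stmt = (
                    db.reports[(iic, site_code, year - 1)].mcr_statement(pid)
                    if (iic, site_code, year - 1) in db.reports
                    else 0
                )
                if stmt > 0 and prev_stmt > 0 and prev_stmt != stmt and config.p_dup_prev_year > 0:
                    choices.append(("dup_prev_year", config.p_dup_prev_year))
                sib_values = [
                    clean_stmt(iic, sc, year, pid)
                    for sc in members
                    if sc != site_code and clean_stmt(iic, sc, year, pid) > 0
                    and clean_stmt(iic, sc, year, pid) != stmt
                ]
                if stmt > 0 and sib_values and config.p_dup_sibling > 0:
                    choices.append(("dup_sibling", config.p_dup_sibling))
                assoc_total = sum(clean_stmt(iic, sc, year, pid) for sc in members)
                if (
                    stmt > 0
                    and len(members) > 1
                    and assoc_total != stmt
                    and config.p_assoc_level_entry > 0
                ):
                    choices.append(("assoc_entry", config.p_assoc_level_entry))
                if stmt > 0 and config.p_digit_shift > 0:
                    choices.append(("digit_shift", config.p_digit_shift))
                swap_candidates = [
                    q
                    for q in spec_map
                    if q != pid
                    and (iic, site_code, year, q) not in handled
                    and clean_report.mcr_statement(q) > 0
                    and clean_report.mcr_statement(q) != stmt
                ]
                if stmt > 0 and swap_candidates and config.p_wrong_field > 0:
                    choices.append(("wrong_field", config.p_wrong_field))
                conf_total = _confounder_total(clean_report, spec)
                qi_value = report.qi_statement(spec.qi_id) if spec.qi_id else 0
                if qi_value > 0 and conf_total > 0 and config.p_qi_misaggregate > 0:
                    choices.append(("qi_misaggregate", config.p_qi_misaggregate))

                total_rate = sum(r for _, r in choices)
                if total_rate > 1.0 + 1e-12:
                    raise ValueError(
                        f"error rates sum to {total_rate:.3f} > 1 for record {key}"
                    )
                u = rng.random()
                chosen: Optional[str] = None
                cum = 0.0
                for cls, rate in choices:
                    cum += rate
                    if u < cum:
                        chosen = cls
                        break
                if chosen is None:
                    continue
                handled.add(key)
                if chosen == "nonreport":
                    set_stmt(report, pid, 0)
                    events.append(ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, 0))
                elif chosen == "dup_prev_year":
                    set_stmt(report, pid, prev_stmt)
                    events.append(
                        ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, prev_stmt)
                    )
                elif chosen == "dup_sibling":
                    v = int(sib_values[int(rng.integers(len(sib_values)))])
                    set_stmt(report, pid, v)
                    events.append(ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, v))
                elif chosen == "assoc_entry":
                    set_stmt(report, pid, assoc_total)
                    events.append(
                        ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, assoc_total)
                    )
                elif chosen == "digit_shift":
                    set_stmt(report, pid, stmt * 10)
                    events.append(
                        ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, stmt * 10)
                    )
                elif chosen == "wrong_field":
                    q = swap_candidates[int(rng.integers(len(swap_candidates)))]
                    other = clean_report.mcr_statement(q)
                    set_stmt(report, pid, other)
                    set_stmt(report, q, stmt)
                    handled.add((iic, site_code, year, q))
                    events.append(
                        ErrorEvent(iic, site_code, year, pid, chosen, "mcr", stmt, other)
                    )
                    events.append(
                        ErrorEvent(iic, site_code, year, q, chosen, "mcr", other, stmt)
                    )
                elif chosen == "qi_misaggregate":
                    assert spec.qi_id is not None
                    after = qi_value + conf_total
                    report.qi_statements[spec.qi_id] = after
                    events.append(
                        ErrorEvent(iic, site_code, year, pid, chosen, "qi", qi_value, after)
                    )
    return db, events


def replay_error_log(
    db_clean: ReportDatabase,
    events: Iterable[ErrorEvent],
    procedures: Iterable[ProcedureSpec] = DEFAULT_PROCEDURES,
) -> ReportDatabase:
    """Re-apply a recorded error log to the clean database.

    By construction this reproduces the corrupted database exactly —
    the oracle-equivalence property of the log.
    """
    spec_map = {s.procedure_id: s for s in procedures}
    db = copy.deepcopy(db_clean)
    for e in events:
        report = db.get(e.iic, e.site_code, e.year)
        if e.field_affected == "mcr":
            if e.value_after > 0:
                report.mcr_statements[e.procedure_id] = e.value_after
            else:
                report.mcr_statements.pop(e.procedure_id, None)
        elif e.field_affected == "qi":
            qi_id = spec_map[e.procedure_id].qi_id
            assert qi_id is not None
            report.qi_statements[qi_id] = e.value_after
        else:  # pragma: no cover - log schema guard
            raise ValueError(f"unknown field {e.field_affected!r}")
    return db


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: GroundTruth
    clean_db: ReportDatabase
    corrupted_db: ReportDatabase
    published_db: ReportDatabase
    error_log: list[ErrorEvent]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Full generator pipeline: truth → clean reports → errors → masking."""
    truth, clean = generate_truth(config)
    corrupted, events = inject_errors(clean, truth, config)
    published = mask_small_counts(corrupted) if config.masking_enabled else corrupted
    return SimulationResult(
        config=config,
        truth=truth,
        clean_db=clean,
        corrupted_db=corrupted,
        published_db=published,
        error_log=events,
    )
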