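"""Domain model for GHQR-like hospital quality reports.

The German Hospital Quality Report (GHQR) is the compulsory annual
self-report of every German hospital site.  For validating minimum
caseload requirements (MCR) three cross-comparable *key variables* exist
per (site, year, procedure):

* the **target variable** -- the MCR caseload the site states itself,
* **reference variable 1** -- the frequency of the MCR-defining OPS
  procedure codes summed over the site's medical departments, and
* **reference variable 2** -- for total knee replacement only, the case
  count of the external quality indicator "indication for elective knee
  endoprosthesis - primary implantation" (ID 54020).

Sites belonging to one hospital association share an institution
identification code (IIC) and are distinguished by a site code; the
association report is the sum of its site reports.  Department-level OPS
frequencies between 1 and 3 are suppressed for privacy and are imputed
with a configurable constant (default 1.5) during aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union


class _Masked:
    """Sentinel for a privacy-suppressed OPS count (1 <= n <= 3)."""

    _instance: Optional["_Masked"] = None

    def __new__(cls) -> "_Masked":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MASKED"


#: The single masked-count sentinel.  OPS cells are either a non-negative
#: integer or MASKED; MCR and QI statements are never masked.
MASKED = _Masked()

Count = Union[int, _Masked]

#: Default imputation constant for a masked OPS count.
DEFAULT_IMPUTE = 1.5


@dataclass(frozen=True)
class ProcedureSpec:
    """One minimum-caseload procedure and everything needed to validate it.

    Parameters
    ----------
    procedure_id:
        Short key, e.g. ``"knee"``.
    threshold:
        Minimum number of cases per year and hospital site.
    mcr_ops_codes:
        OPS codes whose department frequencies define reference variable 1.
    confounder_ops_codes:
        OPS codes that are similar but do *not* count toward the MCR
        (e.g. unicondylar or revision knee replacement); their frequency
        is used to recognise a mis-aggregated quality indicator.
    competent_departments:
        Department codes plausibly able to perform the procedure.
    qi_id:
        Quality-indicator id providing reference variable 2, if any.
    pediatric_exempt:
        Whether sites treating only children are exempt from the MCR.
    """

    procedure_id: str
    display_name: str
    threshold: int
    mcr_ops_codes: frozenset[str]
    confounder_ops_codes: frozenset[str] = frozenset()
    competent_departments: frozenset[str] = frozenset()
    qi_id: Optional[str] = None
    pediatric_exempt: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold}")
        if not self.mcr_ops_codes:
            raise ValueError("mcr_ops_codes must be non-empty")
        overlap = set(self.mcr_ops_codes) & set(self.confounder_ops_codes)
        if overlap:
            raise ValueError(f"MCR and confounder OPS codes overlap: {overlap}")


@dataclass
class DepartmentRecord:
    """One medical department of a site with its OPS frequency table."""

    dept_code: str
    ops_counts: dict[str, Count] = field(default_factory=dict)

    def count(self, ops_code: str) -> Count:
        return self.ops_counts.get(ops_code, 0)


@dataclass
class SiteReport:
    """Annual report of one hospital site.

    ``mcr_statements`` and ``qi_statements`` map ids to plain integers;
    a missing entry means "not reported", which by convention equals a
    caseload of zero (data not available <=> value 0).
    """

    year: int
    iic: str
    site_code: str
    pediatric_only: bool = False
    departments: list[DepartmentRecord] = field(default_factory=list)
    mcr_statements: dict[str, int] = field(default_factory=dict)
    qi_statements: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.iic, self.site_code, self.year)

    def mcr_statement(self, procedure_id: str) -> int:
        return int(self.mcr_statements.get(procedure_id, 0))

    def qi_statement(self, qi_id: Optional[str]) -> int:
        if qi_id is None:
            return 0
        return int(self.qi_statements.get(qi_id, 0))

    def has_department(self, codes: Iterable[str]) -> bool:
        codes = set(codes)
        return any(d.dept_code in codes for d in self.departments)


@dataclass
class AssociationReport:
    """Sum of the site reports sharing one IIC in one year."""

    iic: str
    year: int
    member_sites: list[str]
    mcr_totals: dict[str, float]
    ops_totals: dict[str, float]
    qi_totals: dict[str, float]


@dataclass
class ReportDatabase:
    """Multi-year, multi-association collection of site reports."""

    reports: dict[tuple[str, str, int], SiteReport] = field(default_factory=dict)

    def add(self, report: SiteReport) -> None:
        if report.key in self.reports:
            raise ValueError(f"duplicate site report key {report.key}")
        self.reports[report.key] = report

    def get(self, iic: str, site_code: str, year: int) -> SiteReport:
        try:
            return self.reports[(iic, site_code, year)]
        except KeyError:
            raise KeyError(f"no report for ({iic!r}, {site_code!r}, {year})") from None

    def __len__(self) -> int:
        return len(self.reports)

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        return key in self.reports

    @property
    def year_range(self) -> tuple[int, int]:
        years = [k[2] for k in self.reports]
        return (min(years), max(years)) if years else (0, -1)

    def years(self) -> list[int]:
        return sorted({k[2] for k in self.reports})

    def sorted_keys(self) -> list[tuple[str, str, int]]:
        return sorted(self.reports, key=lambda k: (k[2], k[0], k[1]))

    def association_members(self, iic: str, year: int) -> list[SiteReport]:
        """All site reports of one association in one year, sorted by site code."""
        members = [
            r
            for (r_iic, _sc, r_year), r in self.reports.items()
            if r_iic == iic and r_year == year
        ]
        return sorted(members, key=lambda r: r.site_code)

    def site_years(self, iic: str, site_code: str) -> list[int]:
        return sorted(y for (i, s, y) in self.reports if i == iic and s == site_code)


@dataclass(frozen=True)
class KeyVariables:
    """The comparable values for one (site, year, procedure) record.

    Everything a detection or correction rule may read, extracted purely
    from a :class:`ReportDatabase`.  ``ref1`` values may be fractional
    because masked department counts contribute the imputation constant.
    """

    iic: str
    site_code: str
    year: int
    procedure_id: str
    target: int
    ref1: float
    ref1_competent_only: float
    confounder_freq: float
    ref2: Optional[int]
    assoc_target: float
    assoc_ref1: float
    other_years_targets: Mapping[int, int]
    sibling_values: Mapping[str, tuple[int, float]]
    other_procedures: Mapping[str, tuple[int, float]]
    site_has_competent: bool
    assoc_has_competent: bool
    pediatric_only: bool
    mcr_dup_competent_incompetent: bool

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.iic, self.site_code, self.year, self.procedure_id)


def _cell_value(count: Count, impute: float) -> float:
    if count is MASKED:
        return impute
    return float(count)


def aggregate_ops_frequency(
    site: SiteReport,
    spec: ProcedureSpec,
    impute: float = DEFAULT_IMPUTE,
    scope: str = "all",
) -> float:
    """Aggregate department-level OPS counts to a site-level frequency.

    ``scope`` selects the departments and code set:

    * ``"all"`` -- MCR-defining codes over every department (reference
      variable 1 as compared with the caseload statement),
    * ``"competent_only"`` -- MCR-defining codes restricted to competent
      departments,
    * ``"confounders"`` -- confounder codes over every department.

    A masked cell contributes ``impute`` (default 1.5).
    """
    if impute <= 0:
        raise ValueError("impute must be positive")
    if scope == "all":
        codes, depts = spec.mcr_ops_codes, None
    elif scope == "competent_only":
        codes, depts = spec.mcr_ops_codes, spec.competent_departments
    elif scope == "confounders":
        codes, depts = spec.confounder_ops_codes, None
    else:
        raise ValueError(f"unknown scope {scope!r}")
    total = 0.0
    for dept in site.departments:
        if depts is not None and dept.dept_code not in depts:
            continue
        for code in codes:
            c = dept.ops_counts.get(code)
            if c is None or c == 0:
                continue
            total += _cell_value(c, impute)
    return total


def _has_mcr_duplicate(site: SiteReport, spec: ProcedureSpec) -> bool:
    """Whether an identical numeric MCR-code count occurs in a competent
    and an incompetent department (the duplicate-entry error pattern R2)."""
    competent: set[tuple[str, int]] = set()
    incompetent: set[tuple[str, int]] = set()
    for dept in site.departments:
        bucket = competent if dept.dept_code in spec.competent_departments else incompetent
        for code in spec.mcr_ops_codes:
            c = dept.ops_counts.get(code)
            if isinstance(c, int) and c > 0:
                bucket.add((code, c))
    return bool(competent & incompetent)


class KeyVariablesIndex:
    """Precomputed per-record aggregates for fast repeated extraction.

    Extraction is pure: the index is a cache over an immutable snapshot
    of the database; building it twice yields identical values.
    """

    def __init__(
        self,
        db: ReportDatabase,
        specs: Iterable[ProcedureSpec],
        impute: float = DEFAULT_IMPUTE,
    ) -> None:
        self.db = db
        self.specs = {s.procedure_id: s for s in specs}
        self.impute = impute
        # per (site key, procedure): (target, ref1, ref1_comp, conf, ref2,
        #                             site_has_comp, dup_flag)
        self._site: dict[tuple[tuple[str, str, int], str], tuple] = {}
        # per (iic, year, procedure): (sum target, sum ref1, any competent)
        self._assoc: dict[tuple[str, int, str], tuple[float, float, bool]] = {}
        # per (iic, site_code, procedure): {year: target}
        self._years: dict[tuple[str, str, str], dict[int, int]] = {}
        # per (iic, year): member site codes, sorted
        self._members: dict[tuple[str, int], list[str]] = {}
        for key, report in db.reports.items():
            iic, site_code, year = key
            self._members.setdefault((iic, year), []).append(site_code)
            for pid, spec in self.specs.items():
                target = report.mcr_statement(pid)
                ref1 = aggregate_ops_frequency(report, spec, impute, "all")
                ref1c = aggregate_ops_frequency(report, spec, impute, "competent_only")
                conf = aggregate_ops_frequency(report, spec, impute, "confounders")
                ref2 = report.qi_statement(spec.qi_id) if spec.qi_id else None
                has_comp = report.has_department(spec.competent_departments)
                dup = _has_mcr_duplicate(report, spec)
                self._site[(key, pid)] = (target, ref1, ref1c, conf, ref2, has_comp, dup)
                akey = (iic, year, pid)
                at, ar, ac = self._assoc.get(akey, (0.0, 0.0, False))
                self._assoc[akey] = (at + target, ar + ref1, ac or has_comp)
                self._years.setdefault((iic, site_code, pid), {})[year] = target
        for members in self._members.values():
            members.sort()

    def keys(self) -> list[tuple[str, str, int, str]]:
        """Every (iic, site_code, year, procedure_id) record, in canonical order."""
        out = []
        for iic, site_code, year in self.db.sorted_keys():
            for pid in self.specs:
                out.append((iic, site_code, year, pid))
        return out

    def extract(self, iic: str, site_code: str, year: int, procedure_id: str) -> KeyVariables:
        skey = (iic, site_code, year)
        report = self.db.get(iic, site_code, year)
        target, ref1, ref1c, conf, ref2, has_comp, dup = self._site[(skey, procedure_id)]
        assoc_target, assoc_ref1, assoc_comp = self._assoc[(iic, year, procedure_id)]
        series = self._years[(iic, site_code, procedure_id)]
        other_years = {y: t for y, t in series.items() if y != year}
        siblings: dict[str, tuple[int, float]] = {}
        for member_code in self._members[(iic, year)]:
            if member_code == site_code:
                continue
            mt, mr1 = self._site[((iic, member_code, year), procedure_id)][:2]
            siblings[member_code] = (mt, mr1)
        other_procs: dict[str, tuple[int, float]] = {}
        for pid in self.specs:
            if pid == procedure_id:
                continue
            ot, or1 = self._site[(skey, pid)][:2]
            other_procs[pid] = (ot, or1)
        return KeyVariables(
            iic=iic,
            site_code=site_code,
            year=year,
            procedure_id=procedure_id,
            target=target,
            ref1=ref1,
            ref1_competent_only=ref1c,
            confounder_freq=conf,
            ref2=ref2,
            assoc_target=assoc_target,
            assoc_ref1=assoc_ref1,
            other_years_targets=other_years,
            sibling_values=siblings,
            other_procedures=other_procs,
            site_has_competent=has_comp,
            assoc_has_competent=assoc_comp,
            pediatric_only=report.pediatric_only,
            mcr_dup_competent_incompetent=dup,
        )


def extract_key_variables(
    db: ReportDatabase,
    key: tuple[str, str, int],
    spec: ProcedureSpec,
    all_specs: Optional[Iterable[ProcedureSpec]] = None,
    impute: float = DEFAULT_IMPUTE,
) -> KeyVariables:
    """Extract the :class:`KeyVariables` for one (site, year) and procedure.

    ``all_specs`` supplies the other procedures' values for cross-field
    rules; it defaults to ``[spec]`` (no cross-procedure context).
    """
    if key not in db:
        raise KeyError(f"unknown report key {key}")
    specs = list(all_specs) if all_specs is not None else [spec]
    if spec.procedure_id not in {s.procedure_id for s in specs}:
        specs = [spec] + specs
    index = KeyVariablesIndex(db, specs, impute)
    return index.extract(key[0], key[1], key[2], spec.procedure_id)


def build_association_report(
    db: ReportDatabase,
    iic: str,
    year: int,
    specs: Iterable[ProcedureSpec],
    impute: float = DEFAULT_IMPUTE,
) -> AssociationReport:
    """Aggregate the member site reports of one association.

    Every aggregate equals the sum over member sites, masked OPS cells
    contributing the imputation constant.
    """
    members = db.association_members(iic, year)
    if not members:
        raise KeyError(f"no reports for association {iic!r} in {year}")
    specs = list(specs)
    mcr_totals: dict[str, float] = {}
    ops_totals: dict[str, float] = {}
    qi_totals: dict[str, float] = {}
    for spec in specs:
        pid = spec.procedure_id
        mcr_totals[pid] = float(sum(m.mcr_statement(pid) for m in members))
        ops_totals[pid] = sum(
            aggregate_ops_frequency(m, spec, impute, "all") for m in members
        )
        if spec.qi_id is not None:
            qi_totals[spec.qi_id] = float(
                sum(m.qi_statement(spec.qi_id) for m in members)
            )
    return AssociationReport(
        iic=iic,
        year=year,
        member_sites=[m.site_code for m in members],
        mcr_totals=mcr_totals,
        ops_totals=ops_totals,
        qi_totals=qi_totals,
    )
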