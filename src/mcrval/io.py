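"""Readers and writers for the package's tabular report schema.

An input directory holds five UTF-8 comma-separated files with header
rows::

    sites.csv        year,iic,site_code,pediatric_only
    departments.csv  year,iic,site_code,dept_code
    ops.csv          year,iic,site_code,dept_code,ops_code,count
    mcr.csv          year,iic,site_code,procedure_id,caseload
    qi.csv           year,iic,site_code,qi_id,count

An OPS ``count`` is a non-negative integer or ``*`` for a
privacy-masked small count.  MCR caseloads and QI counts are plain
integers; a missing row means "not reported", i.e. zero.  Writing is
canonical (sorted rows), so load -> write -> load is the identity.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

from .model import MASKED, Count, DepartmentRecord, ReportDatabase, SiteReport

MASK_TOKEN = "*"

_FILES = ("sites.csv", "departments.csv", "mcr.csv", "ops.csv", "qi.csv")


class SchemaError(ValueError):
    """A malformed or inconsistent input file."""


def _read_rows(path: Path, columns: tuple[str, ...]) -> list[dict[str, str]]:
    if not path.is_file():
        raise SchemaError(f"missing input file: {path}")
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != columns:
            raise SchemaError(
                f"{path.name}: expected header {','.join(columns)}, "
                f"got {reader.fieldnames}"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            if any(v is None for v in row.values()):
                raise SchemaError(f"{path.name}:{i}: short row {row}")
            rows.append(row)
        return rows


def _int_field(path_name: str, lineno: int, name: str, value: str) -> int:
    try:
        parsed = int(value)
    except ValueError:
        raise SchemaError(f"{path_name}:{lineno}: {name} {value!r} is not an integer") from None
    if parsed < 0:
        raise SchemaError(f"{path_name}:{lineno}: negative {name} {parsed}")
    return parsed


def _parse_count(path_name: str, lineno: int, value: str) -> Count:
    if value == MASK_TOKEN:
        return MASKED
    return _int_field(path_name, lineno, "count", value)


def _parse_bool(path_name: str, lineno: int, value: str) -> bool:
    if value in ("true", "1"):
        return True
    if value in ("false", "0"):
        return False
    raise SchemaError(f"{path_name}:{lineno}: bad boolean {value!r}")


def load_reports(input_dir: Union[str, Path]) -> ReportDatabase:
    """Load a :class:`ReportDatabase` from a schema directory.

    Malformed rows, duplicate site keys, negative counts and rows
    referring to unknown sites are fatal (:class:`SchemaError`).
    """
    input_dir = Path(input_dir)
    db = ReportDatabase()

    for i, row in enumerate(
        _read_rows(input_dir / "sites.csv", ("year", "iic", "site_code", "pediatric_only")),
        start=2,
    ):
        report = SiteReport(
            year=_int_field("sites.csv", i, "year", row["year"]),
            iic=row["iic"],
            site_code=row["site_code"],
            pediatric_only=_parse_bool("sites.csv", i, row["pediatric_only"]),
        )
        try:
            db.add(report)
        except ValueError as exc:
            raise SchemaError(f"sites.csv:{i}: {exc}") from None

    def _site(fname: str, lineno: int, row: dict[str, str]) -> SiteReport:
        key = (row["iic"], row["site_code"], _int_field(fname, lineno, "year", row["year"]))
        if key not in db:
            raise SchemaError(f"{fname}:{lineno}: unknown site {key}")
        return db.reports[key]

    departments: dict[tuple[str, str, int, str], DepartmentRecord] = {}
    for i, row in enumerate(
        _read_rows(input_dir / "departments.csv", ("year", "iic", "site_code", "dept_code")),
        start=2,
    ):
        report = _site("departments.csv", i, row)
        dkey = report.key + (row["dept_code"],)
        if dkey in departments:
            raise SchemaError(f"departments.csv:{i}: duplicate department {dkey}")
        dept = DepartmentRecord(dept_code=row["dept_code"])
        departments[dkey] = dept
        report.departments.append(dept)

    for i, row in enumerate(
        _read_rows(
            input_dir / "ops.csv",
            ("year", "iic", "site_code", "dept_code", "ops_code", "count"),
        ),
        start=2,
    ):
        report = _site("ops.csv", i, row)
        dkey = report.key + (row["dept_code"],)
        if dkey not in departments:
            raise SchemaError(f"ops.csv:{i}: unknown department {dkey}")
        dept = departments[dkey]
        if row["ops_code"] in dept.ops_counts:
            raise SchemaError(f"ops.csv:{i}: duplicate OPS cell {dkey + (row['ops_code'],)}")
        dept.ops_counts[row["ops_code"]] = _parse_count("ops.csv", i, row["count"])

    for i, row in enumerate(
        _read_rows(input_dir / "mcr.csv", ("year", "iic", "site_code", "procedure_id", "caseload")),
        start=2,
    ):
        report = _site("mcr.csv", i, row)
        if row["procedure_id"] in report.mcr_statements:
            raise SchemaError(f"mcr.csv:{i}: duplicate MCR statement")
        report.mcr_statements[row["procedure_id"]] = _int_field(
            "mcr.csv", i, "caseload", row["caseload"]
        )

    for i, row in enumerate(
        _read_rows(input_dir / "qi.csv", ("year", "iic", "site_code", "qi_id", "count")),
        start=2,
    ):
        report = _site("qi.csv", i, row)
        if row["qi_id"] in report.qi_statements:
            raise SchemaError(f"qi.csv:{i}: duplicate QI statement")
        report.qi_statements[row["qi_id"]] = _int_field("qi.csv", i, "count", row["count"])

    return db


def write_reports(db: ReportDatabase, output_dir: Union[str, Path]) -> None:
    """Write a database to the schema directory in canonical order.

    Zero-valued MCR/QI statements and zero OPS cells are omitted
    (absence means zero); departments are written even when empty.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    def _open(name: str, header: tuple[str, ...]):
        fh = open(output_dir / name, "w", encoding="utf-8", newline="")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        return fh, writer

    keys = db.sorted_keys()
    fh, w = _open("sites.csv", ("year", "iic", "site_code", "pediatric_only"))
    with fh:
        for iic, sc, year in keys:
            r = db.reports[(iic, sc, year)]
            w.writerow([year, iic, sc, "true" if r.pediatric_only else "false"])

    fh, w = _open("departments.csv", ("year", "iic", "site_code", "dept_code"))
    with fh:
        for iic, sc, year in keys:
            r = db.reports[(iic, sc, year)]
            for dept in sorted(r.departments, key=lambda d: d.dept_code):
                w.writerow([year, iic, sc, dept.dept_code])

    fh, w = _open("mcr.csv", ("year", "iic", "site_code", "procedure_id", "caseload"))
    with fh:
        for iic, sc, year in keys:
            r = db.reports[(iic, sc, year)]
            for pid in sorted(r.mcr_statements):
                v = r.mcr_statements[pid]
                if v != 0:
                    w.writerow([year, iic, sc, pid, v])

    fh, w = _open("ops.csv", ("year", "iic", "site_code", "dept_code", "ops_code", "count"))
    with fh:
        for iic, sc, year in keys:
            r = db.reports[(iic, sc, year)]
            for dept in sorted(r.departments, key=lambda d: d.dept_code):
                for code in sorted(dept.ops_counts):
                    c = dept.ops_counts[code]
                    if c == 0:
                        continue
                    w.writerow(
                        [year, iic, sc, dept.dept_code, code, MASK_TOKEN if c is MASKED else c]
                    )

    fh, w = _open("qi.csv", ("year", "iic", "site_code", "qi_id", "count"))
    with fh:
        for iic, sc, year in keys:
            r = db.reports[(iic, sc, year)]
            for qi_id in sorted(r.qi_statements):
                v = r.qi_statements[qi_id]
                if v != 0:
                    w.writerow([year, iic, sc, qi_id, v])
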