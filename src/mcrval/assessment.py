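"""Aggregated assessment of detection and correction outcomes.

Produces the study's tabular summaries: per procedure and year the
availability/consistency tallies and the before/after contrast of
caseload totals, relevance (caseload > 0) and MCR compliance
(caseload >= threshold); the eight before/after error-source categories
built from the 0/S/G caseload bands; and the association-level (IIC)
aggregation used for comparison against an external caseload oracle.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .correction import round_half_away
from .model import ProcedureSpec

CATEGORY_ZERO = "0"
CATEGORY_S = "S"  # positive but below the MCR threshold
CATEGORY_G = "G"  # at or above the MCR threshold

UNCHANGED = "UNCHANGED"

#: the eight before/after contrast combinations of a changed caseload.
CONTRAST_CATEGORIES = ("0-S", "S-0", "0-G", "G-0", "S-G", "G-S", "S-S", "G-G")


def share_pct(part: float, total: float) -> float:
    """Percentage to one decimal, rounded half away from zero."""
    if total == 0:
        raise ZeroDivisionError("share of an empty total is undefined")
    return float(
        (Decimal(100) * Decimal(repr(part)) / Decimal(repr(total))).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def categorize_caseload(caseload: float, threshold: int) -> str:
    """Band a caseload: 0, S (0 < caseload < threshold) or G (>= threshold)."""
    if caseload < 0:
        raise ValueError(f"caseload must be >= 0, got {caseload}")
    if caseload == 0:
        return CATEGORY_ZERO
    if caseload < threshold:
        return CATEGORY_S
    return CATEGORY_G


def contrast_category(original: float, validated: float, threshold: int) -> str:
    """Before/after band pair of a correction; UNCHANGED when equal.

    ``S-S`` and ``G-G`` therefore only occur when the value changed
    within its band.
    """
    if original == validated:
        return UNCHANGED
    return f"{categorize_caseload(original, threshold)}-{categorize_caseload(validated, threshold)}"


def completeness_caseload(original_total: float, validated_total: float) -> float:
    """Caseload completeness of the original data, in percent (one decimal)."""
    if validated_total <= 0:
        raise ValueError("validated total must be positive")
    return share_pct(original_total, validated_total)


def suspicious_share(
    n_consistency_4: int, n_only_target: int, n_only_reference: int, n_possibly_relevant: int
) -> float:
    """Share of possibly-relevant sites whose statement needs processing."""
    return share_pct(n_consistency_4 + n_only_target + n_only_reference, n_possibly_relevant)


SUMMARY_COLUMNS = [
    "procedure_id",
    "year",
    "n_reports",
    "n_availability_iii",
    "n_possibly_relevant",
    "n_consistency_1",
    "n_consistency_2",
    "n_consistency_3",
    "n_consistency_4",
    "n_only_target",
    "n_only_reference",
    "n_corrected",
    "relevant_original",
    "relevant_validated",
    "relevant_change",
    "compliant_original",
    "compliant_validated",
    "compliant_change",
    "noncompliant_original",
    "noncompliant_validated",
    "noncompliant_change",
    "caseload_original",
    "caseload_validated",
    "caseload_change",
]


def _summary_block(g: pd.DataFrame, pid: str, year) -> dict:
    avail = g["availability"]
    cons = g["consistency"]
    thr = g["threshold"]
    original = g["original"]
    validated = g["validated"]
    # fractional validated values (masking imputation) must not have their
    # compliance band changed by output rounding
    frac = validated[validated != validated.round()]
    for v, t in zip(frac, thr[frac.index]):
        assert categorize_caseload(v, t) == categorize_caseload(
            round_half_away(v), t
        ), f"fractional caseload {v} straddles threshold {t}"
    rel_orig = int((original > 0).sum())
    rel_val = int((validated > 0).sum())
    comp_orig = int((original >= thr).sum())
    comp_val = int((validated >= thr).sum())
    return {
        "procedure_id": pid,
        "year": year,
        "n_reports": len(g),
        "n_availability_iii": int((avail == "III").sum()),
        "n_possibly_relevant": int((avail != "III").sum()),
        "n_consistency_1": int((cons == 1).sum()),
        "n_consistency_2": int((cons == 2).sum()),
        "n_consistency_3": int((cons == 3).sum()),
        "n_consistency_4": int((cons == 4).sum()),
        "n_only_target": int(((avail == "II") & g["target_available"]).sum()),
        "n_only_reference": int(((avail == "II") & ~g["target_available"]).sum()),
        "n_corrected": int(g["changed"].sum()),
        "relevant_original": rel_orig,
        "relevant_validated": rel_val,
        "relevant_change": rel_val - rel_orig,
        "compliant_original": comp_orig,
        "compliant_validated": comp_val,
        "compliant_change": comp_val - comp_orig,
        "noncompliant_original": rel_orig - comp_orig,
        "noncompliant_validated": rel_val - comp_val,
        "noncompliant_change": (rel_val - comp_val) - (rel_orig - comp_orig),
        "caseload_original": float(original.sum()),
        "caseload_validated": float(validated.sum()),
        "caseload_change": float(validated.sum() - original.sum()),
    }


def summarize(audit: pd.DataFrame, specs: Iterable[ProcedureSpec]) -> pd.DataFrame:
    """Summary table in the study's row structure, per procedure and year
    plus a per-procedure total row (``year == "total"``).

    The additivity invariants hold on every run: consistency 1–4 plus
    only-target plus only-reference equals the possibly-relevant count,
    and relevant = compliant + non-compliant.
    """
    rows = []
    order = [s.procedure_id for s in specs]
    for pid in order:
        sub = audit[audit["procedure_id"] == pid]
        if sub.empty:
            continue
        for year, g in sub.groupby("year"):
            rows.append(_summary_block(g, pid, int(year)))
        rows.append(_summary_block(sub, pid, "total"))
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    parts = summary[
        [
            "n_consistency_1",
            "n_consistency_2",
            "n_consistency_3",
            "n_consistency_4",
            "n_only_target",
            "n_only_reference",
        ]
    ].sum(axis=1)
    assert (parts == summary["n_possibly_relevant"]).all()
    return summary


def summary_shares(summary: pd.DataFrame) -> pd.DataFrame:
    """Derived percentages over the possibly-relevant denominator."""
    rows = []
    for row in summary.itertuples(index=False):
        if row.n_possibly_relevant == 0:
            continue
        rows.append(
            {
                "procedure_id": row.procedure_id,
                "year": row.year,
                "suspicious_share_pct": suspicious_share(
                    row.n_consistency_4,
                    row.n_only_target,
                    row.n_only_reference,
                    row.n_possibly_relevant,
                ),
                "corrected_share_pct": share_pct(row.n_corrected, row.n_possibly_relevant),
                "consistency_1_share_pct": share_pct(
                    row.n_consistency_1, row.n_possibly_relevant
                ),
                "relevant_change_share_pct": share_pct(
                    row.relevant_change, row.n_possibly_relevant
                ),
                "caseload_completeness_pct": completeness_caseload(
                    row.caseload_original, row.caseload_validated
                )
                if row.caseload_validated > 0
                else None,
            }
        )
    return pd.DataFrame(rows)


def contrast_table(audit: pd.DataFrame, specs: Iterable[ProcedureSpec]) -> pd.DataFrame:
    """Error-source contrast: changed records per 0/S/G category pair.

    One row per (procedure, year, category) with the number of corrected
    sites and the summed caseload delta; the categories partition the
    changed records, so the per-category deltas sum to the total
    caseload change.
    """
    changed = audit[audit["changed"]]
    rows = []
    order = [s.procedure_id for s in specs]
    for pid in order:
        sub = changed[changed["procedure_id"] == pid]
        for year in sorted(sub["year"].unique()):
            g = sub[sub["year"] == year]
            cats = [
                contrast_category(o, v, t)
                for o, v, t in zip(g["original"], g["validated"], g["threshold"])
            ]
            assert UNCHANGED not in cats
            for cat in CONTRAST_CATEGORIES:
                mask = [c == cat for c in cats]
                n = sum(mask)
                delta = float((g["validated"] - g["original"])[mask].sum())
                rows.append(
                    {
                        "procedure_id": pid,
                        "year": int(year),
                        "category": cat,
                        "n_sites": n,
                        "case_delta": delta,
                    }
                )
    return pd.DataFrame(
        rows, columns=["procedure_id", "year", "category", "n_sites", "case_delta"]
    )


def aggregate_to_iic(audit: pd.DataFrame, specs: Iterable[ProcedureSpec]) -> pd.DataFrame:
    """Sum validated caseloads over the sites sharing an IIC.

    MCR compliance remains a site-level notion: the table also carries
    the number of member sites whose own validated caseload meets the
    threshold, and the IIC totals exist purely for comparison against
    an association-level external oracle.
    """
    thresholds = {s.procedure_id: s.threshold for s in specs}
    df = audit.copy()
    df["site_compliant"] = [
        v >= thresholds[p] for v, p in zip(df["validated"], df["procedure_id"])
    ]
    out = (
        df.groupby(["iic", "year", "procedure_id"], as_index=False)
        .agg(
            total_caseload=("validated", "sum"),
            n_sites=("validated", "size"),
            n_sites_compliant=("site_compliant", "sum"),
        )
        .sort_values(["procedure_id", "year", "iic"])
        .reset_index(drop=True)
    )
    return out


def compare_external(
    validated_iic: pd.DataFrame,
    oracle_iic: pd.DataFrame,
    specs: Iterable[ProcedureSpec],
) -> pd.DataFrame:
    """Federal-level comparison of validated caseloads with an oracle.

    Both tables carry (iic, year, procedure_id, total_caseload); they
    must cover exactly the same keys.  Per procedure and year the
    federal total is split into cases from IICs meeting the threshold
    at IIC level and cases from those that do not, for both sources,
    and the relative discrepancy of the federal totals is reported in
    percent.
    """
    thresholds = {s.procedure_id: s.threshold for s in specs}
    keys = ["iic", "year", "procedure_id"]
    merged = validated_iic[keys + ["total_caseload"]].merge(
        oracle_iic[keys + ["total_caseload"]],
        on=keys,
        how="outer",
        suffixes=("_validated", "_oracle"),
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        missing = merged[merged["_merge"] != "both"][keys + ["_merge"]]
        raise ValueError(
            f"oracle and validated tables cover different keys:\n{missing.head()}"
        )
    rows = []
    for (pid, year), g in merged.groupby(["procedure_id", "year"]):
        thr = thresholds[pid]
        v_comp = float(g.loc[g["total_caseload_validated"] >= thr, "total_caseload_validated"].sum())
        v_total = float(g["total_caseload_validated"].sum())
        o_comp = float(g.loc[g["total_caseload_oracle"] >= thr, "total_caseload_oracle"].sum())
        o_total = float(g["total_caseload_oracle"].sum())
        if o_total > 0:
            discrepancy = 100.0 * abs(v_total - o_total) / o_total
        else:
            discrepancy = 0.0 if v_total == 0 else float("inf")
        rows.append(
            {
                "procedure_id": pid,
                "year": int(year),
                "validated_total": v_total,
                "oracle_total": o_total,
                "validated_compliant_cases": v_comp,
                "validated_noncompliant_cases": v_total - v_comp,
                "oracle_compliant_cases": o_comp,
                "oracle_noncompliant_cases": o_total - o_comp,
                "rel_discrepancy_pct": discrepancy,
            }
        )
    return pd.DataFrame(rows).sort_values(["procedure_id", "year"]).reset_index(drop=True)
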