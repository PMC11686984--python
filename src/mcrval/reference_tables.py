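"""Published federal summary tallies of the 2016–2021 GHQR validation.

These are the six-year totals of the study's summary tables for the
four MCR procedures — site counts per detection category, correction
frequencies and caseload totals before and after validation.  They are
*inputs*: the package's assessment formulas recompute the published
percentages and contrasts from them, which ties the summary arithmetic
to the original federal dataset that is itself access-restricted.
"""

from __future__ import annotations

import pandas as pd

from .assessment import (
    completeness_caseload,
    share_pct,
    suspicious_share,
)

#: Six-year totals per procedure (2016–2021, 14 247 site reports overall).
PUBLISHED_TOTALS: dict[str, dict[str, int]] = {
    "oesophagus": dict(
        n_reports=14247,
        n_availability_iii=12067,
        n_possibly_relevant=2180,
        n_consistency_1=1369,
        n_consistency_2=174,
        n_consistency_3=32,
        n_consistency_4=22,
        n_only_target=70,
        n_only_reference=513,
        n_corrected=517,
        relevant_original=1662,
        relevant_validated=2095,
        relevant_change=433,
        compliant_original=1052,
        compliant_validated=1058,
        compliant_change=6,
        noncompliant_original=610,
        noncompliant_validated=1037,
        noncompliant_change=427,
        caseload_original=26737,
        caseload_validated=27738,
        caseload_change=1001,
    ),
    "pancreas": dict(
        n_reports=14247,
        n_availability_iii=10733,
        n_possibly_relevant=3514,
        n_consistency_1=2480,
        n_consistency_2=273,
        n_consistency_3=68,
        n_consistency_4=43,
        n_only_target=70,
        n_only_reference=580,
        n_corrected=536,
        relevant_original=2931,
        relevant_validated=3389,
        relevant_change=458,
        compliant_original=2284,
        compliant_validated=2295,
        compliant_change=11,
        noncompliant_original=647,
        noncompliant_validated=1094,
        noncompliant_change=447,
        caseload_original=72163,
        caseload_validated=73622,
        caseload_change=1459,
    ),
    "stem_cells": dict(
        n_reports=14247,
        n_availability_iii=13660,
        n_possibly_relevant=587,
        n_consistency_1=369,
        n_consistency_2=122,
        n_consistency_3=22,
        n_consistency_4=6,
        n_only_target=20,
        n_only_reference=48,
        n_corrected=48,
        relevant_original=539,
        relevant_validated=547,
        relevant_change=8,
        compliant_original=451,
        compliant_validated=445,
        compliant_change=-6,
        noncompliant_original=88,
        noncompliant_validated=102,
        noncompliant_change=14,
        caseload_original=48253,
        caseload_validated=48604,
        caseload_change=351,
    ),
    "knee": dict(
        n_reports=14247,
        n_availability_iii=7959,
        n_possibly_relevant=6288,
        n_consistency_1=4279,
        n_consistency_2=825,
        n_consistency_3=443,
        n_consistency_4=209,
        n_only_target=30,
        n_only_reference=502,
        n_corrected=496,
        relevant_original=5786,
        relevant_validated=6021,
        relevant_change=235,
        compliant_original=5161,
        compliant_validated=5294,
        compliant_change=133,
        noncompliant_original=625,
        noncompliant_validated=727,
        noncompliant_change=102,
        caseload_original=858961,
        caseload_validated=866473,
        caseload_change=7512,
    ),
}


def published_summary() -> pd.DataFrame:
    """The published totals as one summary row per procedure."""
    rows = []
    for pid, vals in PUBLISHED_TOTALS.items():
        rows.append({"procedure_id": pid, "year": "total", **vals})
    return pd.DataFrame(rows)


def published_headline_figures() -> dict[str, float]:
    """Recompute the study's headline percentages from the tallies.

    All values are derived by the assessment formulas — nothing here is
    a stored percentage.
    """
    out: dict[str, float] = {}
    for pid, t in PUBLISHED_TOTALS.items():
        out[f"suspicious_share_{pid}_pct"] = suspicious_share(
            t["n_consistency_4"],
            t["n_only_target"],
            t["n_only_reference"],
            t["n_possibly_relevant"],
        )
        out[f"corrected_share_{pid}_pct"] = share_pct(
            t["n_corrected"], t["n_possibly_relevant"]
        )
        out[f"consistency_1_share_{pid}_pct"] = share_pct(
            t["n_consistency_1"], t["n_possibly_relevant"]
        )
        out[f"relevant_change_share_{pid}_pct"] = share_pct(
            t["relevant_change"], t["n_possibly_relevant"]
        )
        out[f"caseload_completeness_{pid}_pct"] = completeness_caseload(
            t["caseload_original"], t["caseload_validated"]
        )
        out[f"caseload_change_{pid}"] = float(
            t["caseload_validated"] - t["caseload_original"]
        )
    return out
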