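"""Caseload banding, contrast categories, summary arithmetic, IIC comparison."""

from __future__ import annotations

import pandas as pd
import pytest

from mcrval import (
    aggregate_to_iic,
    categorize_caseload,
    compare_external,
    completeness_caseload,
    contrast_category,
    contrast_table,
    summarize,
    summary_shares,
    validate_all,
)
from mcrval.assessment import CONTRAST_CATEGORIES, share_pct, suspicious_share
from mcrval.reference_tables import PUBLISHED_TOTALS, published_headline_figures

from conftest import DEPT_SURGERY, SPEC, make_db, make_report


class TestCategorisation:
    @pytest.mark.parametrize(
        "caseload, threshold, expected",
        [(0, 10, "0"), (7, 10, "S"), (10, 10, "G"), (9.5, 10, "S"), (50, 50, "G")],
    )
    def test_zero_s_g_bands(self, caseload, threshold, expected):
        assert categorize_caseload(caseload, threshold) == expected

    def test_negative_caseload_rejected(self):
        with pytest.raises(ValueError):
            categorize_caseload(-1, 10)

    @pytest.mark.parametrize(
        "original, validated, threshold, expected",
        [
            (0, 7, 10, "0-S"),
            (12, 0, 10, "G-0"),
            (60, 55, 50, "G-G"),
            (9, 9, 10, "UNCHANGED"),
            (3, 8, 10, "S-S"),
        ],
    )
    def test_contrast_pairs(self, original, validated, threshold, expected):
        assert contrast_category(original, validated, threshold) == expected


class TestCompleteness:
    @pytest.mark.parametrize(
        "original, validated, expected",
        [(72163, 73622, 98.0), (858961, 866473, 99.1), (555, 555, 100.0)],
    )
    def test_caseload_completeness_percent(self, original, validated, expected):
        assert completeness_caseload(original, validated) == expected

    def test_zero_validated_total_rejected(self):
        with pytest.raises(ValueError):
            completeness_caseload(5, 0)


class TestPublishedArithmetic:
    """The assessment formulas reproduce the study's printed percentages
    from the printed category tallies."""

    def test_detection_tallies_are_additive(self):
        for t in PUBLISHED_TOTALS.values():
            parts = (
                t["n_consistency_1"] + t["n_consistency_2"] + t["n_consistency_3"]
                + t["n_consistency_4"] + t["n_only_target"] + t["n_only_reference"]
            )
            assert parts == t["n_possibly_relevant"]
            assert t["n_availability_iii"] + t["n_possibly_relevant"] == t["n_reports"]
            assert t["relevant_original"] == t["compliant_original"] + t["noncompliant_original"]
            assert t["relevant_validated"] == t["compliant_validated"] + t["noncompliant_validated"]

    def test_headline_percentages(self):
        figures = published_headline_figures()
        assert figures["suspicious_share_knee_pct"] == 11.8
        assert figures["suspicious_share_pancreas_pct"] == 19.7
        assert figures["corrected_share_oesophagus_pct"] == 23.7
        assert figures["corrected_share_knee_pct"] == 7.9
        assert figures["caseload_completeness_pancreas_pct"] == 98.0
        assert figures["caseload_completeness_knee_pct"] == 99.1
        assert figures["caseload_change_oesophagus"] == 1001
        assert figures["relevant_change_share_oesophagus_pct"] == 19.9
        assert figures["consistency_1_share_oesophagus_pct"] == 62.8

    def test_rounding_is_half_away_from_zero_to_one_decimal(self):
        assert share_pct(1, 8) == 12.5
        assert share_pct(125, 1000) == 12.5
        assert share_pct(1245, 10000) == 12.5  # 12.45 rounds up, not to even
        assert suspicious_share(1, 1, 0, 16) == 12.5


class TestSummarize:
    def test_single_injected_nonreport_hand_trace(self, specs):
        """One site, truth 7 below threshold 10, statement omitted: the
        summary shows one correction, +1 relevant, +1 non-compliant,
        +7 caseload."""
        db = make_db(make_report("9", "00", 2019, ops=[(DEPT_SURGERY, "5-423", 7)]))
        _vdb, audit = validate_all(db, specs)
        summary = summarize(audit, specs).set_index(["procedure_id", "year"])
        row = summary.loc[("oesophagus", 2019)]
        assert row.n_corrected == 1
        assert row.n_only_reference == 1 and row.n_possibly_relevant == 1
        assert row.relevant_change == 1 and row.noncompliant_change == 1
        assert row.compliant_change == 0 and row.caseload_change == 7.0
        shares = summary_shares(summarize(audit, specs))
        oeso = shares[(shares.procedure_id == "oesophagus") & (shares.year == 2019)]
        assert oeso.suspicious_share_pct.iloc[0] == 100.0

    def test_clean_run_has_no_changes(self, clean_sim, specs):
        _vdb, audit = validate_all(clean_sim.published_db, specs)
        summary = summarize(audit, specs)
        assert (summary.n_corrected == 0).all()
        assert (summary.caseload_change == 0).all()
        assert (summary.relevant_change == 0).all()

    def test_category_counts_partition_possibly_relevant(self, corrupted_sim, specs):
        _vdb, audit = validate_all(corrupted_sim.published_db, specs)
        summary = summarize(audit, specs)
        parts = summary[
            ["n_consistency_1", "n_consistency_2", "n_consistency_3", "n_consistency_4",
             "n_only_target", "n_only_reference"]
        ].sum(axis=1)
        assert (parts == summary.n_possibly_relevant).all()
        assert (
            summary.relevant_validated
            == summary.compliant_validated + summary.noncompliant_validated
        ).all()


class TestContrastTable:
    def test_category_deltas_sum_to_total_caseload_change(self, corrupted_sim, specs):
        _vdb, audit = validate_all(corrupted_sim.published_db, specs)
        summary = summarize(audit, specs).set_index(["procedure_id", "year"])
        contrast = contrast_table(audit, specs)
        assert set(contrast.category) <= set(CONTRAST_CATEGORIES)
        for pid in SPEC:
            sub = contrast[contrast.procedure_id == pid]
            for year in sub.year.unique():
                g = sub[sub.year == year]
                assert g.case_delta.sum() == pytest.approx(
                    summary.loc[(pid, int(year))].caseload_change
                )
                assert g.n_sites.sum() == summary.loc[(pid, int(year))].n_corrected

    def test_completeness_sign_consistency(self, corrupted_sim, specs):
        """Completeness is below 100% exactly when corrections add cases."""
        _vdb, audit = validate_all(corrupted_sim.published_db, specs)
        for row in summarize(audit, specs).itertuples():
            pct = completeness_caseload(row.caseload_original, row.caseload_validated)
            if row.caseload_change > 0:
                assert pct <= 100.0
            elif row.caseload_change < 0:
                assert pct >= 100.0


class TestIICAggregation:
    def test_iic_total_with_site_level_compliance(self, specs):
        db = make_db(
            make_report("9", "00", 2019, mcr={"knee": 40},
                        ops=[("2300", "5-822.1", 40)], qi={"54020": 40}),
            make_report("9", "01", 2019, mcr={"knee": 45},
                        ops=[("2300", "5-822.1", 45)], qi={"54020": 45}),
        )
        _vdb, audit = validate_all(db, specs)
        iic = aggregate_to_iic(audit, specs).set_index(["iic", "year", "procedure_id"])
        row = iic.loc[("9", 2019, "knee")]
        assert row.total_caseload == 85.0
        assert row.n_sites_compliant == 0  # compliance stays site-level

    def test_single_site_association_total_equals_site_value(self, specs):
        db = make_db(make_report("9", "00", 2019, mcr={"oesophagus": 12},
                                 ops=[(DEPT_SURGERY, "5-423", 12)]))
        _vdb, audit = validate_all(db, specs)
        iic = aggregate_to_iic(audit, specs).set_index(["iic", "year", "procedure_id"])
        assert iic.loc[("9", 2019, "oesophagus")].total_caseload == 12.0


class TestExternalComparison:
    def test_identical_tables_have_zero_discrepancy(self, specs):
        db = make_db(make_report("9", "00", 2019, mcr={"oesophagus": 12},
                                 ops=[(DEPT_SURGERY, "5-423", 12)]))
        _vdb, audit = validate_all(db, specs)
        iic = aggregate_to_iic(audit, specs)
        report = compare_external(iic, iic, specs)
        assert (report.rel_discrepancy_pct == 0).all()

    def test_coverage_mismatch_is_fatal(self, specs):
        db = make_db(make_report("9", "00", 2019, mcr={"oesophagus": 12},
                                 ops=[(DEPT_SURGERY, "5-423", 12)]))
        _vdb, audit = validate_all(db, specs)
        iic = aggregate_to_iic(audit, specs)
        truncated = iic[iic.procedure_id != "oesophagus"]
        with pytest.raises(ValueError, match="different keys"):
            compare_external(iic, truncated, specs)

    def test_oracle_split_by_iic_level_compliance(self, corrupted_sim, specs):
        _vdb, audit = validate_all(corrupted_sim.published_db, specs)
        report = compare_external(
            aggregate_to_iic(audit, specs), corrupted_sim.truth.iic_totals(), specs
        )
        assert (
            report.oracle_compliant_cases + report.oracle_noncompliant_cases
        ).equals(report.oracle_total)
        assert (
            report.validated_compliant_cases + report.validated_noncompliant_cases
        ).equals(report.validated_total)
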