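"""Correction criteria, branch combination and whole-database validation."""

from __future__ import annotations

import pytest

from mcrval import (
    CriterionContext,
    Tolerance,
    apply_rejection_criteria,
    correct_availability_ii,
    correct_consistency_4,
    validate_all,
)
from mcrval.detection import consistency_level, deviation
from mcrval.model import extract_key_variables
from mcrval.simulate import SimulationConfig, simulate

from conftest import (
    DEPT_HAEMATOLOGY,
    DEPT_ORTHO,
    DEPT_OTHER,
    DEPT_SURGERY,
    SPEC,
    make_db,
    make_report,
)

OESO = SPEC["oesophagus"]
KNEE = SPEC["knee"]
STEM = SPEC["stem_cells"]


def ctx_from(db, key, spec=OESO) -> CriterionContext:
    kv = extract_key_variables(db, key, spec, db_specs())
    return CriterionContext(kv=kv, spec=spec, tol=Tolerance())


def db_specs():
    return tuple(SPEC.values())


class TestAvailabilityII:
    def test_practicability_adopts_competent_ops_frequency(self):
        db = make_db(make_report("9", "00", 2019, ops=[(DEPT_SURGERY, "5-423", 7)]))
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019)))
        assert (res.validated, res.provenance) == (7.0, "ref1")
        assert res.fired_criteria == {"P1"} and res.changed

    def test_practicability_needs_a_competent_department(self):
        # frequency sits only in an incompetent department, no other years
        db = make_db(
            make_report("9", "00", 2019, ops=[(DEPT_OTHER, "5-423", 7)])
        )
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 0.0 and not res.changed

    def test_probability_supports_lone_statement(self):
        db = make_db(
            make_report("9", "00", 2018, mcr={"oesophagus": 5}),
            make_report("9", "00", 2019, mcr={"oesophagus": 4}),
        )
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 4.0 and not res.changed
        assert res.fired_criteria == {"P2"}

    def test_unsupported_lone_statement_without_competence_is_zeroed(self):
        db = make_db(
            make_report("9", "00", 2018, depts=[DEPT_OTHER]),
            make_report("9", "00", 2019, mcr={"oesophagus": 4}, depts=[DEPT_OTHER]),
        )
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 0.0 and res.changed
        assert res.fired_criteria == {"R1"} and res.provenance == "zeroed"

    def test_lone_statement_with_competence_is_accepted(self):
        db = make_db(make_report("9", "00", 2019, mcr={"oesophagus": 4},
                                 depts=[DEPT_SURGERY]))
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 4.0 and res.fired_criteria == set()

    def test_knee_agreement_of_both_references(self):
        db = make_db(
            make_report("9", "00", 2019, ops=[(DEPT_ORTHO, "5-822.1", 52)],
                        qi={"54020": 50})
        )
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019), KNEE))
        assert res.validated == 52.0 and res.fired_criteria == {"K2"}
        assert res.provenance == "ref1"

    def test_lone_quality_indicator_is_flagged_guesswork(self):
        db = make_db(make_report("9", "00", 2019, qi={"54020": 30}))
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019), KNEE))
        assert res.validated == 30.0 and res.provenance == "ref2"
        assert res.note == "only_ref2_available"

    def test_pediatric_exempt_statement_is_rejected(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"stem_cells": 30}, pediatric=True,
                        depts=[DEPT_HAEMATOLOGY])
        )
        res = correct_availability_ii(ctx_from(db, ("9", "00", 2019), STEM))
        assert res.validated == 0.0 and res.fired_criteria == {"PED"}

    def test_rejects_availability_i_input(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 7},
                        ops=[(DEPT_SURGERY, "5-423", 7)])
        )
        with pytest.raises(ValueError):
            correct_availability_ii(ctx_from(db, ("9", "00", 2019)))


class TestRejectionCriteria:
    def test_digit_shift(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 300},
                        ops=[(DEPT_SURGERY, "5-423", 30)])
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R7_digit_shift" in fired

    def test_previous_year_duplicate(self):
        db = make_db(
            make_report("9", "00", 2018, mcr={"oesophagus": 30}),
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 7)]),
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R3" in fired

    def test_sibling_duplicate(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 7)]),
            make_report("9", "01", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 30)]),
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R4" in fired

    def test_association_level_entry(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 120},
                        ops=[(DEPT_SURGERY, "5-423", 40)]),
            make_report("9", "01", 2019, mcr={"oesophagus": 78},
                        ops=[(DEPT_SURGERY, "5-423", 78)]),
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R6" in fired

    def test_misaggregated_knee_quality_indicator(self):
        db = make_db(
            make_report(
                "9", "00", 2019, mcr={"knee": 10},
                ops=[(DEPT_ORTHO, "5-822.1", 52), (DEPT_ORTHO, "5-822.0", 30)],
                qi={"54020": 80},
            )
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019), KNEE))
        assert "R5" in fired

    def test_duplicate_across_competent_and_incompetent_departments(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 30), (DEPT_OTHER, "5-423", 30)])
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R2" in fired

    def test_wrong_field_matches_another_procedures_frequency(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 25},
                        ops=[(DEPT_SURGERY, "5-423", 7), (DEPT_SURGERY, "5-524", 25)])
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R7_wrong_field" in fired

    def test_grossly_implausible_value(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 900},
                        ops=[(DEPT_SURGERY, "5-423", 40)])
        )
        fired = apply_rejection_criteria(ctx_from(db, ("9", "00", 2019)))
        assert "R7_gross" in fired and "R7_digit_shift" not in fired


class TestConsistency4Resolution:
    def test_rejected_statement_is_replaced_by_reference(self):
        db = make_db(
            make_report("9", "00", 2018, mcr={"oesophagus": 30}),
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 7)]),
        )
        res = correct_consistency_4(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 7.0 and res.provenance == "ref1"
        assert "R3" in res.fired_criteria

    def test_rejected_reference_confirms_statement(self):
        # frequency only in an incompetent department: R1 rejects ref1
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 9},
                        ops=[(DEPT_OTHER, "5-423", 30)])
        )
        res = correct_consistency_4(ctx_from(db, ("9", "00", 2019)))
        assert res.fired_criteria == {"R1"}
        assert res.validated == 9.0 and not res.changed

    def test_duplicate_share_correction_uses_competent_only_sum(self):
        db = make_db(
            make_report("9", "00", 2018, mcr={"oesophagus": 30}),
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 9), (DEPT_OTHER, "5-423", 9)]),
        )
        res = correct_consistency_4(ctx_from(db, ("9", "00", 2019)))
        # R3 rejects the statement, R2 trims ref1 to the competent share
        assert {"R2", "R3"} <= res.fired_criteria
        assert res.validated == 9.0

    def test_no_criterion_keeps_original(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"oesophagus": 30},
                        ops=[(DEPT_SURGERY, "5-423", 7)])
        )
        res = correct_consistency_4(ctx_from(db, ("9", "00", 2019)))
        assert res.validated == 30.0 and res.fired_criteria == set()

    def test_pediatric_only_site_is_zeroed(self):
        db = make_db(
            make_report("9", "00", 2019, mcr={"stem_cells": 40}, pediatric=True,
                        ops=[(DEPT_HAEMATOLOGY, "8-805.3", 12)])
        )
        res = correct_consistency_4(ctx_from(db, ("9", "00", 2019), STEM))
        assert res.validated == 0.0 and res.fired_criteria == {"PED"}


class TestValidateAll:
    def test_clean_database_is_untouched(self, clean_sim, specs):
        _vdb, audit = validate_all(clean_sim.published_db, specs)
        assert not audit.changed.any()
        assert (audit.validated == audit.original).all()

    def test_no_record_is_deleted(self, corrupted_sim, specs):
        vdb, audit = validate_all(corrupted_sim.published_db, specs)
        assert len(vdb) == len(corrupted_sim.published_db)
        assert len(audit) == 4 * len(corrupted_sim.published_db)

    def test_validation_is_stable_on_its_own_output(self, corrupted_sim, specs):
        vdb, audit = validate_all(corrupted_sim.published_db, specs)
        assert audit.changed.any()
        _vdb2, audit2 = validate_all(vdb, specs)
        assert int(audit2.changed.sum()) == 0

    def test_audit_completeness(self, corrupted_sim, specs):
        _vdb, audit = validate_all(corrupted_sim.published_db, specs)
        changed = audit[audit.changed]
        assert (changed.fired_criteria != "").all()
        allowed = {
            "K2", "P1", "P2", "PED", "R1", "R2", "R3", "R4", "R5", "R6",
            "R7_digit_shift", "R7_gross", "R7_wrong_field",
        }
        for crits in audit.fired_criteria:
            assert set(filter(None, crits.split(";"))) <= allowed

    def test_masking_only_deviations_bounded_by_imputation(self, specs):
        """With masking as the only distortion, every validated value
        stays within 1.5 of truth per masked contributing cell."""
        res = simulate(SimulationConfig(seed=41, n_associations=80))
        assert not res.error_log
        _vdb, audit = validate_all(res.published_db, specs)
        for r in audit.itertuples():
            t = res.truth.get(r.iic, r.site_code, r.year, r.procedure_id)
            report = res.published_db.get(r.iic, r.site_code, r.year)
            n_masked = sum(
                1
                for d in report.departments
                for code in SPEC[r.procedure_id].mcr_ops_codes
                if d.ops_counts.get(code) is not None
                and not isinstance(d.ops_counts.get(code), int)
            )
            assert abs(r.validated - t) <= 1.5 * max(n_masked, 0) + 1e-9


def recovery_rate(error_rates: dict, seed: int, n_associations: int = 250,
                  exact: bool = True) -> tuple[float, int]:
    """Share of error-affected records whose validated value matches truth.

    ``exact=False`` counts agreement within the acceptable tolerance
    region (consistency level <= 3 between validated value and truth),
    the resolution limit of the validation method.
    """
    cfg = SimulationConfig(seed=seed, n_associations=n_associations,
                           masking_enabled=False, **error_rates)
    res = simulate(cfg)
    _vdb, audit = validate_all(res.published_db, tuple(SPEC.values()))
    validated = {
        (r.iic, r.site_code, r.year, r.procedure_id): r.validated
        for r in audit.itertuples()
    }
    tol = Tolerance()
    ok = total = 0
    for e in res.error_log:
        total += 1
        t = res.truth.get(e.iic, e.site_code, e.year, e.procedure_id)
        v = validated[(e.iic, e.site_code, e.year, e.procedure_id)]
        if v == t:
            ok += 1
        elif not exact and v > 0 and t > 0:
            ok += consistency_level(*deviation(v, t), tol) <= 3
    return ok / total, total


class TestParameterRecovery:
    """Single-error-class injections are corrected back to truth."""

    def test_nonreporting_recovers_exactly(self):
        rate, n = recovery_rate(
            dict(p_nonreport_small=0.4, p_nonreport_large=0.4), seed=51
        )
        assert n >= 500 and rate == 1.0

    def test_digit_shift_recovers_exactly(self):
        rate, n = recovery_rate(dict(p_digit_shift=0.4), seed=52)
        assert n >= 500 and rate == 1.0

    def test_previous_year_duplicates_recover(self):
        rate, n = recovery_rate(dict(p_dup_prev_year=0.4), seed=53, exact=False)
        assert n >= 500 and rate >= 0.95

    def test_sibling_duplicates_recover(self):
        rate, n = recovery_rate(
            dict(p_dup_sibling=0.6), seed=54, n_associations=1300, exact=False
        )
        assert n >= 500 and rate >= 0.95

    def test_association_level_entries_recover(self):
        rate, n = recovery_rate(
            dict(p_assoc_level_entry=0.9), seed=55, n_associations=1300, exact=False
        )
        assert n >= 500 and rate >= 0.95

    def test_knee_indicator_misaggregation_leaves_caseloads_at_truth(self):
        rate, n = recovery_rate(dict(p_qi_misaggregate=0.7), seed=56)
        assert n >= 500 and rate >= 0.95
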