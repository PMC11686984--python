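"""Parameter-recovery experiment for a single error class.

Injects only previous-year duplicate errors, validates, and measures
how many affected records return to the true caseload — exactly, or
within the tolerance region the method itself treats as acceptable.
"""

from mcrval import DEFAULT_PROCEDURES, Tolerance, validate_all
from mcrval.detection import consistency_level, deviation
from mcrval.simulate import SimulationConfig, simulate

config = SimulationConfig(seed=1, n_associations=250, masking_enabled=False,
                          p_dup_prev_year=0.4)
result = simulate(config)
_validated, audit = validate_all(result.published_db, DEFAULT_PROCEDURES)
validated = {(r.iic, r.site_code, r.year, r.procedure_id): r.validated
             for r in audit.itertuples()}

tol = Tolerance()
exact = within = total = 0
for e in result.error_log:
    total += 1
    truth = result.truth.get(e.iic, e.site_code, e.year, e.procedure_id)
    v = validated[(e.iic, e.site_code, e.year, e.procedure_id)]
    if v == truth:
        exact += 1
    elif v > 0 and truth > 0 and consistency_level(*deviation(v, truth), tol) <= 3:
        within += 1

print(f"{total} records corrupted with a previous-year duplicate")
print(f"recovered exactly:            {exact} ({100 * exact / total:.1f}%)")
print(f"recovered within tolerance:   {within} ({100 * within / total:.1f}%)")
print(f"not recovered:                {total - exact - within}")
print()
print("Duplicates that contradict the OPS frequency beyond the tolerance")
print("are rejected by criterion R3 and replaced exactly; duplicates that")
print("happen to fall within 5 cases or 20% of the frequency are, by the")
print("method's design, indistinguishable from counting noise and kept.")
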