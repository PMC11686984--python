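"""Shipped procedure configuration.

The four MCR procedures with constant thresholds since 2006: complex
oesophageal interventions (10 cases/year/site), complex pancreatic
interventions (10), allogeneic stem cell transplantation (25) and total
knee replacement (50).  Department codes follow the German department
key style ("Fachabteilungsschluessel"): 0100 internal medicine, 0500
haematology/oncology, 1500 general/visceral surgery, 2300 orthopaedics.
The OPS code sets are representative, not the full regulatory lists.
"""

from __future__ import annotations

from typing import Iterable

import yaml

from .model import ProcedureSpec

DEFAULT_PROCEDURES: tuple[ProcedureSpec, ...] = (
    ProcedureSpec(
        procedure_id="oesophagus",
        display_name="Complex oesophageal interventions",
        threshold=10,
        mcr_ops_codes=frozenset({"5-423", "5-424"}),
        competent_departments=frozenset({"1500"}),
        pediatric_exempt=True,
    ),
    ProcedureSpec(
        procedure_id="pancreas",
        display_name="Complex pancreatic interventions",
        threshold=10,
        mcr_ops_codes=frozenset({"5-524", "5-525"}),
        competent_departments=frozenset({"1500"}),
    ),
    ProcedureSpec(
        procedure_id="stem_cells",
        display_name="Allogeneic stem cell transplantation",
        threshold=25,
        mcr_ops_codes=frozenset({"8-805.3", "8-808"}),
        competent_departments=frozenset({"0500"}),
        pediatric_exempt=True,
    ),
    ProcedureSpec(
        procedure_id="knee",
        display_name="Total knee replacement",
        threshold=50,
        mcr_ops_codes=frozenset({"5-822.1"}),
        confounder_ops_codes=frozenset({"5-822.0", "5-823"}),
        competent_departments=frozenset({"2300"}),
        qi_id="54020",
    ),
)


def procedures_to_yaml(specs: Iterable[ProcedureSpec]) -> str:
    """Serialise procedure specs to a YAML document."""
    payload = [
        {
            "procedure_id": s.procedure_id,
            "display_name": s.display_name,
            "threshold": s.threshold,
            "mcr_ops_codes": sorted(s.mcr_ops_codes),
            "confounder_ops_codes": sorted(s.confounder_ops_codes),
            "competent_departments": sorted(s.competent_departments),
            "qi_id": s.qi_id,
            "pediatric_exempt": s.pediatric_exempt,
        }
        for s in specs
    ]
    return yaml.safe_dump(payload, sort_keys=False)


def load_procedures(path) -> tuple[ProcedureSpec, ...]:
    """Load procedure specs from a YAML file written by :func:`procedures_to_yaml`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, list) or not payload:
        raise ValueError(f"procedure config {path} must be a non-empty list")
    specs = []
    for entry in payload:
        specs.append(
            ProcedureSpec(
                procedure_id=entry["procedure_id"],
                display_name=entry.get("display_name", entry["procedure_id"]),
                threshold=int(entry["threshold"]),
                mcr_ops_codes=frozenset(entry["mcr_ops_codes"]),
                confounder_ops_codes=frozenset(entry.get("confounder_ops_codes") or ()),
                competent_departments=frozenset(entry.get("competent_departments") or ()),
                qi_id=entry.get("qi_id"),
                pediatric_exempt=bool(entry.get("pediatric_exempt", False)),
            )
        )
    return tuple(specs)
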