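"""End-to-end orchestration: simulate → detect → correct → assess → compare.

Every stage is a pure function of its inputs plus the master seed, so a
fixed configuration yields byte-identical artifacts.  The stage outputs
are plain CSV/JSONL files with headers, and a manifest records the
configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .assessment import (
    aggregate_to_iic,
    compare_external,
    contrast_table,
    summarize,
    summary_shares,
)
from .correction import validate_all
from .detection import Tolerance, detect_all
from .io import load_reports, write_reports
from .model import DEFAULT_IMPUTE, ProcedureSpec
from .procedures import DEFAULT_PROCEDURES, load_procedures
from .simulate import GroundTruth, SimulationConfig, simulate, write_error_log

logger = logging.getLogger("mcrval")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults encode the study constants: tolerance of 5 cases and 20%,
    masking imputation 1.5, and the four shipped procedures with
    thresholds 10/10/25/50.
    """

    out_dir: Union[str, Path] = "mcrval-run"
    input_dir: Optional[Union[str, Path]] = None
    procedures_path: Optional[Union[str, Path]] = None
    tolerance: Tolerance = field(default_factory=Tolerance)
    impute: float = DEFAULT_IMPUTE
    gross_factor: float = 10.0
    seed: int = 0
    simulation: Optional[SimulationConfig] = None

    def procedures(self) -> tuple[ProcedureSpec, ...]:
        if self.procedures_path is not None:
            return load_procedures(self.procedures_path)
        return DEFAULT_PROCEDURES


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))  # pragma: no cover

    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # the destination is not part of the experiment
    payload = json.dumps(fields, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and return the artifact paths.

    With a simulation configured, the generated (published) reports and
    the ground truth are written alongside the validation artifacts;
    otherwise the reports are loaded from ``input_dir`` and the external
    comparison is skipped unless a ``truth.csv`` is present there.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = config.procedures()
    artifacts: dict[str, Path] = {}

    truth: Optional[GroundTruth] = None
    if config.simulation is not None:
        sim_config = dataclasses.replace(config.simulation, seed=config.seed)
        result = simulate(sim_config)
        db = result.published_db
        truth = result.truth
        input_dir = out_dir / "input"
        write_reports(db, input_dir)
        truth.to_frame().to_csv(input_dir / "truth.csv", index=False)
        write_error_log(result.error_log, input_dir / "error_log.jsonl")
        artifacts["input"] = input_dir
        logger.info("simulated %d site reports, %d injected errors", len(db), len(result.error_log))
    else:
        if config.input_dir is None:
            raise ValueError("either input_dir or a simulation config is required")
        input_dir = Path(config.input_dir)
        db = load_reports(input_dir)
        truth_path = input_dir / "truth.csv"
        if truth_path.is_file():
            truth = GroundTruth.from_frame(pd.read_csv(truth_path, dtype={"iic": str, "site_code": str}))

    detections = detect_all(db, specs, config.tolerance, config.impute)
    detections.to_csv(out_dir / "detection.csv", index=False)
    artifacts["detection"] = out_dir / "detection.csv"

    validated_db, audit = validate_all(
        db, specs, config.tolerance, config.impute, config.gross_factor
    )
    audit[
        [
            "year",
            "iic",
            "site_code",
            "procedure_id",
            "original",
            "validated",
            "availability",
            "consistency",
            "fired_criteria",
            "provenance",
        ]
    ].to_csv(out_dir / "validated_mcr.csv", index=False)
    artifacts["validated_mcr"] = out_dir / "validated_mcr.csv"
    with open(out_dir / "audit.jsonl", "w", encoding="utf-8") as fh:
        for rec in audit.to_dict(orient="records"):
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
    artifacts["audit"] = out_dir / "audit.jsonl"
    write_reports(validated_db, out_dir / "validated")
    artifacts["validated_reports"] = out_dir / "validated"
    for rec in audit[audit["changed"]].itertuples(index=False):
        logger.info(
            "corrected %s %s/%s %s: %s -> %s [%s]",
            rec.year,
            rec.iic,
            rec.site_code,
            rec.procedure_id,
            rec.original,
            rec.validated,
            rec.fired_criteria,
        )

    summary = summarize(audit, specs)
    summary.to_csv(out_dir / "summary.csv", index=False)
    artifacts["summary"] = out_dir / "summary.csv"
    summary_shares(summary).to_csv(out_dir / "summary_shares.csv", index=False)
    artifacts["summary_shares"] = out_dir / "summary_shares.csv"
    contrast_table(audit, specs).to_csv(out_dir / "contrast.csv", index=False)
    artifacts["contrast"] = out_dir / "contrast.csv"

    validated_iic = aggregate_to_iic(audit, specs)
    validated_iic.to_csv(out_dir / "validated_iic.csv", index=False)
    artifacts["validated_iic"] = out_dir / "validated_iic.csv"
    if truth is not None:
        comparison = compare_external(validated_iic, truth.iic_totals(), specs)
        comparison.to_csv(out_dir / "external_comparison.csv", index=False)
        artifacts["external_comparison"] = out_dir / "external_comparison.csv"
    else:
        logger.info("no ground truth available; external comparison skipped")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "artifacts": {
            k: str(v.relative_to(out_dir)) if v.is_relative_to(out_dir) else str(v)
            for k, v in sorted(artifacts.items())
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
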