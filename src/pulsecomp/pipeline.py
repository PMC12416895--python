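"""Pipeline driver: simulate/read -> per-record analysis -> cohort report.

For every subject x condition the driver computes per-territory waveform
features, both compliance estimates and the lumped resistance, plus
whole-subject hemodynamics, assembles them into the long-format cohort
table, and runs the paired statistical battery. Records whose Windkessel
fit fails (e.g. a measured pulse pressure outside the model's attainable
range) are skipped with a logged reason, mirroring per-vessel exclusions in
real cohorts; every other metric of that record is kept.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .compliance import fit_cwk
from .errors import InvalidInputError, PulsecompError
from .hemodynamics import SubjectVisit, Territory, summarize_visit
from .stats import summarize, validate_cohort_table
from .waveform import extract_features

log = logging.getLogger("pulsecomp.pipeline")

RECORDS_FILE = "records.tsv"
SUMMARY_TSV = "summary.tsv"
SUMMARY_JSON = "summary.json"
METADATA_FILE = "run_metadata.json"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    input_dir: Path
    output_dir: Path
    #: per-territory multiplicative correction of the radial PP (e.g. a
    #: carotid-to-radial amplification factor); default 1.0 everywhere
    pp_correction: dict = field(default_factory=dict)
    icp: float = 10.0  # mmHg, cerebral reference pressure
    cvp: float = 10.0  # mmHg, systemic reference pressure
    windkessel_mode: str = "steady_state"
    n_grid: int = 256
    optimizer_tol: float = 1e-4
    ode_tol: float = 1e-6  # accepted periodicity residual of the cycle solution
    seed: int = 0

    def __post_init__(self):
        if self.optimizer_tol <= 0 or self.ode_tol <= 0:
            raise InvalidInputError("tolerances must be positive")
        if self.n_grid < 64:
            raise InvalidInputError("n_grid must be at least 64")
        if self.icp < 0 or self.cvp < 0:
            raise InvalidInputError("reference pressures must be >= 0")
        object.__setattr__(
            self,
            "pp_correction",
            {Territory(k): float(v) for k, v in dict(self.pp_correction).items()},
        )

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def digest(self) -> str:
        """Hash of the scientific configuration (paths excluded, so two runs
        of the same analysis in different locations share a digest)."""
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("input_dir", "output_dir", "pp_correction")
        }
        payload["pp_correction"] = {
            t.value: v for t, v in self.pp_correction.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def analyze_visits(
    visits: list[SubjectVisit], config: RunConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-record metrics for a cohort, in long format.

    Returns ``(table, failures)`` where failures lists skipped Windkessel
    fits with their reasons.
    """
    rows: list[dict] = []
    failures: list[dict] = []

    def add(visit: SubjectVisit, metric: str, value: float) -> None:
        rows.append(
            {
                "subject_id": visit.subject_id,
                "sex": visit.sex.value,
                "condition": visit.condition.value,
                "metric": metric,
                "value": float(value),
            }
        )

    for visit in visits:
        p = visit.pressure
        for name, value in (
            ("map", p.map),
            ("sap", p.sap),
            ("dap", p.dap),
            ("pp", p.pp),
            ("heart_rate", visit.heart_rate),
        ):
            add(visit, name, value)
        summary = summarize_visit(visit, icp=config.icp, cvp=config.cvp)
        for name, value in (
            ("cbf", summary.cbf),
            ("cardiac_output", summary.cardiac_output),
            ("stroke_volume", summary.stroke_volume),
            ("cvr", summary.cvr),
            ("svr", summary.svr),
        ):
            if value is not None:
                add(visit, name, value)
        for terr, sample in sorted(visit.vessels.items(), key=lambda kv: kv[0].value):
            feats = extract_features(sample.waveform, n_grid=config.n_grid)
            suffix = terr.value
            add(visit, f"q_mean_{suffix}", feats.q_mean)
            add(visit, f"flow_{suffix}_ml_min", feats.q_mean * 60.0)
            add(visit, f"delta_q_{suffix}", feats.delta_q)
            if feats.pulsatility_index is not None:
                add(visit, f"pi_{suffix}", feats.pulsatility_index)
            if terr in summary.area_mean:
                add(visit, f"area_mean_{suffix}", summary.area_mean[terr])
                add(visit, f"area_delta_{suffix}", summary.area_delta[terr])
            pv = config.icp if terr is Territory.CBF else config.cvp
            corr = config.pp_correction.get(terr, 1.0)
            pp_eff = p.pp * corr
            dap_eff = p.map - pp_eff / 3.0  # keep MAP, rescale the swing
            try:
                pressure_t = dataclasses.replace(
                    p, pv=pv, pp=pp_eff, dap=dap_eff, sap=dap_eff + pp_eff
                )
                result = fit_cwk(
                    sample.waveform,
                    pressure_t,
                    mode=config.windkessel_mode,
                    territory=terr,
                    n_grid=config.n_grid,
                    tol=config.optimizer_tol,
                )
            except PulsecompError as exc:
                failures.append(
                    {
                        "subject_id": visit.subject_id,
                        "condition": visit.condition.value,
                        "territory": terr.value,
                        "reason": str(exc),
                    }
                )
                log.warning(
                    "skipping Windkessel fit for %s/%s/%s: %s",
                    visit.subject_id,
                    visit.condition.value,
                    terr.value,
                    exc,
                )
                continue
            add(visit, f"resistance_{suffix}", result.resistance)
            add(visit, f"delta_v_{suffix}", result.delta_v)
            add(visit, f"c_vp_{suffix}", result.c_vp)
            add(visit, f"c_wk_{suffix}", result.c_wk)
    table = pd.DataFrame(rows)
    if len(table):
        validate_cohort_table(table)
    return table, failures


@dataclass(frozen=True)
class PipelineResult:
    records: pd.DataFrame
    summary: pd.DataFrame
    failures: list[dict]
    output_dir: Path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # repr-based float formatting: deterministic and round-trip exact
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read a subject directory, analyze every record, write the report.

    Outputs (all plain text, no timestamps, byte-identical across reruns
    with identical inputs and config): ``records.tsv`` (long per-record
    table), ``summary.tsv`` / ``summary.json`` (paired cohort statistics)
    and ``run_metadata.json`` (config, config hash, conventions).
    """
    visits = pio.read_subject_dir(config.input_dir)
    log.info("read %d visits from %s", len(visits), config.input_dir)
    records, failures = analyze_visits(visits, config)
    summary = summarize(records)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(records, out / RECORDS_FILE)
    _write_tsv(summary, out / SUMMARY_TSV)
    (out / SUMMARY_JSON).write_text(
        json.dumps(summary.to_dict(orient="records"), indent=1, sort_keys=True)
        + "\n"
    )
    meta = {
        # paths deliberately excluded: the report must not depend on where
        # the data happen to live
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("pp_correction", "input_dir", "output_dir")
        },
        "pp_correction": {t.value: v for t, v in config.pp_correction.items()},
        "config_hash": config.digest(),
        "n_visits": len(visits),
        "n_failed_fits": len(failures),
        "failures": failures,
        "conventions": {
            "quartiles": "linear interpolation",
            "relative_change": "per-subject (post-pre)/pre*100, median-summarized",
            "multiple_testing": "none (per-comparison alpha=0.05)",
            "q_dias": "global cycle minimum (no end-diastolic gating)",
            "cbf_area": "sum of the four cervical-vessel ROI areas",
        },
    }
    (out / METADATA_FILE).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return PipelineResult(
        records=records, summary=summary, failures=failures, output_dir=out
    )
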