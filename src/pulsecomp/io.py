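"""Plain-text file formats for cohorts: waveform CSVs and a subjects table.

Layout of a subject directory::

    subjects.tsv                      one row per subject x condition
    <subject>_<condition>_<terr>.csv  one cardiac cycle per file
    ground_truth.tsv                  (synthetic cohorts only; test-time aid)

Waveform CSV dialect: a first comment line ``# T=<seconds>`` carrying the
cycle duration, then a header ``time_s,flow_ml_per_s[,area_cm2]`` and one
row per cardiac phase. Floats are written with ``repr`` so a
read-write-read round trip is byte-identical.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .compliance import PressureSummary
from .errors import DataFormatError, InvalidInputError
from .hemodynamics import Condition, Sex, SubjectVisit
from .synthetic import SyntheticCohort
from .waveform import (
    FlowWaveform,
    NONNEGATIVE_TERRITORIES,
    Territory,
    VesselSample,
)

log = logging.getLogger("pulsecomp.io")

SUBJECTS_FILE = "subjects.tsv"
GROUND_TRUTH_FILE = "ground_truth.tsv"
SUBJECT_COLUMNS = (
    "subject_id",
    "sex",
    "condition",
    "map_mmhg",
    "sap_mmhg",
    "dap_mmhg",
    "pp_mmhg",
    "heart_rate_bpm",
)


def _fmt(x: float) -> str:
    return repr(float(x))


def waveform_filename(subject_id: str, condition: str, territory: Territory) -> str:
    return f"{subject_id}_{condition}_{Territory(territory).value}.csv"


def write_waveform_csv(path: Path, sample: VesselSample) -> None:
    w = sample.waveform
    cols = ["time_s", "flow_ml_per_s"]
    series = [w.times, w.flows]
    if sample.area_series is not None:
        cols.append("area_cm2")
        series.append(sample.area_series)
    if sample.velocity_series is not None:
        cols.append("velocity_cm_per_s")
        series.append(sample.velocity_series)
    lines = [f"# T={_fmt(w.cycle_duration)}", ",".join(cols)]
    for row in zip(*series):
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform_csv(path: Path, territory: Territory) -> VesselSample:
    path = Path(path)
    try:
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("# T="):
                raise DataFormatError(
                    f"{path.name}: first line must be '# T=<seconds>', got {first!r}"
                )
            try:
                T = float(first[4:])
            except ValueError as exc:
                raise DataFormatError(
                    f"{path.name}: cannot parse cycle duration from {first!r}"
                ) from exc
            df = pd.read_csv(fh, float_precision="round_trip")
    except OSError as exc:
        raise DataFormatError(f"cannot read {path}: {exc}") from exc
    for col in ("time_s", "flow_ml_per_s"):
        if col not in df.columns:
            raise DataFormatError(f"{path.name}: missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            raise DataFormatError(
                f"{path.name}: non-numeric value in column {col!r} "
                f"(data row {int(bad[0]) + 1 if len(bad) else '?'})"
            )
    try:
        waveform = FlowWaveform(
            times=df["time_s"].to_numpy(dtype=float),
            flows=df["flow_ml_per_s"].to_numpy(dtype=float),
            cycle_duration=T,
        )
        area = (
            df["area_cm2"].to_numpy(dtype=float) if "area_cm2" in df.columns else None
        )
        velocity = (
            df["velocity_cm_per_s"].to_numpy(dtype=float)
            if "velocity_cm_per_s" in df.columns
            else None
        )
        sample = VesselSample(
            territory=territory,
            waveform=waveform,
            area_series=area,
            velocity_series=velocity,
        )
    except InvalidInputError as exc:
        raise DataFormatError(f"{path.name}: {exc}") from exc
    if territory in NONNEGATIVE_TERRITORIES and np.any(waveform.flows < 0):
        log.warning(
            "%s: negative flow phase(s) in %s — physiologically suspect, kept",
            path.name,
            Territory(territory).value,
        )
    return sample


def write_subject_dir(visits: list[SubjectVisit], path: Path) -> Path:
    """Write a cohort as subjects.tsv plus one waveform CSV per record."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for visit in sorted(visits, key=lambda v: (v.subject_id, v.condition.value)):
        p = visit.pressure
        rows.append(
            "\t".join(
                [
                    visit.subject_id,
                    visit.sex.value,
                    visit.condition.value,
                    _fmt(p.map),
                    _fmt(p.sap),
                    _fmt(p.dap),
                    _fmt(p.pp),
                    _fmt(visit.heart_rate),
                ]
            )
        )
        for terr in sorted(visit.vessels, key=lambda t: t.value):
            write_waveform_csv(
                path / waveform_filename(visit.subject_id, visit.condition.value, terr),
                visit.vessels[terr],
            )
    header = "\t".join(SUBJECT_COLUMNS)
    (path / SUBJECTS_FILE).write_text("\n".join([header] + rows) + "\n")
    return path


def read_subject_dir(path: Path) -> list[SubjectVisit]:
    """Read a subject directory into validated SubjectVisit objects.

    Missing territory files are tolerated (logged) — real cohorts have
    unmeasurable vessels; malformed subjects.tsv rows or waveform files are
    hard errors with file/row context.
    """
    path = Path(path)
    subjects_path = path / SUBJECTS_FILE
    if not subjects_path.exists():
        raise DataFormatError(f"{subjects_path} not found")
    df = pd.read_csv(
        subjects_path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{SUBJECTS_FILE}: missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataFormatError(
            f"{SUBJECTS_FILE}: duplicate key "
            f"(subject_id={row['subject_id']!r}, condition={row['condition']!r})"
        )
    visits = []
    for idx, row in df.iterrows():
        try:
            pressure = PressureSummary(
                map=float(row["map_mmhg"]),
                sap=float(row["sap_mmhg"]),
                dap=float(row["dap_mmhg"]),
                pp=float(row["pp_mmhg"]),
            )
        except (InvalidInputError, ValueError) as exc:
            raise DataFormatError(
                f"{SUBJECTS_FILE} row {idx + 2} "
                f"(subject {row['subject_id']!r}): {exc}"
            ) from exc
        vessels = {}
        for terr in Territory:
            fname = waveform_filename(str(row["subject_id"]), str(row["condition"]), terr)
            fpath = path / fname
            if not fpath.exists():
                log.info(
                    "subject %s %s: territory %s not measured (no %s)",
                    row["subject_id"],
                    row["condition"],
                    terr.value,
                    fname,
                )
                continue
            vessels[terr] = read_waveform_csv(fpath, terr)
        try:
            visits.append(
                SubjectVisit(
                    subject_id=str(row["subject_id"]),
                    condition=Condition(str(row["condition"])),
                    sex=Sex(str(row["sex"])),
                    vessels=vessels,
                    pressure=pressure,
                    heart_rate=float(row["heart_rate_bpm"]),
                )
            )
        except (InvalidInputError, ValueError) as exc:
            raise DataFormatError(
                f"{SUBJECTS_FILE} row {idx + 2} "
                f"(subject {row['subject_id']!r}): {exc}"
            ) from exc
    return visits


def write_cohort(cohort: SyntheticCohort, path: Path) -> Path:
    """Write a synthetic cohort including its ground-truth table."""
    path = write_subject_dir(cohort.visits, path)
    gt = cohort.ground_truth.copy()
    lines = ["\t".join(gt.columns)]
    for _, row in gt.iterrows():
        lines.append(
            "\t".join(
                _fmt(v) if isinstance(v, float) else str(v) for v in row.to_list()
            )
        )
    (path / GROUND_TRUTH_FILE).write_text("\n".join(lines) + "\n")
    return path


def read_ground_truth(path: Path) -> pd.DataFrame:
    p = Path(path) / GROUND_TRUTH_FILE
    if not p.exists():
        raise DataFormatError(f"{p} not found (analysis does not require it)")
    return pd.read_csv(p, sep="\t", dtype={"subject_id": str}, float_precision="round_trip")
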