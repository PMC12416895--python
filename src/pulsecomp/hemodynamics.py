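"""Whole-subject hemodynamic summaries derived from the measured planes.

Total cerebral blood flow is the phase-wise sum of the four cervical
arteries (left/right internal carotid + vertebral); cardiac output is the
mean ascending-aorta flow; resistances follow the conventional pressure
gradient over flow forms, with intracranial and central venous pressure
assumed 10 mmHg unless configured otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .compliance import PressureSummary
from .errors import InvalidInputError
from .waveform import (
    CANONICAL_GRID_SIZE,
    FlowWaveform,
    Territory,
    VesselSample,
    cyclic_mean,
    extract_features,
)

#: conventional unit factor: (mmHg / (L/min)) * 80 = dyn*s*cm^-5
SVR_UNIT_FACTOR = 80.0


class Condition(str, Enum):
    BASELINE = "baseline"
    NOREPINEPHRINE = "norepinephrine"


class Sex(str, Enum):
    F = "F"
    M = "M"


@dataclass(eq=False)
class SubjectVisit:
    """All measured territories and pressures for one subject x condition."""

    subject_id: str
    condition: Condition
    sex: Sex
    vessels: dict[Territory, VesselSample]
    pressure: PressureSummary
    heart_rate: float  # beats/min

    def __post_init__(self):
        self.condition = Condition(self.condition)
        self.sex = Sex(self.sex)
        if self.heart_rate <= 0:
            raise InvalidInputError(f"heart_rate must be positive, got {self.heart_rate}")
        vessels = {}
        for terr, sample in self.vessels.items():
            terr = Territory(terr)
            if terr in vessels:
                raise InvalidInputError(f"duplicate territory {terr.value}")
            if Territory(sample.territory) != terr:
                raise InvalidInputError(
                    f"vessel keyed {terr.value} labelled {sample.territory}"
                )
            vessels[terr] = sample
        self.vessels = vessels


@dataclass(frozen=True)
class HemodynamicSummary:
    """Derived whole-subject quantities for one visit."""

    cbf: float | None  # ml/min
    cardiac_output: float | None  # ml/min
    stroke_volume: float | None  # ml
    cvr: float | None  # mmHg*min/ml
    svr: float | None  # dyn*s*cm^-5
    area_mean: dict[Territory, float] = field(default_factory=dict)  # cm^2
    area_delta: dict[Territory, float] = field(default_factory=dict)  # cm^2


def total_cbf(
    ica_l: FlowWaveform,
    ica_r: FlowWaveform,
    va_l: FlowWaveform,
    va_r: FlowWaveform,
    n_grid: int = CANONICAL_GRID_SIZE,
) -> FlowWaveform:
    """Sum the four cervical-artery waveforms into one cerebral inflow cycle.

    The four cycles must agree in duration to within 1% (they come from the
    same gated acquisition); each is resampled onto the canonical uniform
    grid before the phase-wise sum, so the mean of the sum equals the sum of
    the means.
    """
    waves = [ica_l, ica_r, va_l, va_r]
    durations = np.array([w.cycle_duration for w in waves])
    T = float(durations.mean())
    if np.any(np.abs(durations - T) > 0.01 * T):
        raise InvalidInputError(
            f"cycle durations differ by more than 1%: {durations.tolist()}"
        )
    n = max([n_grid] + [w.n_samples for w in waves])
    grid = np.arange(n) * (T / n)
    flows = sum(w(grid * (w.cycle_duration / T)) for w in waves)
    return FlowWaveform(times=grid, flows=flows, cycle_duration=T)


def cvr(map_mmhg: float, icp: float, cbf_ml_min: float) -> float:
    """Cerebrovascular resistance (MAP - ICP)/CBF in mmHg*min/ml."""
    if cbf_ml_min <= 0:
        raise InvalidInputError(f"CBF must be positive, got {cbf_ml_min}")
    if map_mmhg <= icp:
        raise InvalidInputError(f"MAP ({map_mmhg}) must exceed ICP ({icp})")
    return (map_mmhg - icp) / cbf_ml_min


def svr(map_mmhg: float, cvp: float, cardiac_output_l_min: float) -> float:
    """Systemic vascular resistance ((MAP - CVP)/CO[L/min]) * 80 in dyn*s*cm^-5."""
    if cardiac_output_l_min <= 0:
        raise InvalidInputError(
            f"cardiac output must be positive, got {cardiac_output_l_min}"
        )
    if map_mmhg <= cvp:
        raise InvalidInputError(f"MAP ({map_mmhg}) must exceed CVP ({cvp})")
    return (map_mmhg - cvp) / cardiac_output_l_min * SVR_UNIT_FACTOR


def area_metrics(
    area_series: np.ndarray,
    times: np.ndarray | None = None,
    cycle_duration: float | None = None,
) -> tuple[float, float]:
    """Time-weighted mean lumen area and systole-diastole range over a cycle.

    With no explicit ``times`` the phases are assumed uniform over the
    cycle (retrospective gating), making the cyclic mean the arithmetic
    mean of the samples. Returns ``(mean_cm2, delta_a_cm2)`` where
    ``delta_a = max - min``.
    """
    a = np.asarray(area_series, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("area_series must be a 1-D array of >= 2 phases")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise InvalidInputError("areas must be positive and finite")
    if times is None:
        mean = float(a.mean())
    else:
        if cycle_duration is None:
            raise InvalidInputError("cycle_duration required with explicit times")
        mean = cyclic_mean(a, np.asarray(times, dtype=float), cycle_duration)
    return mean, float(a.max() - a.min())


def summarize_visit(
    visit: SubjectVisit,
    icp: float = 10.0,
    cvp: float = 10.0,
) -> HemodynamicSummary:
    """Assemble the derived hemodynamic quantities for one visit.

    Missing territories yield ``None`` entries rather than failure,
    mirroring per-vessel exclusions in real cohorts.
    """
    cbf_ml_min = co_ml_min = sv = cvr_val = svr_val = None
    if Territory.CBF in visit.vessels:
        cbf_ml_min = extract_features(visit.vessels[Territory.CBF].waveform).q_mean * 60.0
        cvr_val = cvr(visit.pressure.map, icp, cbf_ml_min)
    if Territory.AOA in visit.vessels:
        co_ml_min = extract_features(visit.vessels[Territory.AOA].waveform).q_mean * 60.0
        sv = co_ml_min / visit.heart_rate
        svr_val = svr(visit.pressure.map, cvp, co_ml_min / 1000.0)
    area_mean: dict[Territory, float] = {}
    area_delta: dict[Territory, float] = {}
    for terr, sample in visit.vessels.items():
        if sample.area_series is not None:
            m, d = area_metrics(sample.area_series)
            area_mean[terr] = m
            area_delta[terr] = d
    return HemodynamicSummary(
        cbf=cbf_ml_min,
        cardiac_output=co_ml_min,
        stroke_volume=sv,
        cvr=cvr_val,
        svr=svr_val,
        area_mean=area_mean,
        area_delta=area_delta,
    )
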