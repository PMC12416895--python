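"""Synthetic paired-condition cohorts with known Windkessel ground truth.

The generator emulates the structure of a norepinephrine induced-hypertension
study in healthy adults: per subject, a baseline visit and a visit at
pharmacologically raised pressure, each with 32-phase periodic flow
waveforms for four territories (cerebral inflow CBF, external carotid ECA,
ascending and descending aorta), lumen-area traces, and a blood-pressure
summary.

Waveform shape is a smooth periodic pulse: a von Mises systolic bump plus a
smaller dicrotic bump, and (aorta only) a brief early-diastolic reversal
dip. The shape is affinely scaled so the cycle's mean flow and peak-to-peak
amplitude hit per-subject targets drawn log-normally around cohort medians;
log-normal dispersion is moment-matched to median/IQR summaries
(sigma = ln(q3/q1)/1.349), which respects positivity and right skew.

The condition effect is multiplicative per metric (e.g. MAP x1.23, cerebral
flow x0.86, heart rate x0.80, cerebral Windkessel compliance x2.10), with
its own per-subject log-normal dispersion, plus a per-visit repeatability
factor so paired differences are non-degenerate even under a null effect.

Pulse pressure is *not* drawn: each territory's PP is produced by running
the two-element Windkessel model forward in periodic steady state with the
record's true (R, C), and the subject's measured PP is the cerebral
territory's forward PP plus measurement noise. Every record's generating
parameters are kept in a ground-truth table so estimator recovery can be
checked exactly. C_VP has no imposed ground truth: the two compliance
models embody incompatible capillary-pulsatility assumptions, so C_VP is an
emergent property of the generated waveform and pressure.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compliance import PressureSummary, windkessel_pressure
from .errors import InvalidInputError
from .hemodynamics import Condition, Sex, SubjectVisit
from .waveform import (
    FlowWaveform,
    NONNEGATIVE_TERRITORIES,
    Territory,
    VesselSample,
    extract_features,
)

#: moment-matching constant: IQR of a standard normal
_IQR_NORMAL = 1.3489795003921634


def lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-scale SD of a log-normal matched to quartiles (q1, q3)."""
    if not (0 < q1 < q3):
        raise InvalidInputError("quartiles must satisfy 0 < q1 < q3")
    return math.log(q3 / q1) / _IQR_NORMAL


@dataclass(frozen=True)
class ShapeParams:
    """Dimensionless periodic pulse shape; times are in fractions of a cycle."""

    peak_time: float
    peak_kappa: float
    dicrotic_amp: float
    dicrotic_time: float
    dicrotic_kappa: float
    reversal_amp: float = 0.0
    reversal_time: float = 0.35
    reversal_kappa: float = 25.0

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the unit pulse at cycle fractions u (any real values)."""
        u = np.asarray(u, dtype=float)

        def bump(center: float, kappa: float) -> np.ndarray:
            return np.exp(kappa * (np.cos(2 * np.pi * (u - center)) - 1.0))

        p = bump(self.peak_time, self.peak_kappa)
        p = p + self.dicrotic_amp * bump(self.dicrotic_time, self.dicrotic_kappa)
        if self.reversal_amp:
            p = p - self.reversal_amp * bump(self.reversal_time, self.reversal_kappa)
        return p


@dataclass(frozen=True)
class TerritoryLevels:
    """Baseline cohort medians and log-normal dispersions for one territory."""

    q_mean: float  # ml/s
    q_mean_sigma: float
    pi: float  # Gosling index, dimensionless
    pi_sigma: float
    c_wk: float  # ml/mmHg
    c_wk_sigma: float
    area_mean: float  # cm^2
    area_mean_sigma: float
    area_delta: float  # cm^2
    area_delta_sigma: float


@dataclass(frozen=True)
class TerritoryEffects:
    """Median condition multipliers (hypertension / baseline) and their spread."""

    q_mean: float
    q_mean_sigma: float
    pi: float
    pi_sigma: float
    c_wk: float
    c_wk_sigma: float
    area_mean: float
    area_mean_sigma: float
    area_delta: float
    area_delta_sigma: float


def default_shapes() -> dict[Territory, ShapeParams]:
    return {
        Territory.CBF: ShapeParams(0.18, 6.0, 0.22, 0.45, 18.0),
        Territory.ECA: ShapeParams(0.17, 9.0, 0.15, 0.42, 20.0),
        Territory.AOA: ShapeParams(0.16, 12.0, 0.08, 0.42, 25.0, 0.06, 0.34, 25.0),
        Territory.AOD: ShapeParams(0.18, 12.0, 0.10, 0.45, 25.0, 0.06, 0.36, 25.0),
    }


def default_levels() -> dict[Territory, TerritoryLevels]:
    # medians from a healthy adult cohort; dispersions moment-matched to the
    # published median (IQR) summaries on the log scale
    s = lognormal_sigma_from_iqr
    return {
        Territory.CBF: TerritoryLevels(
            q_mean=12.90, q_mean_sigma=s(11.22, 14.37),
            pi=0.95, pi_sigma=s(0.88, 1.09),
            c_wk=0.008, c_wk_sigma=s(0.007, 0.013),
            area_mean=0.914, area_mean_sigma=s(0.800, 1.002),
            area_delta=0.08, area_delta_sigma=0.30,
        ),
        Territory.ECA: TerritoryLevels(
            q_mean=182.0 / 60.0, q_mean_sigma=s(140.0, 273.0),
            pi=2.30, pi_sigma=s(1.93, 2.58),
            c_wk=0.008, c_wk_sigma=s(0.006, 0.014),
            area_mean=0.316, area_mean_sigma=s(0.259, 0.457),
            area_delta=0.03, area_delta_sigma=0.30,
        ),
        Territory.AOA: TerritoryLevels(
            q_mean=5874.0 / 60.0, q_mean_sigma=s(5199.0, 6355.0),
            pi=3.98, pi_sigma=s(3.69, 4.54),
            c_wk=0.87, c_wk_sigma=s(0.70, 1.00),
            area_mean=7.002, area_mean_sigma=s(5.692, 8.711),
            area_delta=1.147, area_delta_sigma=s(1.009, 1.469),
        ),
        # descending-aorta mean flow is not tabulated in the reference cohort;
        # ~70% of cardiac output passes the diaphragm-level plane
        Territory.AOD: TerritoryLevels(
            q_mean=0.70 * 5874.0 / 60.0, q_mean_sigma=0.15,
            pi=4.38, pi_sigma=s(4.00, 4.81),
            c_wk=0.57, c_wk_sigma=s(0.50, 0.69),
            area_mean=4.284, area_mean_sigma=s(3.559, 4.762),
            area_delta=0.714, area_delta_sigma=s(0.587, 0.886),
        ),
    }


def default_effects() -> dict[Territory, TerritoryEffects]:
    s = lognormal_sigma_from_iqr
    return {
        Territory.CBF: TerritoryEffects(
            q_mean=0.86, q_mean_sigma=s(0.82, 0.90),
            pi=1.06, pi_sigma=0.15,
            c_wk=2.10, c_wk_sigma=s(1.56, 2.63),
            area_mean=0.95, area_mean_sigma=s(0.83, 0.97),
            area_delta=1.00, area_delta_sigma=0.20,
        ),
        Territory.ECA: TerritoryEffects(
            q_mean=0.91, q_mean_sigma=0.12,
            pi=0.95, pi_sigma=0.20,
            c_wk=1.12, c_wk_sigma=s(1.01, 1.32),
            area_mean=1.00, area_mean_sigma=0.15,
            area_delta=1.00, area_delta_sigma=0.20,
        ),
        Territory.AOA: TerritoryEffects(
            q_mean=0.84, q_mean_sigma=s(0.77, 0.85),
            pi=1.18, pi_sigma=s(1.07, 1.32),
            c_wk=1.00, c_wk_sigma=0.15,
            area_mean=1.07, area_mean_sigma=s(1.04, 1.11),
            area_delta=1.22, area_delta_sigma=s(1.10, 1.47),
        ),
        Territory.AOD: TerritoryEffects(
            q_mean=0.84, q_mean_sigma=s(0.77, 0.85),
            pi=1.23, pi_sigma=s(1.11, 1.52),
            c_wk=1.00, c_wk_sigma=0.15,
            area_mean=1.08, area_mean_sigma=s(1.06, 1.11),
            area_delta=1.06, area_delta_sigma=s(0.95, 1.36),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a paired synthetic cohort."""

    n_subjects: int = 18
    territories: tuple[Territory, ...] = (
        Territory.CBF,
        Territory.ECA,
        Territory.AOA,
        Territory.AOD,
    )
    n_phases: int = 32
    icp: float = 10.0  # mmHg, cerebral reference pressure
    cvp: float = 10.0  # mmHg, systemic reference pressure
    map_median: float = 87.0
    map_sigma: float = lognormal_sigma_from_iqr(80.0, 92.0)
    hr_median: float = 66.0  # beats/min
    hr_sigma: float = lognormal_sigma_from_iqr(56.0, 74.0)
    map_effect: float = 1.23
    map_effect_sigma: float = lognormal_sigma_from_iqr(1.19, 1.29)
    hr_effect: float = 0.80
    hr_effect_sigma: float = 0.08
    shapes: dict[Territory, ShapeParams] = field(default_factory=default_shapes)
    levels: dict[Territory, TerritoryLevels] = field(default_factory=default_levels)
    effects: dict[Territory, TerritoryEffects] = field(default_factory=default_effects)
    #: per-phase additive flow noise SD, as a fraction of the territory median flow
    flow_noise_frac: float = 0.03
    #: multiplicative (log-scale) measurement noise on measured PP and MAP
    pp_noise_sigma: float = 0.02
    map_noise_sigma: float = 0.01
    #: per-visit repeatability (log-scale) on all latent levels; this is what
    #: keeps paired differences non-degenerate under a null condition effect
    repeat_sigma: float = 0.04

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidInputError("n_subjects must be at least 2")
        for terr in self.territories:
            if terr not in self.levels or terr not in self.shapes or terr not in self.effects:
                raise InvalidInputError(f"missing parameters for territory {terr}")
        for dc in (
            [self]
            + list(self.levels.values())
            + list(self.effects.values())
        ):
            for f in dataclasses.fields(dc):
                if not isinstance(getattr(dc, f.name), (int, float)):
                    continue
                v = float(getattr(dc, f.name))
                if f.name.endswith("_sigma") or "noise" in f.name:
                    if v < 0:
                        raise InvalidInputError(f"{f.name} must be >= 0, got {v}")
                elif f.name in ("map_effect", "hr_effect") and v <= 0:
                    raise InvalidInputError(f"{f.name} must be > 0, got {v}")
        for eff in self.effects.values():
            for f in dataclasses.fields(eff):
                if not f.name.endswith("_sigma") and getattr(eff, f.name) <= 0:
                    raise InvalidInputError(
                        f"effect multiplier {f.name} must be > 0"
                    )


def _zero_sigmas(dc):
    updates = {
        f.name: 0.0
        for f in dataclasses.fields(dc)
        if f.name.endswith("_sigma")
    }
    return replace(dc, **updates)


def zero_dispersion(spec: CohortSpec) -> CohortSpec:
    """Copy of the spec with all dispersions and noise set to zero.

    Every subject then receives identical, noise-free data: useful for
    ground-truth closure tests.
    """
    spec = _zero_sigmas(spec)
    return replace(
        spec,
        levels={t: _zero_sigmas(v) for t, v in spec.levels.items()},
        effects={t: _zero_sigmas(v) for t, v in spec.effects.items()},
        flow_noise_frac=0.0,
    )


def null_effects(spec: CohortSpec) -> CohortSpec:
    """Copy of the spec with all condition multipliers set to exactly 1.

    Level dispersion, repeatability and measurement noise are retained, so
    paired differences are pure within-subject noise — the null hypothesis
    of the paired tests.
    """
    eff = {
        t: TerritoryEffects(
            q_mean=1.0, q_mean_sigma=0.0,
            pi=1.0, pi_sigma=0.0,
            c_wk=1.0, c_wk_sigma=0.0,
            area_mean=1.0, area_mean_sigma=0.0,
            area_delta=1.0, area_delta_sigma=0.0,
        )
        for t in spec.effects
    }
    return replace(
        spec, effects=eff, map_effect=1.0, map_effect_sigma=0.0,
        hr_effect=1.0, hr_effect_sigma=0.0,
    )


def make_waveform(
    shape: ShapeParams,
    q_mean_target: float,
    delta_q_target: float,
    T: float,
    n_phases: int = 32,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    nonnegative: bool = False,
) -> FlowWaveform:
    """One-cycle flow waveform with prescribed mean and peak-to-peak amplitude.

    The dimensionless shape is scaled affinely, ``Q = c0 + c1 * p(t/T)``, so
    that the dense-grid mean equals ``q_mean_target`` and the dense-grid
    range equals ``delta_q_target``; the cycle is then sampled at
    ``n_phases`` uniform phases (pre-noise features round-trip to within 1%
    for the default shapes). Additive Gaussian per-phase noise of SD
    ``noise_sd`` emulates measurement noise.
    """
    if q_mean_target <= 0:
        raise InvalidInputError(f"q_mean_target must be > 0, got {q_mean_target}")
    if delta_q_target < 0:
        raise InvalidInputError(f"delta_q_target must be >= 0, got {delta_q_target}")
    if n_phases < 8:
        raise InvalidInputError("n_phases must be at least 8")
    u_dense = np.arange(4096) / 4096.0
    p = shape.evaluate(u_dense)
    p_max, p_min, p_mean = p.max(), p.min(), p.mean()
    if delta_q_target == 0:
        c0, c1 = q_mean_target, 0.0
    else:
        c1 = delta_q_target / (p_max - p_min)
        c0 = q_mean_target - c1 * p_mean
    q_dias = c0 + c1 * p_min
    if nonnegative and q_dias < 0:
        raise InvalidInputError(
            f"infeasible targets: q_mean={q_mean_target:.4g}, "
            f"delta_q={delta_q_target:.4g} give diastolic flow {q_dias:.4g} < 0 "
            "for a non-negative-flow territory"
        )
    u = np.arange(n_phases) / n_phases
    flows = c0 + c1 * shape.evaluate(u)
    if noise_sd > 0:
        if rng is None:
            raise InvalidInputError("rng is required when noise_sd > 0")
        flows = flows + rng.normal(0.0, noise_sd, n_phases)
    return FlowWaveform(times=u * T, flows=flows, cycle_duration=T)


@dataclass(eq=False)
class SyntheticCohort:
    """Generated visits plus the per-record generating parameters."""

    visits: list[SubjectVisit]
    ground_truth: pd.DataFrame
    spec: CohortSpec


def _draw(rng: np.random.Generator, sigma: float) -> float:
    """A unit-median log-normal factor; 1.0 exactly when sigma == 0."""
    if sigma == 0:
        return 1.0
    return float(np.exp(sigma * rng.standard_normal()))


def _max_feasible_pi(shape: ShapeParams) -> float:
    u = np.arange(4096) / 4096.0
    p = shape.evaluate(u)
    return (p.max() - p.min()) / (p.mean() - p.min())


def forward_windkessel_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = 0
) -> SyntheticCohort:
    """Generate a paired cohort by running the Windkessel model forward.

    Fully deterministic for a given (spec, seed). Sexes alternate so an
    even-sized cohort is balanced. For each subject x condition x territory,
    the record's true resistance comes from the drawn MAP and the realized
    mean flow, the true compliance from the territory's drawn level, and the
    territory PP from the periodic steady-state Windkessel solution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    visits: list[SubjectVisit] = []
    gt_rows: list[dict] = []
    pi_caps = {t: 0.98 * _max_feasible_pi(spec.shapes[t]) for t in spec.territories}

    for i in range(spec.n_subjects):
        sid = f"S{i + 1:03d}"
        sex = Sex.F if i % 2 == 0 else Sex.M
        map_base = spec.map_median * _draw(rng, spec.map_sigma)
        hr_base = spec.hr_median * _draw(rng, spec.hr_sigma)
        latent = {
            t: {
                "q_mean": spec.levels[t].q_mean * _draw(rng, spec.levels[t].q_mean_sigma),
                "pi": spec.levels[t].pi * _draw(rng, spec.levels[t].pi_sigma),
                "c_wk": spec.levels[t].c_wk * _draw(rng, spec.levels[t].c_wk_sigma),
                "area_mean": spec.levels[t].area_mean
                * _draw(rng, spec.levels[t].area_mean_sigma),
                "area_delta": spec.levels[t].area_delta
                * _draw(rng, spec.levels[t].area_delta_sigma),
            }
            for t in spec.territories
        }
        eff = {
            t: {
                "q_mean": spec.effects[t].q_mean * _draw(rng, spec.effects[t].q_mean_sigma),
                "pi": spec.effects[t].pi * _draw(rng, spec.effects[t].pi_sigma),
                "c_wk": spec.effects[t].c_wk * _draw(rng, spec.effects[t].c_wk_sigma),
                "area_mean": spec.effects[t].area_mean
                * _draw(rng, spec.effects[t].area_mean_sigma),
                "area_delta": spec.effects[t].area_delta
                * _draw(rng, spec.effects[t].area_delta_sigma),
            }
            for t in spec.territories
        }
        map_eff = spec.map_effect * _draw(rng, spec.map_effect_sigma)
        hr_eff = spec.hr_effect * _draw(rng, spec.hr_effect_sigma)

        for condition in (Condition.BASELINE, Condition.NOREPINEPHRINE):
            post = condition is Condition.NOREPINEPHRINE
            map_c = map_base * (map_eff if post else 1.0) * _draw(rng, spec.repeat_sigma)
            hr_c = hr_base * (hr_eff if post else 1.0) * _draw(rng, spec.repeat_sigma)
            T = 60.0 / hr_c
            vessels: dict[Territory, VesselSample] = {}
            pp_reference = None
            for terr in spec.territories:
                lv, ef = latent[terr], eff[terr]
                q_mean_t = lv["q_mean"] * (ef["q_mean"] if post else 1.0) * _draw(
                    rng, spec.repeat_sigma
                )
                pi_t = lv["pi"] * (ef["pi"] if post else 1.0) * _draw(rng, spec.repeat_sigma)
                pi_t = min(pi_t, pi_caps[terr])
                c_true = lv["c_wk"] * (ef["c_wk"] if post else 1.0) * _draw(
                    rng, spec.repeat_sigma
                )
                clean = make_waveform(
                    spec.shapes[terr],
                    q_mean_t,
                    pi_t * q_mean_t,
                    T,
                    n_phases=spec.n_phases,
                    nonnegative=terr in NONNEGATIVE_TERRITORIES,
                )
                feats = extract_features(clean)
                pv = spec.icp if terr is Territory.CBF else spec.cvp
                r_true = (map_c - pv) / feats.q_mean
                pp_true = windkessel_pressure(
                    clean, r_true, c_true, mode="steady_state"
                ).modeled_pp
                if pp_reference is None:
                    pp_reference = pp_true

                noise_sd = spec.flow_noise_frac * spec.levels[terr].q_mean
                flows = clean.flows
                if noise_sd > 0:
                    flows = flows + rng.normal(0.0, noise_sd, spec.n_phases)
                waveform = FlowWaveform(clean.times.copy(), flows, T)

                a_mean = lv["area_mean"] * (ef["area_mean"] if post else 1.0) * _draw(
                    rng, spec.repeat_sigma
                )
                a_delta = lv["area_delta"] * (ef["area_delta"] if post else 1.0) * _draw(
                    rng, spec.repeat_sigma
                )
                u = np.arange(spec.n_phases) / spec.n_phases
                p_area = spec.shapes[terr].evaluate(u - 0.05)  # area lags flow slightly
                p_rng = p_area.max() - p_area.min()
                areas = a_mean + a_delta * (p_area - p_area.mean()) / p_rng

                vessels[terr] = VesselSample(
                    territory=terr, waveform=waveform, area_series=areas
                )
                gt_rows.append(
                    {
                        "subject_id": sid,
                        "condition": condition.value,
                        "territory": terr.value,
                        "cycle_duration_s": T,
                        "q_mean_target": q_mean_t,
                        "delta_q_target": pi_t * q_mean_t,
                        "r_true": r_true,
                        "c_true": c_true,
                        "pp_true": pp_true,
                        "map_true": map_c,
                        "pv": pv,
                    }
                )

            pp_meas = pp_reference * _draw(rng, spec.pp_noise_sigma)
            map_meas = map_c * _draw(rng, spec.map_noise_sigma)
            dap = map_meas - pp_meas / 3.0
            pressure = PressureSummary(
                map=map_meas, sap=dap + pp_meas, dap=dap, pp=pp_meas, pv=spec.icp
            )
            visits.append(
                SubjectVisit(
                    subject_id=sid,
                    condition=condition,
                    sex=sex,
                    vessels=vessels,
                    pressure=pressure,
                    heart_rate=hr_c,
                )
            )
    return SyntheticCohort(
        visits=visits, ground_truth=pd.DataFrame(gt_rows), spec=spec
    )
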