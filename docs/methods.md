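# Methods

## The problem

Induced hypertension (norepinephrine titrated to raise mean arterial
pressure, MAP, by roughly 20%) is used clinically to boost cerebral blood
flow (CBF). Raising MAP also raises pulsatile load, so the question is
whether the compliant cerebral arteries adapt — storing more volume per
mmHg of pulse pressure — and thereby keep shielding the microcirculation.
`pulsecomp` implements the analysis that answers this from phase-contrast
MRI flow waveforms and a radial-artery blood-pressure summary, measured per
subject at baseline and during induced hypertension.

## Compliance models

Both models describe everything distal to a flow-measurement plane, and
they bracket the physiology: the truth lies between full damping and full
transmission of pressure pulsatility at the capillaries.

**Pulsatile-volume compliance (C_VP).** If pulsatility is fully damped
before the capillaries, every ml of pulsatile inflow expands the arterial
walls. The stored volume over one cycle of duration T is

    V(t) = ∫₀ᵗ (Q(τ) − Q_mean) dτ,     ΔV = max V − min V,

and C_VP = ΔV / PP, with PP the measured pulse pressure. Because the
integrand has zero cycle mean, V closes to 0 at t = T; `pulsecomp`
integrates by the trapezoidal rule with periodic closure, which is exact
for piecewise-linear flow.

**Two-element Windkessel compliance (C_WK).** If pulsatility is fully
transmitted, the bed is a resistor R = (MAP − P_v)/Q_mean in parallel with
a capacitor C, driven by the pulsatile inflow Q_in = Q − Q_mean (P_v is
the downstream reference: intracranial pressure for the cerebral bed,
central venous pressure otherwise, both taken as 10 mmHg by default).
Pressure obeys

    C dP/dt = Q_in(t) − P(t)/R,

and C_WK is the C whose periodic solution reproduces the measured PP as
max P − min P. Since part of the pulsatile inflow exits through the
resistor (capillary) branch, C_WK ≤ C_VP to first order (see
*Known properties and limitations*).

Derived quantities: Gosling's pulsatility index PI = ΔQ/Q_mean with
ΔQ = Q_syst − Q_dias; cerebrovascular resistance CVR = (MAP − ICP)/CBF;
systemic vascular resistance SVR = 80·(MAP − CVP)/CO with CO in L/min;
stroke volume SV = CO/HR; the Doppler-style velocity index
(PSV + 2·EDV)/3; lumen-area mean and systole–diastole range.

## Numerical design

* **Waveforms** are one retrospectively gated cycle (typically 32 phases)
  on [0, T). All interpolation uses a *periodic* cubic spline (value and
  slope continuous across the wrap) — the signal is one period of a
  periodic process, so natural boundary conditions would be wrong. The
  internal canonical grid is 256 uniform points per cycle; features move
  by <0.1% of the pulse amplitude between 256 and 1024 points.
* **Q_syst / Q_dias** are the global cycle maximum/minimum; no
  systole/diastole gating is attempted, and Q_dias is *not* forced to the
  end-diastolic sample. Means are time-weighted (trapezoid with periodic
  closure), which on a uniform periodic grid reduces to the arithmetic
  mean but stays correct for non-uniform sampling.
* **ODE solution.** The Windkessel equation is linear, so each canonical
  grid step is integrated *exactly* with an exponential integrator
  (exact decay term, piecewise-linear forcing). This is unconditionally
  stable — explicit schemes would go unstable for small RC — and leaves
  only the forcing-interpolation error (~1e−4 relative at 256 points).
  The recurrence is evaluated as an IIR filter for speed.
* **Periodic steady state.** One cycle maps pressure affinely,
  P(T) = A·P(0) + b with A = exp(−T/RC), so the periodic solution is the
  fixed point P* = b/(1 − A), computed in closed form from a single cycle
  integration rather than by transient cycling (which for RC ≫ T would
  need hundreds of cycles to settle). `mode="single_cycle"` instead integrates a
  single cycle from P(0) = 0, reproducing a convention in which the
  start-up transient contributes to the reported PP.
* **PP fit.** The modeled PP is continuous and strictly decreasing in C
  (asserted numerically over the physiological grid), with supremum
  R·ΔQ at C → 0⁺. The fit starts from C_VP (a natural initial guess,
  since the models agree at first order for cerebral operating points)
  and runs a scalar Nelder–Mead simplex with tolerances 1e−4; if the
  residual exceeds 1e−3 mmHg a bracketed Brent root-find, guaranteed by
  monotonicity, polishes it. A measured PP at or above R·ΔQ has no
  positive-compliance solution and raises a diagnostic error; the
  pipeline records such fits as exclusions rather than silently clamping.
* **Degenerate inputs.** Constant flow gives ΔV = 0, PI = 0 and a
  Windkessel pressure that is pure RC decay of the initial condition.
  A non-positive mean flow makes PI and R undefined; both are signalled
  explicitly, never returned as NaN.

### Single-cycle transient vs periodic steady state

How many cycles the original optimization integrated is not documented,
so `pulsecomp` quantifies the difference instead of guessing:
`mode_sensitivity_survey` tabulates PP for both conventions over a (R, C)
grid. The discrepancy vanishes for RC ≪ T (the transient dies within the
cycle) *and* for RC ≫ T (the start-up term becomes a near-constant offset
that cancels in max − min), peaking at ~15–18% when RC ≈ 0.5–1·T. At the
cerebral operating point (RC/T ≈ 0.05) the conventions differ by ~0.3%,
so the choice is immaterial exactly where the study's headline result
lives; the steady-state convention is the default because it is the
well-posed one.

## Synthetic cohort generator

No subject-level data are published, so the generator reproduces the
*study conditions* — cohort medians and dispersions of a healthy-adult
induced-hypertension experiment — with full per-record ground truth.

* **Pulse shape**: a von Mises systolic bump plus a smaller dicrotic
  bump; ascending/descending aorta additionally get a brief
  early-diastolic reversal dip (negative phases are permitted only
  there; cerebral and external-carotid waveforms are constrained
  non-negative). The shape is scaled affinely to hit per-record targets
  for Q_mean and ΔQ; at 32 phases the extracted features round-trip to
  within 1% before noise.
* **Levels**: per-territory medians for flow, PI, C_WK, lumen areas, and
  global MAP and heart-rate medians are set to the published cohort
  medians (e.g. cerebral Q_mean 12.9 ml/s, PI 0.95, C_WK 0.008 ml/mmHg,
  MAP 87 mmHg, HR 66 bpm). The descending-aorta mean flow is not
  tabulated; it defaults to 70% of cardiac output, the approximate
  fraction passing the diaphragm level. Subject dispersion is log-normal
  with σ = ln(q3/q1)/1.349 moment-matched to the published IQRs —
  log-normality respects positivity and the right skew of the summaries.
* **Condition effects** are per-metric multiplicative medians with their
  own log-normal per-subject spread (MAP ×1.23, heart rate ×0.80,
  cerebral flow ×0.86, cerebral C_WK ×2.10, aortic areas ×1.07–1.08, …),
  again matched to the published relative-change summaries. A per-visit
  repeatability factor (σ = 0.04) keeps paired differences
  non-degenerate under a null effect, and per-phase Gaussian flow noise
  (SD 3% of the territory median flow) plus multiplicative measurement
  noise on PP (2%) and MAP (1%) emulate measurement error.
* **Pressure is emergent, not drawn.** Each record's PP comes from the
  forward Windkessel model at the record's true (R, C); the subject's
  "radial" PP is the cerebral territory's forward PP plus measurement
  noise. C_VP has no imposed ground truth either: the two models embody
  incompatible capillary assumptions and cannot both be exact on the
  same record, so C_VP is whatever the generated waveform and pressure
  imply.

**What the generator does not emulate**: beat-to-beat variability,
baroreflex dynamics, norepinephrine pharmacokinetics, realistic MRI noise
spectra, or carotid-to-radial PP amplification. Two further limitations
matter for interpretation. First, the emergent radial PP is ~45–60 mmHg
at baseline (close to the published 58) but its condition change is
−5 to 0%, not the observed +14%: the published parameter changes are not
exactly self-consistent under a two-element model with this harmonic
content, and the generator resolves the conflict in favour of the
imposed compliance/flow/pressure levels. Second, passing tests on this
cohort demonstrates correctness of the estimators and statistics under
the model's own assumptions, not fidelity of the two-element Windkessel
to real cerebrovascular beds.

## Statistics

Small paired cohort, nonparametric throughout: Wilcoxon signed-rank
across conditions (exact null for n ≤ 25 without ties, normal
approximation with tie correction otherwise; zero differences dropped),
Mann–Whitney U between sexes on relative changes, Spearman correlations
with tie-corrected ranks. Summaries are median (IQR) with
linear-interpolation quartiles. The within-subject change is computed per
subject as (post − pre)/pre × 100 and then median-summarized — this is
*not* the ratio of condition medians, and the two can differ substantially
(a cohort whose C_WK medians move 0.008 → 0.018 can have a median
per-subject change of +110%, not +125%). No multiple-testing correction
is applied (per-comparison two-sided α = 0.05), and the report metadata
says so.

Operating characteristics are verified by simulation: under a null
condition effect the paired test's rejection rate sits inside the 95%
binomial band around 0.05 (500 replicate cohorts of n = 18), and under
the calibrated effects the cerebral C_WK increase is detected with power
≈ 1 at n = 18.

## Known properties and limitations

* **Ordering of the two models.** C_WK ≤ C_VP is exact per Fourier
  harmonic (each pressure mode is attenuated relative to the volume
  integral by |iωRC/(1 + iωRC)| < 1). For multi-harmonic waveforms it is
  not a strict theorem: when ωRC ≫ 1 the two estimators coincide to
  first order and the RC filter's phase shifts can realign harmonics so
  that C_WK exceeds C_VP by <1%. Over large replicate samples of the
  synthetic family this happens in ~0.3% of cerebral/external-carotid
  records — always records whose applied PP is far below their
  attainable R·ΔQ, driving the fit into the saturated integrator
  regime. On a study-scale default cohort the ordering holds on every
  record.
* The same radial PP is applied to all territories (with an optional
  per-territory correction factor, default 1.0), as in the underlying
  measurement protocol; central PP is lower than radial, so aortic
  compliances inherit that bias.
* ICP and CVP are assumed constants (10 mmHg, configurable), not
  measured.
* Problem sizes used by the verification suite — 200 records for
  parameter recovery, 500 replicates for the type-I rate, 200 for power,
  n = 18 paired subjects per cohort — were chosen to give Monte-Carlo
  error comfortably below the asserted tolerances.
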