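"""Pulsatile-volume compliance, Windkessel solver and the PP-matching fit."""
import numpy as np
import pytest

from pulsecomp import (
    FlowWaveform,
    InvalidInputError,
    PressureSummary,
    Territory,
    UnreachablePulsePressureError,
    c_vp,
    fit_cwk,
    lumped_resistance,
    mode_discrepancy,
    pulsatile_volume,
    windkessel_pressure,
)
from pulsecomp.synthetic import default_shapes

from conftest import make_sine


def square_wave(q0: float = 4.0, T: float = 1.0, n_half: int = 8) -> FlowWaveform:
    """+-q0 square wave with near-instantaneous transitions.

    The jumps are represented by sample pairs a distance eps apart, so the
    trapezoidal integral differs from the ideal square's by O(q0*eps).
    """
    eps = 1e-9
    up = np.linspace(0.0, T / 2 - eps, n_half)
    down = np.linspace(T / 2, T - eps, n_half)
    times = np.concatenate([up, down])
    flows = np.concatenate([np.full(n_half, q0), np.full(n_half, -q0)])
    return FlowWaveform(times, flows, T)


class TestPulsatileVolume:
    def test_constant_flow_stores_nothing(self):
        w = FlowWaveform(np.arange(8) / 8, np.full(8, 10.0), 1.0)
        _, v, dv = pulsatile_volume(w)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)
        assert dv == 0.0

    def test_sinusoid_closed_form(self):
        # dV = q0*T/pi for Q = qm + q0*sin(2*pi*t/T)
        w = make_sine(q0=6.0, q_mean=12.0, n=512)
        _, _, dv = pulsatile_volume(w)
        assert dv == pytest.approx(6.0 / np.pi, rel=1e-4)

    def test_square_wave_trapezoid_exact(self):
        _, _, dv = pulsatile_volume(square_wave(q0=4.0, T=1.0))
        assert dv == pytest.approx(2.0, abs=1e-6)

    def test_volume_closes_at_cycle_end(self):
        w = make_sine(q0=5.0, q_mean=9.0, n=128)
        _, v, dv = pulsatile_volume(w)
        assert abs(v[-1]) <= 1e-6 * dv


class TestCvp:
    @pytest.mark.parametrize(
        "dv, pp, expected",
        [(1.9099, 60.0, 0.031832), (0.0, 50.0, 0.0), (1.5, 58.0, 0.025862)],
    )
    def test_ratio(self, dv, pp, expected):
        assert c_vp(dv, pp) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_pp_rejected(self):
        with pytest.raises(InvalidInputError):
            c_vp(1.0, 0.0)


class TestLumpedResistance:
    @pytest.mark.parametrize(
        "map_, pv, qm, expected",
        [(87.0, 10.0, 12.9, 5.9690), (11.0, 10.0, 1.0, 1.0), (107.0, 10.0, 11.75, 8.2553)],
    )
    def test_values(self, map_, pv, qm, expected):
        assert lumped_resistance(map_, pv, qm) == pytest.approx(expected, rel=1e-4)

    def test_preconditions(self):
        with pytest.raises(InvalidInputError):
            lumped_resistance(87.0, 10.0, 0.0)
        with pytest.raises(InvalidInputError):
            lumped_resistance(9.0, 10.0, 5.0)


class TestWindkesselSolver:
    def test_rc_decay_with_zero_inflow(self):
        w = FlowWaveform(np.arange(64) / 64, np.full(64, 10.0), 1.0)  # Qin == 0
        R, C, p0 = 1.0, 0.1, 5.0
        sol = windkessel_pressure(w, R, C, mode="single_cycle", p0=p0)
        exact = p0 * np.exp(-sol.times / (R * C))
        assert np.max(np.abs(sol.pressure - exact)) <= 1e-6 * p0

    @pytest.mark.parametrize("R, C", [(5.969, 0.0193), (0.5, 0.05), (2.0, 0.9)])
    def test_sinusoid_transfer_function(self, R, C):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        sol = windkessel_pressure(w, R, C, mode="steady_state")
        expected = 2 * 6.0 * R / np.sqrt(1 + (2 * np.pi * R * C) ** 2)
        assert sol.modeled_pp == pytest.approx(expected, rel=1e-3)

    def test_huge_compliance_flattens_pressure(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        sol = windkessel_pressure(w, R=5.0, C=1000.0)
        assert sol.modeled_pp < 0.01

    def test_steady_state_is_periodic(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        sol = windkessel_pressure(w, R=8.0, C=0.9)  # slow transient: RC = 7.2 s
        assert sol.periodicity_residual < 1e-5

    def test_flow_balance_at_grid_points(self):
        # Qin = P/R + C dP/dt, with dP/dt from central differences
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        R, C = 3.0, 0.05
        sol = windkessel_pressure(w, R, C, n_grid=1024)
        p = sol.pressure[:-1]
        h = sol.times[1] - sol.times[0]
        dpdt = (np.roll(p, -1) - np.roll(p, 1)) / (2 * h)
        qin = 6.0 * np.sin(2 * np.pi * sol.times[:-1])
        residual = np.abs(qin - p / R - C * dpdt)
        assert np.max(residual) < 0.01 * 6.0  # discretization-limited

    def test_pp_strictly_decreasing_in_compliance(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        pps = [
            windkessel_pressure(w, 5.0, C).modeled_pp
            for C in np.geomspace(1e-3, 2.0, 30)
        ]
        assert np.all(np.diff(pps) < 0)

    def test_invalid_parameters(self):
        w = make_sine()
        with pytest.raises(InvalidInputError):
            windkessel_pressure(w, R=-1.0, C=0.1)
        with pytest.raises(InvalidInputError):
            windkessel_pressure(w, R=1.0, C=0.1, mode="bogus")


def pressure_for(R: float, q_mean: float, pp: float, pv: float = 10.0) -> PressureSummary:
    """PressureSummary whose MAP reproduces a prescribed R for a given Qmean."""
    map_ = pv + R * q_mean
    dap = map_ - pp / 3
    return PressureSummary(map=map_, sap=dap + pp, dap=dap, pp=pp, pv=pv)


class TestFitCwk:
    def test_sinusoid_closed_form_inversion(self):
        # C = sqrt((2*q0*R/PP)^2 - 1) / (omega*R)
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        R, pp = 5.969, 58.0
        res = fit_cwk(w, pressure_for(R, 12.0, pp))
        expected = np.sqrt((2 * 6.0 * R / pp) ** 2 - 1) / (2 * np.pi * R)
        assert res.c_wk == pytest.approx(expected, rel=2e-3)
        assert res.c_wk == pytest.approx(0.0193, rel=5e-3)
        assert res.diagnostics.residual_mmhg <= 1e-3

    def test_forward_simulation_recovery(self):
        shape = default_shapes()[Territory.CBF]
        u = np.arange(32) / 32
        w = FlowWaveform(u * 0.9, 10.5 + 12.6 * shape.evaluate(u), 0.9)
        R, C_true = 6.0, 0.011
        pp = windkessel_pressure(w, R, C_true).modeled_pp
        from pulsecomp import extract_features

        qm = extract_features(w).q_mean
        res = fit_cwk(w, pressure_for(R, qm, pp))
        assert res.c_wk == pytest.approx(C_true, rel=5e-3)
        assert res.c_wk <= res.c_vp

    def test_near_zero_compliance_boundary(self):
        # measured PP just below the zero-compliance supremum R*dQ
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        R = 5.969
        from pulsecomp.compliance import _WindkesselGrid

        grid = _WindkesselGrid(w)
        pp = 0.999 * R * (grid.q_syst - grid.q_dias)
        res = fit_cwk(w, pressure_for(R, 12.0, pp))
        expected = np.sqrt((2 * 6.0 * R / pp) ** 2 - 1) / (2 * np.pi * R)
        assert res.c_wk == pytest.approx(expected, rel=0.05)
        assert res.c_wk < 0.002  # approaching the pure-resistor limit

    def test_unreachable_pp_raises(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        R = 5.969
        with pytest.raises(UnreachablePulsePressureError):
            fit_cwk(w, pressure_for(R, 12.0, 1.05 * R * 12.0))

    def test_joint_flow_pressure_scaling_leaves_compliances_unchanged(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        res1 = fit_cwk(w, pressure_for(5.0, 12.0, 40.0))
        k = 2.0
        w2 = FlowWaveform(w.times, k * w.flows, w.cycle_duration)
        # MAP gradient and PP scale with flow, so R is unchanged
        res2 = fit_cwk(w2, pressure_for(5.0, k * 12.0, k * 40.0))
        assert res2.c_vp == pytest.approx(res1.c_vp, rel=1e-9)
        assert res2.c_wk == pytest.approx(res1.c_wk, rel=1e-6)
        assert res2.resistance == pytest.approx(res1.resistance, rel=1e-9)


class TestModeDiscrepancy:
    def test_transient_matters_for_slow_rc(self):
        w = make_sine(q0=6.0, q_mean=12.0, n=64)
        fast = mode_discrepancy(w, R=1.0, C=0.01)  # RC = 0.01 s << T
        slow = mode_discrepancy(w, R=5.0, C=1.0)  # RC = 5 s >> T
        assert abs(fast["rel_discrepancy_pct"]) < 0.5
        assert abs(slow["rel_discrepancy_pct"]) > 2.0


class TestPressureSummary:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            PressureSummary(map=80, sap=70, dap=60, pp=10)  # MAP above SAP
        with pytest.raises(InvalidInputError):
            PressureSummary(map=80, sap=120, dap=60, pp=50)  # PP != SAP-DAP
        with pytest.raises(InvalidInputError):
            PressureSummary(map=80, sap=120, dap=60, pp=60, pv=90)  # Pv >= MAP
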