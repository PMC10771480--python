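"""Space-clamped membrane patch: currents, electroporation law, dynamics."""

import math

import numpy as np
import pytest

from excitep.gating import GatingModel, LuoRudyGating
from excitep.membrane import (
    ChannelParams,
    EPParams,
    MembraneState,
    PulseProtocol,
    SimulationBlowUp,
    gating_derivatives,
    gep_dynamics,
    ionic_currents,
    resting_state,
    simulate_patch,
)


class _StubGating(GatingModel):
    """Constant-parameter gating for closed-form checks."""

    def __init__(self, y_inf=1.0, tau=1e-3, n=0.5):
        self._y, self._tau, self._n = y_inf, tau, n

    def y_inf(self, name, Um):
        return self._y

    def tau_y(self, name, Um):
        return self._tau

    def n_inf(self, Um):
        return self._n


class TestIonicCurrents:
    def test_sodium_zero_at_reversal(self, channels, gating):
        st = MembraneState(Um=channels.E_Na, m=0.7, h=0.5, j=0.5)
        j_na, _, _ = ionic_currents(st, channels, gating)
        assert j_na == pytest.approx(0.0)

    def test_closed_gate_blocks_sodium(self, channels, gating):
        st = MembraneState(Um=0.0, m=0.0, h=1.0, j=1.0)
        j_na, _, _ = ionic_currents(st, channels, gating)
        assert j_na == 0.0

    def test_leak_arithmetic(self, gating):
        p = ChannelParams(g_L=0.05)
        st = MembraneState(Um=p.E_L + 0.1, m=0.0, h=1.0, j=1.0)
        _, _, j_l = ionic_currents(st, p, gating)
        assert j_l == pytest.approx(0.005)

    def test_rejects_nonfinite_voltage(self):
        with pytest.raises(ValueError):
            MembraneState(Um=float("nan"), m=0.5, h=0.5, j=0.5)


class TestGatingDerivatives:
    def test_fixed_point(self, gating):
        um = -0.06
        st = MembraneState(
            Um=um,
            m=float(gating.y_inf("m", um)),
            h=float(gating.y_inf("h", um)),
            j=float(gating.y_inf("j", um)),
        )
        for d in gating_derivatives(st, gating):
            assert d == pytest.approx(0.0, abs=1e-9)

    def test_unit_rate(self):
        st = MembraneState(Um=0.0, m=0.0, h=0.0, j=0.0)
        dm, dh, dj = gating_derivatives(st, _StubGating(y_inf=1.0, tau=1e-3))
        assert dm == pytest.approx(1000.0)
        assert dh == pytest.approx(1000.0)


class TestGepDynamics:
    PROTO = PulseProtocol(amplitude=1.0, t_start=0.0, t_pulse=1e-4)

    def test_zero_voltage_gives_zero(self):
        ep = EPParams(alpha=1e-6, beta=40.0)
        assert gep_dynamics(0.0, 5e-5, ep, self.PROTO) == 0.0

    def test_direct_evaluation(self):
        ep = EPParams(alpha=1e-6, beta=40.0)
        expected = 1e-6 * (math.exp(40.0 * 0.3) - 1.0)
        assert gep_dynamics(0.3, 5e-5, ep, self.PROTO) == pytest.approx(expected)
        assert gep_dynamics(-0.3, 5e-5, ep, self.PROTO) == pytest.approx(expected)

    def test_resealing_one_time_constant(self):
        ep = EPParams(alpha=1e-6, beta=40.0, tau_r=2.0, recover=True)
        g_end = 0.4
        g = gep_dynamics(0.0, self.PROTO.t_end + 2.0, ep, self.PROTO, g_end=g_end)
        assert g == pytest.approx(g_end / math.e)

    def test_persistent_without_recovery(self):
        ep = EPParams(recover=False)
        g = gep_dynamics(0.0, 1.5, ep, self.PROTO, g_end=0.2)
        assert g == 0.2

    def test_monotone_in_voltage_during_pulse(self):
        ep = EPParams(alpha=1e-6, beta=40.0)
        u = np.linspace(0.0, 0.5, 50)
        g = ep.g_pulse(u)
        assert np.all(np.diff(g) > 0)
        assert np.all(g >= 0)


class TestSimulatePatch:
    def test_resting_state_is_stationary(self, channels, gating, rest):
        sol = simulate_patch(channels, gating, duration=3.0, dt=0.01)
        assert np.max(np.abs(sol.Um - rest.Um)) < 1e-4  # 0.1 mV over 3 s

    def test_single_ap_shape(self, channels, gating, rest):
        drv = lambda t: 0.15 if 0.05 <= t <= 0.052 else 0.0
        sol = simulate_patch(
            channels, gating, drive=drv, duration=2.5, dt=0.002,
            drive_breaks=(0.05, 0.052),
        )
        assert sol.Um.max() > 0.0  # overshoot above 0 V
        assert abs(sol.Um[-1] - rest.Um) < 5e-3  # back within 5 mV of rest
        # exactly one crossing of 0 V from below
        above = sol.Um > 0.0
        assert (np.diff(above.astype(int)) == 1).sum() == 1

    def test_all_or_none(self, channels, gating, rest):
        def peak(amplitude):
            drv = lambda t: amplitude if 0.05 <= t <= 0.052 else 0.0
            sol = simulate_patch(
                channels, gating, drive=drv, duration=1.0, dt=0.002,
                drive_breaks=(0.05, 0.052),
            )
            return sol.Um.max()

        assert peak(0.05) < rest.Um + 0.020  # subthreshold: < 20 mV depol
        assert peak(0.15) > 0.0  # suprathreshold: overshoot

    def test_matches_independent_fixed_step_integration(self, channels, gating):
        """LSODA solution agrees with a naive RK4 oracle at fine steps."""
        drv = lambda t: 0.15 if 0.01 <= t <= 0.012 else 0.0
        duration, dt_out = 0.12, 0.002
        sol = simulate_patch(
            channels, gating, drive=drv, duration=duration, dt=dt_out,
            drive_breaks=(0.01, 0.012),
        )

        p = channels
        def rhs(t, y):
            u, m, h, j = y
            j_ion = (
                p.g_Na * m**3 * h * j * (u - p.E_Na)
                + p.g_K * float(gating.n_inf(u)) * (u - p.E_K)
                + p.g_L * (u - p.E_L)
            )
            mi, tm, hi, th, ji, tj = gating.rates_mhj(u)
            return np.array([
                (-j_ion + drv(t)) / p.C_m,
                (mi - m) / tm, (hi - h) / th, (ji - j) / tj,
            ])

        r = resting_state(p, gating)
        y = np.array([r.Um, r.m, r.h, r.j])
        h_step = 2e-6
        out = {0.0: y[0]}
        t = 0.0
        n = int(round(duration / h_step))
        for i in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + h_step / 2, y + h_step / 2 * k1)
            k3 = rhs(t + h_step / 2, y + h_step / 2 * k2)
            k4 = rhs(t + h_step, y + h_step * k3)
            y = y + h_step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = (i + 1) * h_step
            out[round(t, 9)] = y[0]
        ref = np.array([out[round(tt, 9)] for tt in sol.t])
        assert np.max(np.abs(ref - sol.Um)) < 1e-4  # 0.1 mV

    def test_refining_output_grid_is_consistent(self, channels, gating):
        drv = lambda t: 0.15 if 0.05 <= t <= 0.052 else 0.0
        kw = dict(drive=drv, duration=1.0, drive_breaks=(0.05, 0.052))
        coarse = simulate_patch(channels, gating, dt=0.004, **kw)
        fine = simulate_patch(channels, gating, dt=0.002, **kw)
        common = np.intersect1d(np.round(coarse.t, 9), np.round(fine.t, 9))
        uc = coarse.Um[np.isin(np.round(coarse.t, 9), common)]
        uf = fine.Um[np.isin(np.round(fine.t, 9), common)]
        assert np.max(np.abs(uc - uf)) < 1e-4

    def test_blowup_detection(self, channels, gating):
        drv = lambda t: 1e4  # absurd sustained current
        with pytest.raises(SimulationBlowUp):
            simulate_patch(channels, gating, drive=drv, duration=0.5, dt=0.01)

    def test_trace_frame_columns(self, channels, gating):
        sol = simulate_patch(channels, gating, duration=0.05, dt=0.01)
        df = sol.to_frame()
        assert list(df.columns) == ["time_s", "Um_V", "m", "h", "j", "gep_S_per_m2"]


def test_default_leak_reversal_puts_rest_at_minus70(channels, gating):
    r = resting_state(channels, gating)
    assert r.Um == pytest.approx(-0.070, abs=1e-4)
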