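"""Space-clamped membrane patch of an excitable engineered HEK cell.

Current balance over one membrane patch (densities, A/m^2)::

    C_m dUm/dt = -J_Na - J_K - J_L - g_ep*Um + J_drive

with NaV1.5, Kir2.1 and leak currents

    J_Na = g_Na m^3 h j (Um - E_Na)
    J_K  = g_K n_inf(Um) (Um - E_K)
    J_L  = g_L (Um - E_L)

and a dynamic electroporation conductance ``g_ep``: during the pulse an
instantaneous empirical function of the transmembrane voltage,
``alpha*(exp(beta*|Um|) - 1)``; after the pulse either frozen at its
end-of-pulse value or resealing exponentially with time constant ``tau_r``
(clock started at the pulse end so that g_ep is continuous there).

The electroporation shunt is nonselective, so its reversal potential is 0 V.
Units are SI throughout (V, s, S/m^2, F/m^2, A/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from excitep.gating import GATE_NAMES, GatingModel, LuoRudyGating

__all__ = [
    "ChannelParams",
    "EPParams",
    "PulseProtocol",
    "MembraneState",
    "PatchSolution",
    "SimulationBlowUp",
    "ionic_currents",
    "gating_derivatives",
    "gep_dynamics",
    "resting_state",
    "default_channel_params",
    "simulate_patch",
]


class SimulationBlowUp(RuntimeError):
    """Raised when the integrated voltage leaves the physically plausible range."""


@dataclass(frozen=True)
class ChannelParams:
    """Maximal conductances (S/m^2), reversal potentials (V) and C_m (F/m^2)."""

    g_Na: float = 27.5
    g_K: float = 0.5
    g_L: float = 0.05
    E_Na: float = 0.065
    E_K: float = -0.075
    E_L: float = -0.0466
    C_m: float = 0.01

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be non-negative")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")


@dataclass(frozen=True)
class EPParams:
    """Empirical electroporation-conductance law.

    alpha (S/m^2) scales the pore conductance, beta (1/V) its voltage
    sensitivity; tau_r (s) is the resealing time constant used when
    ``recover`` is set.  ``g_max`` caps g_ep (numerical safeguard for the
    exponential at extreme voltages).
    """

    alpha: float = 5e-6
    beta: float = 40.0
    tau_r: float = 2.0
    recover: bool = False
    g_max: float = 1e4

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.beta <= 0 or self.tau_r <= 0:
            raise ValueError("beta and tau_r must be positive")

    def g_pulse(self, Um):
        """Instantaneous g_ep during the pulse as a function of Um."""
        x = np.minimum(self.beta * np.abs(Um), 50.0)
        return np.minimum(self.alpha * np.expm1(x), self.g_max)


@dataclass(frozen=True)
class PulseProtocol:
    """A single rectangular pulse with optionally smoothed edges.

    ``amplitude`` is the applied voltage (V) or field (V/m), interpreted by
    the simulator using the protocol.  ``smoothing`` is the logistic edge
    width (s); 0 gives hard edges.
    """

    amplitude: float
    t_pulse: float = 1e-4
    t_start: float = 0.0
    smoothing: float = 1e-6

    def __post_init__(self) -> None:
        if self.t_pulse <= 0:
            raise ValueError("t_pulse must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    @property
    def t_end(self) -> float:
        return self.t_start + self.t_pulse

    def window(self, t):
        """Smoothed rectangular window in [0, 1]."""
        t = np.asarray(t, dtype=float)
        if self.smoothing <= 0:
            return ((t >= self.t_start) & (t <= self.t_end)).astype(float)
        a = np.clip((t - self.t_start) / self.smoothing, -50, 50)
        b = np.clip((self.t_end - t) / self.smoothing, -50, 50)
        return 1.0 / (1.0 + np.exp(-a)) / (1.0 + np.exp(-b))

    def window_deriv(self, t):
        """d/dt of :meth:`window` (delta-like spikes at the edges)."""
        t = np.asarray(t, dtype=float)
        if self.smoothing <= 0:
            return np.zeros_like(t)
        a = np.clip((t - self.t_start) / self.smoothing, -50, 50)
        b = np.clip((self.t_end - t) / self.smoothing, -50, 50)
        sa = 1.0 / (1.0 + np.exp(-a))
        sb = 1.0 / (1.0 + np.exp(-b))
        return (sa * (1 - sa) * sb - sa * sb * (1 - sb)) / self.smoothing

    def in_pulse(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass(frozen=True)
class MembraneState:
    """Voltage, NaV gates and electroporation conductance of one patch."""

    Um: float
    m: float
    h: float
    j: float
    g_ep: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.Um):
            raise ValueError("Um must be finite")
        for name in GATE_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gate {name}={v} outside [0, 1]")
        if self.g_ep < 0:
            raise ValueError("g_ep must be non-negative")


def ionic_currents(
    state: MembraneState, params: ChannelParams, gating: GatingModel
) -> tuple[float, float, float]:
    """(J_Na, J_K, J_L) current densities (A/m^2) for one membrane state."""
    u = state.Um
    j_na = params.g_Na * state.m**3 * state.h * state.j * (u - params.E_Na)
    j_k = params.g_K * float(gating.n_inf(u)) * (u - params.E_K)
    j_l = params.g_L * (u - params.E_L)
    return j_na, j_k, j_l


def gating_derivatives(
    state: MembraneState, gating: GatingModel
) -> tuple[float, float, float]:
    """(dm/dt, dh/dt, dj/dt) in 1/s at the state's voltage."""
    out = []
    for name in GATE_NAMES:
        tau = float(gating.tau_y(name, state.Um))
        if tau <= 0:
            raise ValueError(f"tau_{name} must be positive")
        out.append((float(gating.y_inf(name, state.Um)) - getattr(state, name)) / tau)
    return tuple(out)


def gep_dynamics(
    Um: float,
    t: float,
    ep: EPParams,
    protocol: PulseProtocol,
    g_end: float = 0.0,
):
    """Electroporation conductance at time ``t``.

    Before the pulse: 0.  During the pulse: alpha*(exp(beta*|Um|)-1).
    After the pulse: the end-of-pulse value ``g_end``, decaying as
    exp(-(t - t_pulse_end)/tau_r) when ``ep.recover`` is set.
    """
    if t < protocol.t_start:
        return 0.0
    if t <= protocol.t_end:
        return float(ep.g_pulse(Um))
    if not ep.recover:
        return float(g_end)
    return float(g_end) * float(np.exp(-(t - protocol.t_end) / ep.tau_r))


def _balance_current(u: float, params: ChannelParams, gating: GatingModel) -> float:
    m, h, j = (float(g) for g in gating.steady_gates(u))
    st = MembraneState(Um=u, m=m, h=h, j=j)
    return float(sum(ionic_currents(st, params, gating)))


def resting_state(
    params: ChannelParams | None = None,
    gating: GatingModel | None = None,
    search: tuple[float, float] = (-0.15, 0.05),
) -> MembraneState:
    """Resting fixed point: root of the steady current balance.

    Roots are located by a sign-change scan of the steady-state ionic current
    over ``search``; among stable roots (positive slope of the outward
    current) the most negative is returned.
    """
    params = params or default_channel_params()
    gating = gating or LuoRudyGating()
    grid = np.linspace(search[0], search[1], 4001)
    f = np.array([_balance_current(u, params, gating) for u in grid])
    roots = []
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        u0 = brentq(_balance_current, grid[i], grid[i + 1], args=(params, gating))
        slope = (
            _balance_current(u0 + 5e-5, params, gating)
            - _balance_current(u0 - 5e-5, params, gating)
        ) / 1e-4
        if slope > 0:
            roots.append(u0)
    if not roots:
        raise RuntimeError("no stable resting state found in search interval")
    u_rest = min(roots)
    m, h, j = (float(g) for g in gating.steady_gates(u_rest))
    return MembraneState(Um=u_rest, m=m, h=h, j=j, g_ep=0.0)


def default_channel_params(
    gating: GatingModel | None = None, rest: float = -0.070
) -> ChannelParams:
    """Channel parameters with the leak reversal solved for the target rest.

    The printed maximal conductances are kept; E_Na and E_K are Nernst-style
    defaults for the low-K+ Tyrode bath; E_L is chosen so that the steady
    current balance is zero exactly at ``rest`` (about -70 mV in these cells).
    """
    gating = gating or LuoRudyGating()
    base = ChannelParams()
    m, h, j = (float(g) for g in gating.steady_gates(rest))
    st = MembraneState(Um=rest, m=m, h=h, j=j)
    j_na = base.g_Na * st.m**3 * st.h * st.j * (rest - base.E_Na)
    j_k = base.g_K * float(gating.n_inf(rest)) * (rest - base.E_K)
    e_l = rest + (j_na + j_k) / base.g_L
    return replace(base, E_L=e_l)


@dataclass
class PatchSolution:
    """Time series of one simulated membrane patch."""

    t: np.ndarray
    Um: np.ndarray
    m: np.ndarray
    h: np.ndarray
    j: np.ndarray
    g_ep: np.ndarray

    def state_at(self, i: int) -> MembraneState:
        return MembraneState(
            Um=float(self.Um[i]),
            m=float(np.clip(self.m[i], 0, 1)),
            h=float(np.clip(self.h[i], 0, 1)),
            j=float(np.clip(self.j[i], 0, 1)),
            g_ep=float(max(self.g_ep[i], 0.0)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "Um_V": self.Um,
                "m": self.m,
                "h": self.h,
                "j": self.j,
                "gep_S_per_m2": self.g_ep,
            }
        )


def _patch_rhs_factory(
    params: ChannelParams,
    gating: GatingModel,
    gep_of: Callable[[float, float], float],
    drive: Callable[[float], float] | None,
):
    g_na, g_k, g_l = params.g_Na, params.g_K, params.g_L
    e_na, e_k, e_l = params.E_Na, params.E_K, params.E_L
    c_m = params.C_m

    def rhs(t, y):
        u, m, h, j = y
        m = min(max(m, 0.0), 1.0)
        h = min(max(h, 0.0), 1.0)
        j = min(max(j, 0.0), 1.0)
        j_ion = (
            g_na * m**3 * h * j * (u - e_na)
            + g_k * float(gating.n_inf(u)) * (u - e_k)
            + g_l * (u - e_l)
            + gep_of(t, u) * u
        )
        j_drv = drive(t) if drive is not None else 0.0
        du = (-j_ion + j_drv) / c_m
        dg = []
        for name in GATE_NAMES:
            tau = float(gating.tau_y(name, u))
            dg.append((float(gating.y_inf(name, u)) - {"m": m, "h": h, "j": j}[name]) / tau)
        return [du, *dg]

    return rhs


def simulate_patch(
    params: ChannelParams | None = None,
    gating: GatingModel | None = None,
    ep: EPParams | None = None,
    protocol: PulseProtocol | None = None,
    drive: Callable[[float], float] | None = None,
    duration: float = 3.0,
    dt: float = 1e-3,
    drive_breaks: Sequence[float] = (),
    initial: MembraneState | None = None,
    blowup_limit: float = 1.5,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> PatchSolution:
    """Integrate one space-clamped patch and sample it on a fixed grid.

    The initial state is the resting steady state unless ``initial`` is given.
    Integration is adaptive (LSODA), split at the pulse edges so that the
    end-of-pulse electroporation conductance can be frozen exactly there.
    ``dt`` is the output sampling interval.  A voltage excursion beyond
    ``blowup_limit`` (V) aborts with :class:`SimulationBlowUp`.
    """
    params = params or default_channel_params()
    gating = gating or LuoRudyGating()
    if initial is None:
        initial = resting_state(params, gating)
    t_eval = np.arange(0.0, duration + dt / 2, dt)
    t_eval = t_eval[t_eval <= duration]

    # Phase boundaries at the pulse edges (if a pulse lies inside the window)
    # and at any discontinuities of the drive waveform, so the adaptive
    # integrator cannot step over a brief stimulus.
    cuts = [0.0, duration]
    if protocol is not None and ep is not None:
        for tc in (protocol.t_start, protocol.t_end):
            if 0.0 < tc < duration:
                cuts.append(tc)
    for tc in drive_breaks:
        if 0.0 < tc < duration:
            cuts.append(float(tc))
    cuts = sorted(set(cuts))

    y = [initial.Um, initial.m, initial.h, initial.j]
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    geps: list[np.ndarray] = []
    g_end = initial.g_ep

    def blowup(t, yv):
        return blowup_limit - abs(yv[0])

    blowup.terminal = True

    for a, b in zip(cuts[:-1], cuts[1:]):
        if protocol is not None and ep is not None:
            mid = 0.5 * (a + b)
            if mid < protocol.t_start:
                gep_of = lambda t, u: 0.0
            elif mid <= protocol.t_end:
                gep_of = lambda t, u: float(ep.g_pulse(u))
            else:
                ge = g_end
                if ep.recover:
                    gep_of = lambda t, u, ge=ge: ge * float(
                        np.exp(-(t - protocol.t_end) / ep.tau_r)
                    )
                else:
                    gep_of = lambda t, u, ge=ge: ge
        else:
            gep_of = lambda t, u: 0.0

        rhs = _patch_rhs_factory(params, gating, gep_of, drive)
        seg_eval = t_eval[(t_eval >= a) & (t_eval < b)]
        pts = np.unique(np.concatenate([seg_eval, [b]]))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=pts,
            rtol=rtol,
            atol=atol,
            events=blowup,
            max_step=(b - a) if b - a < 1e-3 else np.inf,
        )
        if sol.status == 1:
            raise SimulationBlowUp(
                f"|Um| exceeded {blowup_limit} V at t={sol.t_events[0][0]:.6g} s"
            )
        if not sol.success:
            raise RuntimeError(f"patch integration failed: {sol.message}")
        y = list(sol.y[:, -1])
        n_out = len(pts) - 1 if pts[-1] == b and (b not in seg_eval) else len(pts)
        if n_out:
            ts.append(sol.t[:n_out])
            ys.append(sol.y[:, :n_out])
            geps.append(
                np.array(
                    [gep_of(tt, uu) for tt, uu in zip(sol.t[:n_out], sol.y[0, :n_out])]
                )
            )
        if protocol is not None and ep is not None and abs(b - protocol.t_end) < 1e-15:
            g_end = float(ep.g_pulse(y[0]))

    # Final sample at t = duration.
    ts.append(np.array([duration]))
    ys.append(np.array(y)[:, None])
    geps.append(
        np.array(
            [
                gep_dynamics(y[0], duration, ep, protocol, g_end)
                if (ep is not None and protocol is not None)
                else 0.0
            ]
        )
    )

    t = np.concatenate(ts)
    yy = np.concatenate(ys, axis=1)
    g = np.concatenate(geps)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return PatchSolution(
        t=t[keep], Um=yy[0, keep], m=yy[1, keep], h=yy[2, keep], j=yy[3, keep],
        g_ep=g[keep],
    )
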