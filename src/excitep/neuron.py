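"""Hodgkin-Huxley neuron equivalent circuit with an electroporation shunt.

The classic squid-axon HH model (m^3*h sodium, n^4 potassium, leak) in SI
per-area units, extended with one extra branch: a fixed nonselective
electroporation conductance ``g_ep`` with 0 mV reversal, representing
membrane permeabilization that persists over the observation window::

    C_m dUm/dt = -g_Na m^3 h (Um-E_Na) - g_K n^4 (Um-E_K)
                 - g_L (Um-E_L) - g_ep*Um + J_stim(t)

With increasing g_ep the response to one brief suprathreshold stimulus
progresses from a single action potential, through repetitive firing (the
shunt acts as a steady depolarizing current), to sustained depolarization
(excitation block), which is the qualitative signature this module exists to
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from excitep.membrane import SimulationBlowUp
from excitep import trace_analysis as ta

__all__ = ["HHNeuronParams", "simulate_neuron", "gep_response_scan", "hh_rates"]


@dataclass(frozen=True)
class HHNeuronParams:
    """Classic HH parameters (SI per-area units) plus the g_ep shunt.

    The stimulus is a brief rectangular depolarizing current pulse
    (``stim_amplitude`` A/m^2 from ``stim_start`` for ``stim_duration``).
    """

    g_Na: float = 1200.0
    g_K: float = 360.0
    g_L: float = 3.0
    E_Na: float = 0.050
    E_K: float = -0.077
    E_L: float = -0.054387
    C_m: float = 0.01
    g_ep: float = 0.0
    stim_amplitude: float = 0.2
    stim_start: float = 0.010
    stim_duration: float = 0.002

    def __post_init__(self) -> None:
        if min(self.g_Na, self.g_K, self.g_L, self.g_ep) < 0:
            raise ValueError("conductances must be non-negative")
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")


def hh_rates(v_mv):
    """Classic HH rate constants (1/ms) for gates n, m, h; voltage in mV."""
    v = np.asarray(v_mv, dtype=float)

    def _safe_lin_exp(x, scale):
        # x / (1 - exp(-x/scale)) with the removable singularity at x = 0
        y = x / scale
        small = np.abs(y) < 1e-7
        denom = 1.0 - np.exp(-np.where(small, 1.0, y))
        return np.where(small, scale, x / np.where(small, 1.0, denom))

    a_n = 0.01 * _safe_lin_exp(v + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    a_m = 0.1 * _safe_lin_exp(v + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    return (a_n, b_n), (a_m, b_m), (a_h, b_h)


def _steady_gates(v_mv: float) -> tuple[float, float, float]:
    (an, bn), (am, bm), (ah, bh) = hh_rates(v_mv)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _steady_current(u: float, p: HHNeuronParams) -> float:
    m, h, n = _steady_gates(u * 1e3)
    return (
        p.g_Na * m**3 * h * (u - p.E_Na)
        + p.g_K * n**4 * (u - p.E_K)
        + p.g_L * (u - p.E_L)
        + p.g_ep * u
    )


def resting_voltage(params: HHNeuronParams) -> float:
    """Most negative stable fixed point of the (shunted) HH current balance."""
    grid = np.linspace(-0.090, 0.0, 1801)
    f = np.array([_steady_current(u, params) for u in grid])
    for i in np.flatnonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0):
        u0 = brentq(_steady_current, grid[i], grid[i + 1], args=(params,))
        slope = (
            _steady_current(u0 + 5e-5, params) - _steady_current(u0 - 5e-5, params)
        ) / 1e-4
        if slope > 0:
            return float(u0)
    raise RuntimeError("no stable HH resting state found")


def simulate_neuron(
    params: HHNeuronParams,
    duration: float = 0.5,
    dt: float = 5e-4,
    blowup_limit: float = 1.0,
) -> pd.DataFrame:
    """Integrate the shunted HH circuit; returns time_s, Um_V (plus gates).

    The initial state is the unshunted (g_ep = 0) resting state: the membrane
    is at its normal rest when electroporation switches the shunt on at t=0.
    """
    u0 = resting_voltage(replace(params, g_ep=0.0))
    m0, h0, n0 = _steady_gates(u0 * 1e3)

    def rhs(t, y):
        u, m, h, n = y
        (an, bn), (am, bm), (ah, bh) = hh_rates(u * 1e3)
        j_ion = (
            params.g_Na * m**3 * h * (u - params.E_Na)
            + params.g_K * n**4 * (u - params.E_K)
            + params.g_L * (u - params.E_L)
            + params.g_ep * u
        )
        j_stim = (
            params.stim_amplitude
            if params.stim_start <= t <= params.stim_start + params.stim_duration
            else 0.0
        )
        # HH rates are per ms.
        return [
            (-j_ion + j_stim) / params.C_m,
            1e3 * (am * (1 - m) - bm * m),
            1e3 * (ah * (1 - h) - bh * h),
            1e3 * (an * (1 - n) - bn * n),
        ]

    def blowup(t, y):
        return blowup_limit - abs(y[0])

    blowup.terminal = True

    t_eval = np.arange(0.0, duration + dt / 2, dt)
    cuts = sorted(
        {0.0, duration}
        | {
            tc
            for tc in (params.stim_start, params.stim_start + params.stim_duration)
            if 0.0 < tc < duration
        }
    )
    y = [u0, m0, h0, n0]
    ts, ys = [], []
    for a, b in zip(cuts[:-1], cuts[1:]):
        pts = np.unique(np.concatenate([t_eval[(t_eval >= a) & (t_eval < b)], [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=pts,
                        rtol=1e-7, atol=1e-9, events=blowup)
        if sol.status == 1:
            raise SimulationBlowUp("neuron voltage left the plausible range")
        if not sol.success:
            raise RuntimeError(f"HH integration failed: {sol.message}")
        y = list(sol.y[:, -1])
        n_out = len(pts) - (1 if (pts[-1] == b and b not in t_eval) else 0)
        ts.append(sol.t[:n_out])
        ys.append(sol.y[:, :n_out])
    t = np.concatenate(ts)
    yy = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return pd.DataFrame(
        {"time_s": t[keep], "Um_V": yy[0, keep], "m": yy[1, keep],
         "h": yy[2, keep], "n": yy[3, keep]}
    )


def gep_response_scan(
    params: HHNeuronParams,
    gep_values: Sequence[float],
    duration: float = 0.5,
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Response class and peak count for each electroporation conductance.

    Each simulated voltage trace is normalized to the optical-response scale
    and classified with the same four-class rule used for experimental
    traces.  Returns one row per g_ep value.
    """
    if list(gep_values) != sorted(gep_values):
        raise ValueError("gep_values must be sorted ascending")
    if any(g < 0 for g in gep_values):
        raise ValueError("gep_values must be non-negative")
    rest = resting_voltage(replace(params, g_ep=0.0))
    rows = []
    for g in gep_values:
        df = simulate_neuron(replace(params, g_ep=float(g)), duration, dt)
        resp = ta.from_membrane_trace(
            df["time_s"].to_numpy(),
            df["Um_V"].to_numpy(),
            rest=rest,
            pulse_time=max(params.stim_start - dt, 0.0),
            ap_amplitude=0.105,
        )
        peaks = ta.detect_peaks(resp, smooth_frames=1)
        p = ta.extract_params(resp, peaks)
        cls = ta.classify(p)
        rows.append(
            {"g_ep_S_per_m2": float(g), "response_class": cls.value,
             "n_peaks": p.n_peaks}
        )
    return pd.DataFrame(rows)
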