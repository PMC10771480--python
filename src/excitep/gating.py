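"""Voltage-gated channel kinetics for the engineered excitable HEK membrane.

The excitable ("spiking") HEK line expresses exactly two channels: the cardiac
fast sodium channel NaV1.5, gated by activation ``m`` (cubed) and two
inactivation gates ``h`` and ``j``, and the inward-rectifier potassium channel
Kir2.1, whose open fraction is treated as the instantaneous rectification
function ``n_inf(Um)``.

The gating formulation is pluggable.  The default, :class:`LuoRudyGating`,
adopts the classic Luo-Rudy phase-1 rate functions for the NaV m/h/j gates --
the standard m^3*h*j description of the cardiac sodium current -- with an
overall kinetics scale factor that slows all rates relative to the original
37 deg C formulation (experiments on these cells are done at room temperature).
Kir2.1 rectification is a Boltzmann function of voltage: the open fraction is
high near the potassium reversal potential and shuts off steeply with
depolarization, which is what makes the resting state easily excitable.

All quantities are SI: volts and seconds.  Rate functions are vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GatingModel", "LuoRudyGating", "GATE_NAMES"]

GATE_NAMES = ("m", "h", "j")


class GatingModel:
    """Interface for NaV1.5 m^3*h*j gating plus Kir2.1 rectification.

    Subclasses implement ``y_inf(name, Um)`` and ``tau_y(name, Um)`` for
    ``name`` in ``("m", "h", "j")`` and the rectification ``n_inf(Um)``.
    Voltages in volts, time constants in seconds.
    """

    def y_inf(self, name: str, Um):  # pragma: no cover - interface
        raise NotImplementedError

    def tau_y(self, name: str, Um):  # pragma: no cover - interface
        raise NotImplementedError

    def n_inf(self, Um):  # pragma: no cover - interface
        raise NotImplementedError

    # Convenience bundles used by the simulators.
    def steady_gates(self, Um):
        """(m_inf, h_inf, j_inf) at voltage ``Um``."""
        return tuple(self.y_inf(n, Um) for n in GATE_NAMES)

    def rates(self, Um):
        """((m_inf, tau_m), (h_inf, tau_h), (j_inf, tau_j)) at ``Um``."""
        return tuple((self.y_inf(n, Um), self.tau_y(n, Um)) for n in GATE_NAMES)


def _lr_sodium_rates(v_mv):
    """Luo-Rudy phase-1 fast-sodium rate constants (1/ms), voltage in mV.

    Voltages are clamped to [-150, 150] mV before evaluation: every gate is
    fully saturated there, and the clamp keeps the exponentials finite during
    the extreme transmembrane voltages reached within an electroporating
    pulse.
    """
    v = np.clip(np.asarray(v_mv, dtype=float), -150.0, 150.0)

    # m gate: guard the removable singularity at v = -47.13 mV.
    dv = v + 47.13
    denom = 1.0 - np.exp(-0.1 * dv)
    small = np.abs(dv) < 1e-7
    a_m = np.where(small, 3.2, 0.32 * dv / np.where(small, 1.0, denom))
    b_m = 0.08 * np.exp(-v / 11.0)

    low = v < -40.0
    with np.errstate(over="ignore"):
        a_h = np.where(low, 0.135 * np.exp(-(80.0 + v) / 6.8), 0.0)
        b_h = np.where(
            low,
            3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v),
            1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
        )
        a_j = np.where(
            low,
            (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23))),
            0.0,
        )
        b_j = np.where(
            low,
            0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
            0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
        )
    return (a_m, b_m), (a_h, b_h), (a_j, b_j)


@dataclass(frozen=True)
class LuoRudyGating(GatingModel):
    """Default gating model: Luo-Rudy NaV m^3*h*j + Boltzmann Kir2.1 rectifier.

    Parameters
    ----------
    kinetics_scale : float
        Multiplier applied to every NaV rate constant.  Default 1/3,
        a Q10~3 slowdown of the 37 deg C rates to room temperature.
    kir_v_half : float
        Voltage (V) at which the Kir2.1 open fraction is one half.
    kir_slope : float
        Boltzmann slope factor (V); smaller is steeper rectification.
    """

    kinetics_scale: float = 1.0 / 3.0
    kir_v_half: float = -0.060
    kir_slope: float = 0.008

    def _ab(self, name: str, Um):
        v_mv = np.asarray(Um, dtype=float) * 1e3
        rates = _lr_sodium_rates(v_mv)
        a, b = rates[GATE_NAMES.index(name)]
        # 1/ms -> 1/s, then the room-temperature slowdown.
        s = 1e3 * self.kinetics_scale
        return a * s, b * s

    def y_inf(self, name: str, Um):
        a, b = self._ab(name, Um)
        return a / (a + b)

    def tau_y(self, name: str, Um):
        a, b = self._ab(name, Um)
        return 1.0 / (a + b)

    def n_inf(self, Um):
        u = np.asarray(Um, dtype=float)
        x = np.clip((u - self.kir_v_half) / self.kir_slope, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(x))

    def rates_mhj(self, Um):
        """All six NaV rate quantities at once (vectorized fast path).

        Returns (m_inf, tau_m, h_inf, tau_h, j_inf, tau_j); equivalent to the
        per-gate accessors but evaluates the rate functions a single time.
        """
        v_mv = np.asarray(Um, dtype=float) * 1e3
        s = 1e3 * self.kinetics_scale
        out = []
        for a, b in _lr_sodium_rates(v_mv):
            tot = (a + b) * s
            out.extend((a / (a + b), 1.0 / tot))
        return tuple(out)
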