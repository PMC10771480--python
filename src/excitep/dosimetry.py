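"""Closed-form exposure bookkeeping for pulse delivery between wire electrodes.

Nominal electric field, delivered pulse power, and the worst-case adiabatic
temperature rise of the bathing medium (all heat deposited instantaneously,
no dissipation)::

    dT = E^2 * sigma * t_pulse / (c_heat * rho)

The default conductivity is that of the low-K+ Tyrode buffer (1.432 S/m).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ExposureSpec", "nominal_field", "pulse_power", "temp_rise"]


@dataclass(frozen=True)
class ExposureSpec:
    """One pulse exposure between parallel wire electrodes.

    Parameters
    ----------
    U : float
        Applied voltage (V).
    d : float
        Distance between electrode inner edges (m).
    I : float or None
        Measured current (A), if available.
    sigma : float
        Medium conductivity (S/m).
    t_pulse : float
        Pulse duration (s).
    c_heat : float
        Specific heat of the medium (J/(kg K)).
    rho : float
        Medium density (kg/m^3).
    """

    U: float
    d: float = 5e-3
    I: float | None = None
    sigma: float = 1.432
    t_pulse: float = 1e-4
    c_heat: float = 4200.0
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("electrode distance d must be positive")
        if self.sigma <= 0 or self.c_heat <= 0 or self.rho <= 0:
            raise ValueError("sigma, c_heat and rho must be positive")


def nominal_field(U: float, d: float) -> float:
    """Nominal field U/d (V/m) between electrodes at distance ``d``."""
    if d <= 0:
        raise ValueError("electrode distance d must be positive")
    return U / d


def pulse_power(U: float, I: float) -> float:
    """Instantaneous delivered power U*I (W)."""
    return U * I


def temp_rise(spec: ExposureSpec) -> float:
    """Worst-case adiabatic temperature rise (K) of the medium for one pulse."""
    E = nominal_field(spec.U, spec.d)
    return E * E * spec.sigma * spec.t_pulse / (spec.c_heat * spec.rho)
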