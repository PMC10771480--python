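"""Flat YAML configuration for the simulator CLIs.

A config file is a flat mapping of parameter names to numbers/booleans, e.g.::

    g_Na: 27.5
    g_K: 0.5
    g_L: 0.05
    C_m: 0.01
    alpha: 5.0e-6
    beta: 40.0
    tau_r: 2.0
    recover: false
    amplitude: 15000.0   # V/m (or V for voltage-driven protocols)
    t_pulse: 1.0e-4
    t_start: 0.36

Unknown keys are rejected so typos do not silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import yaml

from excitep.gating import LuoRudyGating
from excitep.membrane import ChannelParams, EPParams, PulseProtocol, default_channel_params

__all__ = ["load_config", "build_membrane_setup"]

_CHANNEL_KEYS = {f.name for f in dc_fields(ChannelParams)}
_EP_KEYS = {f.name for f in dc_fields(EPParams)}
_PROTOCOL_KEYS = {f.name for f in dc_fields(PulseProtocol)}
_GATING_KEYS = {f.name for f in dc_fields(LuoRudyGating)}


def load_config(path: str | Path) -> dict:
    """Read a flat YAML mapping."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def build_membrane_setup(cfg: dict):
    """(ChannelParams, LuoRudyGating, EPParams | None, PulseProtocol | None).

    Channel reversal potentials omitted from the config are filled by the
    default leak-reversal solve (resting voltage -70 mV).  An electroporation
    block is built only if ``alpha`` is present; a protocol only if
    ``amplitude`` is present.
    """
    known = _CHANNEL_KEYS | _EP_KEYS | _PROTOCOL_KEYS | _GATING_KEYS
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    gating = LuoRudyGating(**{k: cfg[k] for k in _GATING_KEYS & set(cfg)})
    ch_kwargs = {k: cfg[k] for k in _CHANNEL_KEYS & set(cfg)}
    if "E_L" in ch_kwargs:
        channels = ChannelParams(**ch_kwargs)
    else:
        base = default_channel_params(gating)
        channels = ChannelParams(**{**base.__dict__, **ch_kwargs})
    ep = (
        EPParams(**{k: cfg[k] for k in _EP_KEYS & set(cfg)})
        if "alpha" in cfg
        else None
    )
    protocol = (
        PulseProtocol(**{k: cfg[k] for k in _PROTOCOL_KEYS & set(cfg)})
        if "amplitude" in cfg
        else None
    )
    return channels, gating, ep, protocol
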