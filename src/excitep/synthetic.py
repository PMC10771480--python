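"""Ground-truth-labelled synthetic optical-voltage and calcium traces.

Emulates the two acquisition modes of the experiments on engineered
excitable HEK monolayers so that the analysis pipelines can be validated
without any microscopy data:

* ElectroFluor630 voltage traces: 80 frames at 36 ms, pulse after the 10th
  frame.  The raw intensity is ``F(t) = (k*t + F0) * (1 - R_true(t)) + noise``
  with a linear photobleaching trend ``k`` and a class-specific response
  template ``R_true``: no response, a single AP bump (exponential rise,
  logistic repolarization), a train of AP bumps, or a step with a slow decay
  (sustained depolarization), optionally with an onset delay after the pulse.
* Fura-2 ratio traces: 40 frames at 1 s, pulse near 5 s, zeroed origin, slow
  linear baseline drift, and 0/1/2-peak morphologies (the two-peak shape has
  a larger delayed second peak) plus a sigmoid-plateau morphology.

Every generator draws all randomness from one seeded generator; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from excitep.fura2 import RatioTrace
from excitep.trace_analysis import (
    FluorescenceTrace,
    ResponseClass,
    ResponseParams,
    write_trace,
)

__all__ = [
    "TraceGenSpec",
    "Fura2GenSpec",
    "ExperimentSpec",
    "gen_electrofluor_trace",
    "gen_fura2_trace",
    "gen_experiment",
    "default_class_probabilities",
]

#: Acquisition grid of the voltage-dye recordings.
N_FRAMES = 80
FRAME_INTERVAL = 0.036
PULSE_TIME = 0.324  # pulse delivered after the 10th frame

#: Acquisition grid of the calcium recordings.
CA_N_FRAMES = 40
CA_FRAME_INTERVAL = 1.0
CA_PULSE_TIME = 5.0


@dataclass(frozen=True)
class TraceGenSpec:
    """Recipe for one synthetic voltage-dye trace.

    The single-AP bump rises with time constant ``rise_tau`` and repolarizes
    sigmoidally, reaching half amplitude ``decay_half`` after onset with a
    transition width ``repol_width`` -- the shape of a regeneratively
    repolarizing action potential, for which t90/t50 < 2.  The sustained-
    depolarization template is a step whose decay (``slow_decay_tau``) is far
    slower than the 2.5 s observation window.
    """

    target_class: ResponseClass = ResponseClass.single_AP
    amplitude: float = 0.05
    rise_tau: float = 0.020
    decay_half: float = 0.350
    repol_width: float = 0.060
    slow_decay_tau: float = 5.0
    n_peaks: int = 3
    peak_interval: float = 0.550
    onset_delay: float = 0.0
    fading_k: float = -5.0
    baseline: float = 100.0
    noise_sd: float = 0.0
    n_frames: int = N_FRAMES
    frame_interval: float = FRAME_INTERVAL
    pulse_time: float = PULSE_TIME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if min(self.rise_tau, self.decay_half, self.repol_width,
               self.slow_decay_tau) <= 0:
            raise ValueError("time constants must be positive")


def _ap_bump(t: np.ndarray, t0: float, amp: float, tau_r: float,
             d_half: float, width: float):
    """AP-shaped bump: exponential rise times a logistic repolarization."""
    s = t - t0
    with np.errstate(over="ignore"):
        shape = (1.0 - np.exp(-np.maximum(s, 0.0) / tau_r)) / (
            1.0 + np.exp(np.clip((s - d_half) / width, -50, 50))
        )
    shape[s < 0] = 0.0
    sf = np.linspace(0.0, d_half + 10 * width, 4001)
    norm = np.max(
        (1.0 - np.exp(-sf / tau_r)) / (1.0 + np.exp(np.clip((sf - d_half) / width,
                                                            -50, 50)))
    )
    return amp * shape / norm


def _ca_bump(t: np.ndarray, t0: float, amp: float, tau_r: float, tau_d: float):
    """Difference-of-exponentials bump, unit-normalized to peak at ``amp``."""
    s = np.maximum(t - t0, 0.0)
    raw = np.exp(-s / tau_d) - np.exp(-s / tau_r)
    s_peak = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    norm = np.exp(-s_peak / tau_d) - np.exp(-s_peak / tau_r)
    out = amp * raw / norm
    out[t < t0] = 0.0
    return out, t0 + s_peak


def _response_template(spec: TraceGenSpec, t: np.ndarray) -> np.ndarray:
    """Continuous noiseless response template R_true evaluated at times ``t``."""
    t0 = spec.pulse_time + spec.onset_delay
    cls = ResponseClass(spec.target_class)
    if cls == ResponseClass.no_response:
        return np.zeros_like(t)
    if cls == ResponseClass.single_AP:
        return _ap_bump(t, t0, spec.amplitude, spec.rise_tau, spec.decay_half,
                        spec.repol_width)
    if cls == ResponseClass.multiple_APs:
        r = np.zeros_like(t)
        for i in range(spec.n_peaks):
            r += _ap_bump(t, t0 + i * spec.peak_interval, spec.amplitude,
                          spec.rise_tau, spec.decay_half, spec.repol_width)
        return r
    # Sustained depolarization: fast rise, decay much slower than the window.
    s = np.maximum(t - t0, 0.0)
    r = spec.amplitude * (1.0 - np.exp(-s / spec.rise_tau)) * np.exp(
        -s / spec.slow_decay_tau
    )
    r[t < t0] = 0.0
    return r


def _truth_params(spec: TraceGenSpec) -> ResponseParams:
    """Ground-truth response parameters from the continuous template.

    Evaluated on a dense 1 ms grid, independently of the analysis pipeline.
    """
    from scipy.signal import find_peaks as _fp

    if ResponseClass(spec.target_class) == ResponseClass.no_response:
        return ResponseParams(n_peaks=0)
    t_end = spec.pulse_time + 2.5
    tf = np.arange(0.0, t_end + 1e-3, 1e-3)
    r = _response_template(spec, tf)
    idx, _ = _fp(r, prominence=0.02 * spec.amplitude)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(r))])
    apexes = [float(tf[i]) for i in idx]
    first = apexes[0]
    max_response = float(np.max(r))
    params = ResponseParams(
        n_peaks=len(apexes),
        peak_times=apexes,
        max_response=max_response,
        time_to_first_peak=float(first - spec.pulse_time),
    )
    if len(apexes) >= 2:
        params.mean_peak_to_peak = float(np.mean(np.diff(apexes)))
    for name, frac in (("t25", 0.25), ("t50", 0.50), ("t90", 0.90)):
        level = max_response * (1.0 - frac)
        after = np.flatnonzero((tf > first) & (r <= level))
        setattr(params, name, float(tf[after[0]] - first) if len(after) else None)
    return params


def gen_electrofluor_trace(
    spec: TraceGenSpec,
) -> tuple[FluorescenceTrace, FluorescenceTrace, ResponseParams, ResponseClass]:
    """One synthetic voltage-dye trace, its control, and the ground truth."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.frame_interval
    r_true = _response_template(spec, t)
    base = spec.fading_k * t + spec.baseline
    f = base * (1.0 - r_true) + rng.normal(0.0, spec.noise_sd * spec.baseline, len(t))
    f_ctrl = base + rng.normal(0.0, spec.noise_sd * spec.baseline, len(t))
    trace = FluorescenceTrace(times=t, F=np.maximum(f, 1e-6), pulse_time=spec.pulse_time)
    control = FluorescenceTrace(times=t, F=np.maximum(f_ctrl, 1e-6), is_control=True)
    truth = _truth_params(spec)
    return trace, control, truth, ResponseClass(spec.target_class)


@dataclass(frozen=True)
class Fura2GenSpec:
    """Recipe for one synthetic Fura-2 ratio trace.

    ``morphology`` is one of ``"none"`` (drift only), ``"one_peak"``,
    ``"two_peak"`` (second peak larger and delayed) or ``"sigmoid"``
    (plateau-reaching rise exercising the 95% fallback rule).
    """

    morphology: str = "one_peak"
    amplitude: float = 0.10
    second_amplitude: float = 0.20
    second_delay: float = 12.0
    rise_tau: float = 1.0
    decay_tau: float = 5.0
    drift_slope: float = 0.002
    noise_sd: float = 0.0
    n_frames: int = CA_N_FRAMES
    frame_interval: float = CA_FRAME_INTERVAL
    pulse_time: float = CA_PULSE_TIME
    seed: int = 0


def gen_fura2_trace(spec: Fura2GenSpec) -> tuple[RatioTrace, dict]:
    """One synthetic ratio trace plus its ground truth (peak times/amps)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.frame_interval
    y = spec.drift_slope * t
    truth: dict = {"n_peaks": 0, "peak_times": [], "peak_amplitudes": []}
    if spec.morphology == "one_peak":
        b, apex = _ca_bump(t, spec.pulse_time, spec.amplitude, spec.rise_tau,
                           spec.decay_tau)
        y = y + b
        truth = {"n_peaks": 1, "peak_times": [apex],
                 "peak_amplitudes": [spec.amplitude]}
    elif spec.morphology == "two_peak":
        b1, a1 = _ca_bump(t, spec.pulse_time, spec.amplitude, spec.rise_tau,
                          spec.decay_tau)
        b2, a2 = _ca_bump(t, spec.pulse_time + spec.second_delay,
                          spec.second_amplitude, 2.0 * spec.rise_tau,
                          2.0 * spec.decay_tau)
        y = y + b1 + b2
        truth = {"n_peaks": 2, "peak_times": [a1, a2],
                 "peak_amplitudes": [spec.amplitude, spec.second_amplitude]}
    elif spec.morphology == "sigmoid":
        # Smoothstep rise to an exact plateau: the discrete derivative truly
        # reaches zero, exercising the 95%-of-zero-crossing fallback rule.
        ramp = np.clip((t - spec.pulse_time) / (6.0 * spec.rise_tau), 0.0, 1.0)
        y = y + spec.amplitude * ramp * ramp * (3.0 - 2.0 * ramp)
        truth = {"n_peaks": 1, "peak_times": [None],
                 "peak_amplitudes": [spec.amplitude]}
    elif spec.morphology != "none":
        raise ValueError(f"unknown morphology {spec.morphology!r}")
    y = y + rng.normal(0.0, spec.noise_sd, len(t))
    y = y - y[0]
    return RatioTrace(times=t, ratio=y, pulse_time=spec.pulse_time), truth


def default_class_probabilities(variant: str = "excitable") -> pd.DataFrame:
    """Qualitative per-field class-probability schedule of a pulse sequence.

    For the excitable variant, multiple APs are most common at low fields and
    sustained depolarization dominates at and above 250 V/cm; the
    non-excitable variant never fires APs and only shows depolarizations of
    increasing persistence.
    """
    fields = [126.0, 150.0, 176.0, 200.0, 250.0, 300.0, 350.0, 400.0]
    if variant == "excitable":
        rows = [
            (0.35, 0.20, 0.30, 0.15),
            (0.25, 0.25, 0.30, 0.20),
            (0.15, 0.25, 0.30, 0.30),
            (0.10, 0.25, 0.25, 0.40),
            (0.05, 0.15, 0.15, 0.65),
            (0.03, 0.10, 0.07, 0.80),
            (0.02, 0.05, 0.05, 0.88),
            (0.02, 0.03, 0.03, 0.92),
        ]
    elif variant == "non_excitable":
        rows = [
            (0.55, 0.0, 0.0, 0.45),
            (0.45, 0.0, 0.0, 0.55),
            (0.35, 0.0, 0.0, 0.65),
            (0.30, 0.0, 0.0, 0.70),
            (0.20, 0.0, 0.0, 0.80),
            (0.12, 0.0, 0.0, 0.88),
            (0.08, 0.0, 0.0, 0.92),
            (0.05, 0.0, 0.0, 0.95),
        ]
    else:
        raise ValueError(f"unknown cell variant {variant!r}")
    return pd.DataFrame(
        rows,
        columns=[c.value for c in ResponseClass],
        index=pd.Index(fields, name="field_V_per_cm"),
    )


@dataclass(frozen=True)
class ExperimentSpec:
    """A full pseudo-experiment: a field sweep with replicates and controls."""

    fields: Sequence[float] = (126.0, 150.0, 176.0, 200.0, 250.0, 300.0, 350.0, 400.0)
    n_replicates: int = 20
    cell_variant: str = "excitable"
    class_probabilities: pd.DataFrame | None = None
    noise_sd: float = 0.002
    seed: int = 0
    trace_defaults: Mapping = field(default_factory=dict)

    def probabilities(self) -> pd.DataFrame:
        table = (
            self.class_probabilities
            if self.class_probabilities is not None
            else default_class_probabilities(self.cell_variant)
        )
        if not np.allclose(table.sum(axis=1), 1.0):
            raise ValueError("class probabilities must sum to 1 per field")
        return table


def gen_experiment(
    spec: ExperimentSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list, list]:
    """Sample one pseudo-experiment from the class-probability table.

    Each replicate is one pulse sequence: one trace per field plus one control
    sequence.  Returns (manifest, truth table, traces, controls) where
    ``traces`` is a list of (field, FluorescenceTrace) ready for
    :func:`excitep.trace_analysis.analyze_batch`.  When ``out_dir`` is given,
    traces are written as delimited text and the manifest/truth as CSV,
    mirroring a real acquisition session.
    """
    table = spec.probabilities()
    rng = np.random.default_rng(spec.seed)
    classes = list(ResponseClass)
    manifest_rows = []
    truth_rows = []
    traces: list[tuple[float, FluorescenceTrace]] = []
    controls: list[FluorescenceTrace] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "traces").mkdir(parents=True, exist_ok=True)

    for rep in range(spec.n_replicates):
        ctrl_spec = TraceGenSpec(
            target_class=ResponseClass.no_response,
            noise_sd=spec.noise_sd,
            seed=int(rng.integers(2**31)),
            **spec.trace_defaults,
        )
        _, control, _, _ = gen_electrofluor_trace(ctrl_spec)
        controls.append(control)
        ctrl_id = f"rep{rep:02d}_control"
        manifest_rows.append(
            {"trace_id": ctrl_id, "field_V_per_cm": np.nan, "is_control": True,
             "file": f"traces/{ctrl_id}.csv"}
        )
        if out is not None:
            write_trace(control, out / "traces" / f"{ctrl_id}.csv")
        for fld in spec.fields:
            probs = table.loc[float(fld)].to_numpy()
            cls = classes[int(rng.choice(len(classes), p=probs))]
            tspec = TraceGenSpec(
                target_class=cls,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(2**31)),
                **spec.trace_defaults,
            )
            trace, _, truth, _ = gen_electrofluor_trace(tspec)
            tid = f"rep{rep:02d}_f{int(fld):03d}"
            traces.append((float(fld), trace))
            manifest_rows.append(
                {"trace_id": tid, "field_V_per_cm": float(fld), "is_control": False,
                 "file": f"traces/{tid}.csv"}
            )
            truth_rows.append(
                {"trace_id": tid, "field_V_per_cm": float(fld), "class": cls.value,
                 "n_peaks": truth.n_peaks, "max_response": truth.max_response}
            )
            if out is not None:
                write_trace(trace, out / "traces" / f"{tid}.csv")

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        pd.Series({"seed": spec.seed, "n_replicates": spec.n_replicates,
                   "cell_variant": spec.cell_variant}).to_json(out / "run_spec.json")
    return manifest, truth, traces, controls
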