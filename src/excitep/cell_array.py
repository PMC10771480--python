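"""Reduced-order equivalent-circuit network of a hemispherical cell array.

Stands in for a 3D finite-element model of a 10 x 10 array of hemispherical
cells (radius 9 µm, centre spacing 1.9 R, ~10% of membrane area in cell-cell
contacts) exposed to a uniform applied field between two virtual electrodes.

Topology (quasi-static lumped network):

* one intracellular node per cell (the cell interior is equipotential --
  cytoplasmic resistance is negligible on this length scale);
* one extracellular node per cell-row boundary plane along the field axis;
  the two outermost planes are pinned to the electrode potentials
  (anode = E * L, cathode = 0) during the pulse;
* consecutive planes are linked by slab resistors,
  G_e = sigma_e * A_cross / pitch with A_cross the bath cross-section
  (array width x bath height) -- the medium charges in well under a
  microsecond, so its dielectric response is not modelled;
* each cell carries two membrane patches (anodic and cathodic halves of the
  free membrane, equal areas) connecting its intracellular node to the
  adjacent planes; each patch carries the full membrane current balance:
  capacitance C_m, NaV1.5/Kir2.1/leak currents, and the electroporation
  conductance g_ep driven by the local |Um| during the pulse;
* neighbouring cells are linked through their contact areas by the
  gap-junction conductance g_Cxn (zero in the non-connected variant) in
  parallel with the series capacitance C_m/2 of the two contact membranes
  (present in both variants).

The area-averaged transmembrane voltage over all free membrane patches is
the model counterpart of the optically recorded whole-field signal and is
classified with the same four-class rule as experimental traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from excitep.gating import GatingModel, LuoRudyGating
from excitep.membrane import (
    ChannelParams,
    EPParams,
    PulseProtocol,
    SimulationBlowUp,
    default_channel_params,
    resting_state,
)
from excitep import trace_analysis as ta

__all__ = [
    "ArrayGeometry",
    "ArrayParams",
    "CircuitNetwork",
    "NetworkSolution",
    "build_network",
    "simulate_array",
    "threshold_sweep",
    "end_of_pulse_tmv_profile",
    "response_class",
]

#: Default gap-junction specific conductance (S/m^2).  Calibrated once so
#: that the connected 10x10 array first fires an action potential at
#: 100 V/cm in the standard field sweep (see docs/methods.md).
DEFAULT_G_CXN = 2000.0


@dataclass(frozen=True)
class ArrayGeometry:
    """Grid size and single-cell geometry of the hemispherical array."""

    n_cells_x: int = 10
    n_cells_y: int = 10
    R_cell: float = 9e-6
    pitch: float = 1.9
    shared_fraction: float = 0.10
    patches_per_cell: int = 2
    bath_height: float = 100e-6

    def __post_init__(self) -> None:
        if self.pitch >= 2.0:
            raise ValueError("pitch must be < 2 cell radii (cells in contact)")
        if not 0.0 < self.shared_fraction < 1.0:
            raise ValueError("shared_fraction must be in (0, 1)")
        if self.patches_per_cell != 2:
            raise ValueError(
                "the plane-node reduced network lumps each cell into "
                "anodic/cathodic faces; patches_per_cell must be 2"
            )
        if min(self.n_cells_x, self.n_cells_y) < 1:
            raise ValueError("grid must contain at least one cell")
        if self.R_cell <= 0 or self.bath_height <= 0:
            raise ValueError("R_cell and bath_height must be positive")

    @property
    def pitch_m(self) -> float:
        return self.pitch * self.R_cell

    @property
    def membrane_area(self) -> float:
        """Curved membrane area of one hemispherical cell."""
        return 2.0 * np.pi * self.R_cell**2

    @property
    def free_patch_area(self) -> float:
        """Area of one (anodic or cathodic) free-membrane patch."""
        return 0.5 * (1.0 - self.shared_fraction) * self.membrane_area

    @property
    def contact_area(self) -> float:
        """Contact area of one cell-cell junction (shared area split 4 ways)."""
        return self.shared_fraction * self.membrane_area / 4.0

    @property
    def length(self) -> float:
        """Electrode-to-electrode extent along the field axis."""
        return self.n_cells_y * self.pitch_m

    @property
    def cross_section(self) -> float:
        return self.n_cells_x * self.pitch_m * self.bath_height


@dataclass(frozen=True)
class ArrayParams:
    """Electrical parameters of the array model."""

    sigma_i: float = 0.5
    sigma_e: float = 1.432
    g_Cxn: float = DEFAULT_G_CXN
    connected: bool = True
    channels: ChannelParams | None = None
    gating: GatingModel = field(default_factory=LuoRudyGating)
    ep: EPParams | None = field(default_factory=EPParams)

    def __post_init__(self) -> None:
        if self.sigma_i <= 0 or self.sigma_e <= 0:
            raise ValueError("conductivities must be positive")
        if self.g_Cxn < 0:
            raise ValueError("g_Cxn must be non-negative")

    def junction_conductance(self) -> float:
        return self.g_Cxn if self.connected else 0.0


class CircuitNetwork:
    """Assembled lumped network: node bookkeeping and stamped matrices."""

    def __init__(self, geometry: ArrayGeometry, params: ArrayParams):
        self.geometry = geometry
        self.params = params
        self.channels = params.channels or default_channel_params(params.gating)
        nx, ny = geometry.n_cells_x, geometry.n_cells_y
        self.n_cells = nx * ny
        # Free nodes: cells 0..n_cells-1, then interior planes 1..ny-1.
        self.n_planes = ny + 1
        self.n_free = self.n_cells + (self.n_planes - 2)
        if geometry.free_patch_area <= 0 or geometry.contact_area <= 0:
            raise ValueError("degenerate geometry: zero membrane areas")

        def cell_index(r: int, c: int) -> int:
            return r * nx + c

        def plane_node(p: int) -> int | None:
            """Free-node index of plane p, or None if pinned."""
            if p == 0 or p == ny:
                return None
            return self.n_cells + (p - 1)

        self._cell_index = cell_index
        self._plane_node = plane_node

        # Patches: anodic face of cell (r,c) sees plane r, cathodic plane r+1.
        cells, planes, faces = [], [], []
        for r in range(ny):
            for c in range(nx):
                for face, p in (("anodic", r), ("cathodic", r + 1)):
                    cells.append(cell_index(r, c))
                    planes.append(p)
                    faces.append(face)
        self.patch_cell = np.array(cells)
        self.patch_plane = np.array(planes)
        self.patch_face = np.array(faces)
        self.n_patches = len(cells)
        self.patch_area = np.full(self.n_patches, geometry.free_patch_area)

        # Gap junctions: 4-neighbour pairs of cells.
        edges = []
        for r in range(ny):
            for c in range(nx):
                if c + 1 < nx:
                    edges.append((cell_index(r, c), cell_index(r, c + 1)))
                if r + 1 < ny:
                    edges.append((cell_index(r, c), cell_index(r + 1, c)))
        self.junction_edges = edges

        n_tot = self.n_free + 2  # + [anode, cathode] pinned columns
        self._i_anode = self.n_free
        self._i_cathode = self.n_free + 1
        M = np.zeros((self.n_free, n_tot))
        G = np.zeros((self.n_free, n_tot))
        cm = self.channels.C_m

        def node_col(p: int) -> int:
            n = plane_node(p)
            if n is not None:
                return n
            return self._i_anode if p == 0 else self._i_cathode

        # Membrane patches: capacitive stamps.
        for k in range(self.n_patches):
            i = self.patch_cell[k]
            jp = node_col(self.patch_plane[k])
            cap = cm * self.patch_area[k]
            M[i, i] += cap
            M[i, jp] -= cap
            if jp < self.n_free:
                M[jp, jp] += cap
                M[jp, i] -= cap

        # Contact membranes between neighbouring cells: series capacitance
        # C_m/2 always; conductance g_Cxn only when connected.
        g_j = params.junction_conductance() * geometry.contact_area
        c_j = 0.5 * cm * geometry.contact_area
        for i, j in edges:
            M[i, i] += c_j
            M[i, j] -= c_j
            M[j, j] += c_j
            M[j, i] -= c_j
            G[i, i] += g_j
            G[i, j] -= g_j
            G[j, j] += g_j
            G[j, i] -= g_j

        # Extracellular slab resistors between consecutive planes.
        g_e = params.sigma_e * geometry.cross_section / geometry.pitch_m
        for p in range(self.n_planes - 1):
            a, b = node_col(p), node_col(p + 1)
            for u, v in ((a, b), (b, a)):
                if u < self.n_free:
                    G[u, u] += g_e
                    G[u, v] -= g_e

        self.patch_plane_cols = np.array([node_col(p) for p in self.patch_plane])
        self.plane_cols = np.array([node_col(p) for p in range(self.n_planes)])
        self.M_ff = M[:, : self.n_free]
        self.M_fp = M[:, self.n_free :]
        self.G_ff = G[:, : self.n_free]
        self.G_fp = G[:, self.n_free :]
        self._lu = lu_factor(self.M_ff)
        self.rest = resting_state(self.channels, params.gating)

    # -- helpers -----------------------------------------------------------

    def patch_um(self, v_free: np.ndarray, v_pin: np.ndarray) -> np.ndarray:
        """Per-patch transmembrane voltage from node potentials."""
        v_all = np.concatenate([v_free, v_pin])
        return v_all[self.patch_cell] - v_all[self.patch_plane_cols]

    def initial_state(self) -> np.ndarray:
        v = np.zeros(self.n_free)
        v[: self.n_cells] = self.rest.Um
        gates = np.tile(
            [self.rest.m, self.rest.h, self.rest.j], (self.n_patches, 1)
        ).T.ravel()
        return np.concatenate([v, gates])


def build_network(geometry: ArrayGeometry, params: ArrayParams) -> CircuitNetwork:
    """Assemble the lumped resistor-capacitor network for the cell array."""
    return CircuitNetwork(geometry, params)


@dataclass
class NetworkSolution:
    """Full solution of one array simulation."""

    t: np.ndarray
    Um: np.ndarray  # (n_patches, nt)
    V_cells: np.ndarray  # (n_cells, nt)
    V_planes: np.ndarray  # (n_planes, nt), including pinned electrodes
    averaged_Um: np.ndarray  # area-weighted mean over free patches
    Um_pulse_end: np.ndarray  # per-patch snapshot at the end of the pulse
    network: CircuitNetwork
    protocol: PulseProtocol

    @property
    def rest(self) -> float:
        return self.network.rest.Um


def _assemble_rhs(net: CircuitNetwork, protocol: PulseProtocol, u_applied: float,
                  gep_mode: str, g_end: np.ndarray | None):
    """RHS of the network ODE for one integration phase.

    ``gep_mode``: "off" (before pulse / no electroporation), "pulse"
    (instantaneous g_ep(|Um|)), "frozen" or "decay" (post-pulse).
    """
    p = net.channels
    gating = net.params.gating
    ep = net.params.ep
    n_free, n_patch = net.n_free, net.n_patches
    area = net.patch_area
    cell_rows = net.patch_cell
    plane_cols = net.patch_plane_cols
    plane_free = plane_cols < n_free

    def rhs(t, y):
        v_f = y[:n_free]
        gates = y[n_free:].reshape(3, n_patch)
        m = np.clip(gates[0], 0.0, 1.0)
        h = np.clip(gates[1], 0.0, 1.0)
        j = np.clip(gates[2], 0.0, 1.0)
        w = float(protocol.window(t))
        dw = float(protocol.window_deriv(t))
        v_pin = np.array([u_applied * w, 0.0])
        dv_pin = np.array([u_applied * dw, 0.0])
        v_all = np.concatenate([v_f, v_pin])
        um = v_all[cell_rows] - v_all[plane_cols]

        if gep_mode == "pulse" and ep is not None:
            gep = ep.g_pulse(um)
        elif gep_mode == "frozen" and g_end is not None:
            gep = g_end
        elif gep_mode == "decay" and g_end is not None and ep is not None:
            gep = g_end * np.exp(-(t - protocol.t_end) / ep.tau_r)
        else:
            gep = 0.0

        j_ion = (
            p.g_Na * m**3 * h * j * (um - p.E_Na)
            + p.g_K * gating.n_inf(um) * (um - p.E_K)
            + p.g_L * (um - p.E_L)
            + gep * um
        ) * area

        s = np.zeros(n_free)
        np.add.at(s, cell_rows, j_ion)
        np.subtract.at(s, plane_cols[plane_free], j_ion[plane_free])

        b = -(net.G_ff @ v_f) - (net.G_fp @ v_pin) - (net.M_fp @ dv_pin) - s
        dv = lu_solve(net._lu, b)

        dgates = np.empty((3, n_patch))
        if hasattr(gating, "rates_mhj"):
            m_inf, tau_m, h_inf, tau_h, j_inf, tau_j = gating.rates_mhj(um)
            dgates[0] = (m_inf - m) / tau_m
            dgates[1] = (h_inf - h) / tau_h
            dgates[2] = (j_inf - j) / tau_j
        else:
            for gi, (name, val) in enumerate(zip("mhj", (m, h, j))):
                dgates[gi] = (gating.y_inf(name, um) - val) / gating.tau_y(name, um)
        return np.concatenate([dv, dgates.ravel()])

    return rhs


def simulate_array(
    network: CircuitNetwork,
    protocol: PulseProtocol,
    duration: float = 2.88,
    dt: float = 0.036,
    blowup_limit: float = 1.5,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> NetworkSolution:
    """Integrate the array network through one pulse.

    ``protocol.amplitude`` is the applied field (V/m) across the network
    extent; the anode plane is pinned to E * L during the (smoothed) pulse.
    Output is sampled on the ``dt`` grid (default: the 36 ms acquisition
    interval).
    """
    net = network
    u_applied = protocol.amplitude * net.geometry.length
    t_eval = np.arange(0.0, duration + dt / 2, dt)
    t_eval = t_eval[t_eval <= duration]

    # End-of-pulse state is taken just before the smoothed falling edge
    # (where the applied field is still at full amplitude); the frozen
    # electroporation conductance is evaluated there, since pores created at
    # the peak voltage do not reseal on the microsecond edge timescale.
    t_snap = protocol.t_end - 5.0 * max(protocol.smoothing, 1e-7)
    if t_snap <= protocol.t_start:
        t_snap = protocol.t_end
    cuts = sorted(
        {0.0, duration}
        | {
            tc
            for tc in (protocol.t_start, t_snap, protocol.t_end)
            if 0.0 < tc < duration
        }
    )
    y = network.initial_state()
    g_end: np.ndarray | None = None
    um_pulse_end: np.ndarray | None = None
    ts, ys = [], []

    def blowup(t, yv):
        w = float(protocol.window(t))
        v_pin = np.array([u_applied * w, 0.0])
        um = net.patch_um(yv[: net.n_free], v_pin)
        return blowup_limit - np.max(np.abs(um))

    blowup.terminal = True

    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        if net.params.ep is None:
            mode = "off"
        elif mid < protocol.t_start:
            mode = "off"
        elif mid <= t_snap:
            mode = "pulse"
        elif mid <= protocol.t_end:
            mode = "frozen"  # falling edge: pores persist at their peak value
        else:
            mode = "decay" if net.params.ep.recover else "frozen"
        rhs = _assemble_rhs(net, protocol, u_applied, mode, g_end)
        in_pulse = protocol.t_start - 1e-12 <= mid <= protocol.t_end + 1e-12
        pts = np.unique(np.concatenate([t_eval[(t_eval >= a) & (t_eval < b)], [b]]))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=pts,
            rtol=rtol,
            atol=atol,
            events=blowup,
            max_step=max(protocol.smoothing, 2e-6) if in_pulse else np.inf,
            first_step=1e-7 if in_pulse else None,
        )
        if sol.status == 1:
            raise SimulationBlowUp(
                f"node potential exceeded {blowup_limit} V during array simulation"
            )
        if not sol.success:
            raise RuntimeError(f"array integration failed: {sol.message}")
        y = sol.y[:, -1].copy()
        n_out = len(pts) - (1 if (pts[-1] == b and b not in t_eval) else 0)
        ts.append(sol.t[:n_out])
        ys.append(sol.y[:, :n_out])
        if abs(b - t_snap) < 1e-15:
            w = float(protocol.window(b))
            v_pin = np.array([u_applied * w, 0.0])
            um_end = net.patch_um(y[: net.n_free], v_pin)
            um_pulse_end = um_end
            if net.params.ep is not None:
                g_end = np.asarray(net.params.ep.g_pulse(um_end), dtype=float)

    t = np.concatenate(ts)
    yy = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    t = t[keep]
    yy = yy[:, keep]

    # Reconstruct per-patch Um and plane potentials on the output grid.
    w = protocol.window(t)
    v_pin = np.vstack([u_applied * w, np.zeros_like(t)])
    v_free = yy[: net.n_free]
    v_all = np.vstack([v_free, v_pin])
    plane_cols = net.plane_cols
    um = v_all[net.patch_cell] - v_all[net.patch_plane_cols]
    avg = np.average(um, axis=0, weights=net.patch_area)
    if um_pulse_end is None:
        um_pulse_end = um[:, -1] * np.nan
    return NetworkSolution(
        t=t,
        Um=um,
        V_cells=v_free[: net.n_cells],
        V_planes=v_all[plane_cols],
        averaged_Um=avg,
        Um_pulse_end=um_pulse_end,
        network=net,
        protocol=protocol,
    )


def response_class(solution: NetworkSolution) -> ta.ResponseClass:
    """Classify the area-averaged voltage trace with the optical-trace rule."""
    resp = ta.from_membrane_trace(
        solution.t,
        solution.averaged_Um,
        rest=solution.rest,
        pulse_time=solution.protocol.t_start,
    )
    peaks = ta.detect_peaks(resp)
    params = ta.extract_params(resp, peaks)
    return ta.classify(params)


#: Averaged-voltage level (V) above which a response contains a regenerative
#: sodium upstroke.  The electrotonic (passive) response of the array stays
#: tens of millivolts below this; only an all-or-none action-potential
#: upstroke carries the area-averaged voltage past it.
UPSTROKE_LEVEL = -0.020


def threshold_sweep(
    network: CircuitNetwork,
    fields_v_per_cm: Sequence[float],
    pulse_start: float = 0.36,
    duration: float = 2.88,
    dt: float = 0.036,
    stop_at_first: bool = True,
    criterion: str = "classify",
) -> tuple[float | None, pd.DataFrame]:
    """Smallest applied field (V/cm) at which the averaged response fires.

    Sweeps the sorted field list with one single-pulse simulation per field.
    Two detection criteria are available:

    * ``"classify"``: the four-class optical-trace rule applied to the
      area-averaged trace; an AP is a single_AP or multiple_APs class.
    * ``"upstroke"``: the averaged voltage crosses :data:`UPSTROKE_LEVEL`
      after the pulse, i.e. the trace contains a full regenerative sodium
      upstroke.  With electroporation enabled, high-field responses fire an
      action potential whose recovery is then held back by the frozen
      membrane conductance; the overall trace morphology is then a sustained
      depolarization even though the cells fired, and this criterion still
      registers the AP.

    Returns (threshold or None, per-field table with both readouts).  With
    ``stop_at_first`` the sweep stops once the criterion is met (the fields
    are ascending).
    """
    if list(fields_v_per_cm) != sorted(fields_v_per_cm):
        raise ValueError("fields must be sorted ascending")
    if criterion not in ("classify", "upstroke"):
        raise ValueError("criterion must be 'classify' or 'upstroke'")
    rows = []
    threshold = None
    for f in fields_v_per_cm:
        protocol = PulseProtocol(amplitude=float(f) * 100.0, t_start=pulse_start)
        sol = simulate_array(network, protocol, duration=duration, dt=dt)
        cls = response_class(sol)
        post = sol.t > protocol.t_end
        upstroke = bool(np.max(sol.averaged_Um[post]) > UPSTROKE_LEVEL)
        rows.append(
            {
                "field_V_per_cm": float(f),
                "response_class": cls.value,
                "upstroke": upstroke,
            }
        )
        fired = (
            cls in (ta.ResponseClass.single_AP, ta.ResponseClass.multiple_APs)
            if criterion == "classify"
            else upstroke
        )
        if fired:
            threshold = float(f)
            if stop_at_first:
                break
    return threshold, pd.DataFrame(rows)


def end_of_pulse_tmv_profile(solution: NetworkSolution) -> pd.DataFrame:
    """Per-patch induced transmembrane voltage at the end of the pulse."""
    net = solution.network
    nx = net.geometry.n_cells_x
    return pd.DataFrame(
        {
            "cell_x": net.patch_cell % nx,
            "cell_y": net.patch_cell // nx,
            "face": net.patch_face,
            "Um_V": solution.Um_pulse_end,
        }
    )
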