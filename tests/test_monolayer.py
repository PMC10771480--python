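"""Monolayer monodomain model: field solve, source terms, PDE consistency."""

import numpy as np
import pytest
from scipy.integrate import quad

from excitep.membrane import PulseProtocol, simulate_patch
from excitep.monolayer import (
    FieldMap,
    MonolayerParams,
    SpatioTemporalSolution,
    WellGeometry,
    charging_time,
    conduction_velocity,
    gep_monolayer,
    simulate_monolayer,
    solve_field,
    stim_charge,
    stim_current,
)

PROTO = PulseProtocol(amplitude=1.0, t_start=0.36)


@pytest.fixture(scope="module")
def field_map():
    return solve_field(WellGeometry())


class TestSolveField:
    def test_parallel_plate_limit_uniform(self):
        """Electrode strips spanning the full well width give E/(U/d) = 1."""
        geo = WellGeometry(well_x=0.006, wire_length=0.006, grid_spacing=2e-4)
        fm = solve_field(geo)
        ny, nx = fm.E_norm.shape
        centre = fm.E_norm[ny // 2, 2 : nx - 2]
        assert np.all(np.abs(centre - 1.0) < 0.01)

    def test_wire_midpoint_near_nominal(self, field_map):
        assert abs(field_map.midpoint_value() - 1.0) < 0.15

    def test_field_enhanced_along_electrode_edges(self, field_map):
        """The field peaks adjacent to the wires (strongest at their ends),
        above the value at the inter-electrode midpoint."""
        geo = field_map.geometry
        y, x = geo.grids()
        iy, ix = np.unravel_index(np.argmax(field_map.E_norm),
                                  field_map.E_norm.shape)
        yc = geo.well_y / 2
        wire_centreline = geo.electrode_gap / 2 + geo.wire_diameter / 2
        assert abs(abs(y[iy] - yc) - wire_centreline) < 1.0e-3  # next to a wire
        assert field_map.E_norm[iy, ix] > 1.05 * field_map.midpoint_value()

    def test_boundary_field_below_gap_field(self, field_map):
        ny, nx = field_map.E_norm.shape
        assert field_map.E_norm[0, 0] <= field_map.midpoint_value()

    def test_grid_must_resolve_wires(self):
        with pytest.raises(ValueError):
            WellGeometry(grid_spacing=4e-4)


class TestStimCurrent:
    PARAMS = MonolayerParams()

    def test_zero_field(self):
        assert stim_current(0.0, 0.4, self.PARAMS, PROTO) == pytest.approx(0.0)

    def test_late_pulse_limit_is_leak_term(self, channels):
        t = PROTO.t_start + 50e-6  # >> tau_chg, inside the pulse
        j = stim_current(1e4, t, self.PARAMS, PROTO)
        expected = -0.375 * self.PARAMS.R_cell * 1e4 * channels.g_L
        assert j == pytest.approx(expected, rel=1e-3)

    def test_onset_limit_is_capacitive_term(self, channels):
        t = PROTO.t_start + 1e-12  # << tau_chg
        j = stim_current(1e4, t, self.PARAMS, PROTO)
        expected = (
            -0.375 * self.PARAMS.R_cell * 1e4 * channels.C_m / self.PARAMS.tau_chg
        )
        # the smoothed pulse edge is still rising at t_start
        assert j / expected == pytest.approx(PROTO.window(t), rel=1e-4)

    def test_charge_integral_matches_quadrature(self):
        """stim_charge equals the numerical integral of the current."""
        hard = PulseProtocol(amplitude=1.0, t_start=0.36, smoothing=0.0)
        t1, t2 = hard.t_start, hard.t_start + 2e-5
        num, _ = quad(
            lambda t: stim_current(1e4, t, self.PARAMS, hard), t1, t2,
            points=[t1 + self.PARAMS.tau_chg], limit=200,
        )
        ana = stim_charge(1e4, t1, t2, self.PARAMS, hard)
        assert ana == pytest.approx(num, rel=1e-6)

    def test_charging_time_sub_microsecond(self):
        assert 1e-8 < charging_time() < 1e-6


class TestGepMonolayer:
    PARAMS = MonolayerParams()

    def test_vanishing_field_limit(self):
        g = gep_monolayer(1e-6, 0.4, self.PARAMS, PROTO)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_unit_argument_value(self):
        """u = 1.5*R*E*beta = 1 gives alpha*(e - 2)."""
        ep = self.PARAMS.ep
        E = 1.0 / (1.5 * self.PARAMS.R_cell * ep.beta)
        g = gep_monolayer(E, 0.4, self.PARAMS, PROTO)
        assert g == pytest.approx(ep.alpha * (np.e - 2.0), rel=1e-9)

    def test_strictly_increasing_in_field(self):
        E = np.linspace(1.0, 4e4, 100)
        g = gep_monolayer(E, 0.4, self.PARAMS, PROTO)
        assert np.all(np.diff(g) > 0)

    def test_off_before_pulse(self):
        assert np.all(gep_monolayer(1e4, 0.1, self.PARAMS, PROTO) == 0.0)


def test_gcxn_invariant():
    p = MonolayerParams(g_Cxn=123.0, R_cell=9e-6)
    assert p.G_Cxn == 123.0 * (2 * 9e-6) ** 2


class TestPatchEquivalence:
    def test_uncoupled_uniform_reduces_to_patch(self, channels, gating):
        """G_Cxn = 0 with uniform field: every node follows the space-clamped
        patch driven by J_stim, to < 0.1 mV."""
        geo = WellGeometry(well_x=0.002, well_y=0.0068, wire_length=0.001,
                           grid_spacing=2e-4)
        E_app = 3000.0  # 30 V/cm nominal, comfortably subthreshold
        fm = FieldMap(E_norm=np.ones(geo.shape), geometry=geo,
                      potential=np.zeros(geo.shape))
        params = MonolayerParams(g_Cxn=0.0, channels=channels, gating=gating,
                                 ep=None)
        proto = PulseProtocol(amplitude=E_app, t_start=0.05, smoothing=0.0)
        sol = simulate_monolayer(
            geo, params, proto, duration=0.5, dt_out=0.01,
            dt_macro=2.5e-4, dt_reaction=5e-6, field_map=fm,
        )
        node_trace = sol.Um[:, 1, 1]

        drive = lambda t: -stim_current(E_app, t, params, proto)
        patch = simulate_patch(
            channels, gating, drive=drive, duration=0.5, dt=0.01,
            drive_breaks=(proto.t_start, proto.t_end),
        )
        # compare on the common output grid
        ref = np.interp(sol.t, patch.t, patch.Um)
        assert np.max(np.abs(node_trace - ref)) < 1e-4

    def test_all_nodes_identical_without_coupling(self, channels, gating):
        geo = WellGeometry(well_x=0.002, well_y=0.0068, wire_length=0.001,
                           grid_spacing=2e-4)
        fm = FieldMap(E_norm=np.ones(geo.shape), geometry=geo,
                      potential=np.zeros(geo.shape))
        params = MonolayerParams(g_Cxn=0.0, channels=channels, gating=gating,
                                 ep=None)
        sol = simulate_monolayer(
            geo, params, PulseProtocol(amplitude=3000.0, t_start=0.02),
            duration=0.1, dt_out=0.02, field_map=fm,
        )
        spread = sol.Um.max(axis=(1, 2)) - sol.Um.min(axis=(1, 2))
        assert np.max(spread) < 1e-9


def test_grid_refinement_keeps_roi_peak_time(channels, gating):
    """Halving the grid spacing moves the ROI peak by < one 36 ms frame."""
    times = {}
    for h in (2e-4, 1e-4):
        geo = WellGeometry(well_x=0.002, well_y=0.0068, wire_length=0.001,
                           grid_spacing=h)
        fm = FieldMap(E_norm=np.ones(geo.shape), geometry=geo,
                      potential=np.zeros(geo.shape))
        params = MonolayerParams(channels=channels, gating=gating)
        sol = simulate_monolayer(
            geo, params, PulseProtocol(amplitude=6000.0, t_start=0.1),
            duration=0.6, field_map=fm,
        )
        times[h] = sol.t[np.argmax(sol.roi_trace)]
    assert abs(times[2e-4] - times[1e-4]) < 0.036


class TestConductionVelocity:
    def _solution(self, act_map, geo=None):
        geo = geo or WellGeometry()
        fm = FieldMap(E_norm=np.ones(geo.shape), geometry=geo,
                      potential=np.zeros(geo.shape))
        nt = 2
        ny, nx = geo.shape
        return SpatioTemporalSolution(
            t=np.zeros(nt), Um=np.zeros((nt, ny, nx)), activation_map=act_map,
            roi_trace=np.zeros(nt), roi_mask=np.zeros((ny, nx), bool),
            field=fm, params=MonolayerParams(), protocol=PROTO, rest=-0.07,
            activation_level=-0.02,
        )

    def test_recovers_imposed_planar_speed(self):
        geo = WellGeometry()
        y, x = geo.grids()
        v_true = 0.034
        act = np.tile(((geo.well_y / 2) - y)[:, None] / v_true, (1, len(x)))
        act[act < 0] = np.abs(act[act < 0])
        sol = self._solution(act, geo)
        v = conduction_velocity(sol)
        assert v == pytest.approx(v_true, rel=0.05)

    def test_simultaneous_activation_flagged_infinite(self):
        geo = WellGeometry()
        act = np.full(geo.shape, 0.123)
        assert conduction_velocity(self._solution(act, geo)) == float("inf")

    def test_no_activation_undefined(self):
        geo = WellGeometry()
        act = np.full(geo.shape, np.nan)
        assert conduction_velocity(self._solution(act, geo)) is None
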