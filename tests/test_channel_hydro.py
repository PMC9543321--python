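import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from streampcb.channel_hydro import (
    CFLError, Network, Reach, manning_flow, route_flow, simulate_tracer,
    solve_depth)


@pytest.fixture(scope="module")
def two_reach_network():
    cb = Reach("cb", 0.0, 0.8, width=1.83, slope=2.0e-4, roughness=0.055)
    rc = Reach("rc", 0.8, 3.0, width=4.57, slope=2.9e-4, roughness=0.045)
    return Network([cb, rc], {"cb": 0.0, "rc": 0.8})


class TestSolveDepth:
    def test_zero_flow_gives_zero_depth(self):
        r = Reach("r", 0, 1, width=10, slope=1e-3, roughness=0.03)
        assert solve_depth(0.0, r) == 0.0

    def test_known_inversion(self):
        # forward Manning at h=1 m for w=10, n=0.030, S=0.001 gives 9.335 m3/s
        r = Reach("r", 0, 1, width=10, slope=1e-3, roughness=0.030)
        assert solve_depth(9.335, r) == pytest.approx(1.0, rel=1e-3)

    def test_headwater_base_flow_depth(self):
        # default headwater geometry (~6 ft wide) runs ~0.6 ft deep at base flow
        cb = Reach("cb", 0.0, 0.8, width=1.83, slope=2.0e-4, roughness=0.055)
        depth_ft = solve_depth(0.024, cb) / 0.3048
        assert depth_ft == pytest.approx(0.6, abs=0.05)

    def test_residual_satisfies_rating(self):
        r = Reach("r", 0, 1, width=3.0, slope=5e-4, roughness=0.04)
        for q in (0.01, 0.5, 20.0):
            h = solve_depth(q, r)
            assert abs(manning_flow(h, r) - q) <= 1e-8 * q

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(h=st.floats(0.01, 5.0), w=st.floats(0.5, 30.0),
           s=st.floats(1e-5, 1e-2), n=st.floats(0.02, 0.1))
    def test_round_trip_property(self, h, w, s, n):
        r = Reach("r", 0, 1, width=w, slope=s, roughness=n)
        assert solve_depth(manning_flow(h, r), r) == pytest.approx(h, rel=1e-6)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            Reach("bad", 0, 1, width=-1, slope=1e-3, roughness=0.03)
        with pytest.raises(ValueError):
            Reach("bad", 1, 0, width=1, slope=1e-3, roughness=0.03)


class TestRouteFlow:
    def test_single_reach_conservation(self):
        net = Network([Reach("r", 0, 1, width=2, slope=1e-3, roughness=0.03)],
                      {"in": 0.0})
        hydro = route_flow(net, pd.DataFrame({"in": [1.0] * 5}))
        assert np.allclose(hydro.flow, 1.0)
        assert np.allclose(hydro.velocity * hydro.area, hydro.flow)

    def test_confluence_flows_add(self, two_reach_network):
        flows = pd.DataFrame({"cb": [0.05] * 3, "rc": [0.35] * 3})
        hydro = route_flow(two_reach_network, flows)
        rc_cell = two_reach_network.cell_of_mile(1.5)
        assert np.allclose(hydro.flow[:, rc_cell], 0.40)

    def test_storm_scaling(self, two_reach_network):
        base = 0.02
        flows = pd.DataFrame({"cb": [base, base * 1000], "rc": [0.0, 0.0]})
        hydro = route_flow(two_reach_network, flows)
        cb_cell = two_reach_network.cell_of_mile(0.5)
        assert hydro.flow[1, cb_cell] == pytest.approx(1000 * hydro.flow[0, cb_cell])

    def test_negative_flow_rejected(self, two_reach_network):
        flows = pd.DataFrame({"cb": [-0.1], "rc": [0.3]})
        with pytest.raises(ValueError):
            route_flow(two_reach_network, flows)


class TestTracer:
    def test_plug_flow_arrival_time(self):
        # dispersion ~ 0, steady flow: peak reaches distance L after ~L/u
        reach = Reach("r", 0, 1.0, width=2.0, slope=1e-3, roughness=0.03,
                      n_cells=40, dispersion=1e-6)
        net = Network([reach], {"in": 0.0})
        q = 0.5
        hydro = route_flow(net, pd.DataFrame({"in": [q] * 10}))
        res = simulate_tracer(net, hydro, release_mass=10.0, release_mile=0.0)
        u = hydro.velocity[0, 0]
        target_cell = net.cell_of_mile(0.5)
        dist = (net.mile[target_cell] - net.mile[0]) * 1609.344
        expected_day = dist / u / 86400.0
        peak_day = int(np.argmax(res["conc_g_per_m3"][:, target_cell]))
        assert abs(peak_day - expected_day) <= 1.0

    def test_mass_conserved(self, two_reach_network):
        flows = pd.DataFrame({"cb": [0.05] * 20, "rc": [0.35] * 20})
        hydro = route_flow(two_reach_network, flows)
        res = simulate_tracer(two_reach_network, hydro, release_mass=50.0,
                              release_mile=0.2)
        assert res["mass_balance_error"] <= 0.005

    def test_cfl_violation_reports_required_step(self, two_reach_network):
        flows = pd.DataFrame({"cb": [0.05] * 5, "rc": [0.35] * 5})
        hydro = route_flow(two_reach_network, flows)
        with pytest.raises(CFLError) as err:
            simulate_tracer(two_reach_network, hydro, 1.0, 0.0, dt=86400.0)
        assert err.value.dt_required < 86400.0

    def test_confluence_dilution_factor(self, two_reach_network):
        # flow-weighted mixing: 0.05 m3/s at 500 ng/L joins 0.35 m3/s clean
        q_cb, q_rc, c0 = 0.05, 0.35, 500.0
        mixed = c0 * q_cb / (q_cb + q_rc)
        assert mixed == pytest.approx(62.5)
        assert 5 <= (q_cb + q_rc) / q_cb <= 10


def test_network_domain_length(two_reach_network):
    assert two_reach_network.total_miles == pytest.approx(3.0)
    with pytest.raises(ValueError):
        two_reach_network.cell_of_mile(3.5)
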