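import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from streampcb.channel_hydro import HydroState, Network, Reach, route_flow
from streampcb.fate_transport import (
    BedState, FateParams, dissolved_fraction, simulate)
from streampcb.scenario_engine import build_run
from streampcb import fate_transport


def closed_cell(depth=0.5, n_days=2):
    net = Network([Reach("c", 0, 0.1, width=1.0, slope=1e-4, roughness=0.03,
                         n_cells=1)], {})
    zeros = np.zeros((n_days, 1))
    h = np.full((n_days, 1), depth)
    hydro = HydroState(times=np.arange(n_days), flow=zeros, depth=h,
                       velocity=zeros, area=1.0 * h, lateral=zeros)
    hydro.shear = zeros
    return net, hydro


class TestDissolvedFraction:
    def test_no_solids_fully_dissolved(self):
        assert dissolved_fraction(0.0, 1e5) == 1.0

    def test_half_dissolved_when_kp_tss_is_one(self):
        # Kp=1e5 L/kg * 10 mg/L = 1e5 * 1e-5 kg/L = 1
        assert dissolved_fraction(10.0, 1e5) == pytest.approx(0.5)

    def test_strong_sorption_limit(self):
        assert dissolved_fraction(10.0, 1e12) < 1e-5

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tss=st.floats(0, 1000), kp1=st.floats(0, 1e7), kp2=st.floats(0, 1e7))
    def test_monotone_in_kp(self, tss, kp1, kp2):
        lo, hi = sorted([kp1, kp2])
        assert dissolved_fraction(tss, hi) <= dissolved_fraction(tss, lo) + 1e-15


class TestSimulate:
    def test_dilution_only_steady_state(self):
        # all loss terms zero: constant load W into steady flow Q -> C = W/Q
        reach = Reach("r", 0, 1.0, width=2.0, slope=1e-3, roughness=0.03)
        net = Network([reach], {"in": 0.0})
        q = 0.5
        hydro = route_flow(net, pd.DataFrame({"in": [q] * 40}))
        params = FateParams(settling_v=0, volat_v=0, porewater_v=0,
                            erodibility=0, burial_v=0, bioturb_d=0)
        w_gd = 43.2  # g/day -> W/Q = 43.2/0.5/0.0864 = 1000 ng/L
        loads = {"src": {"cell": 0, "load_gd": np.full(40, w_gd)}}
        res = simulate(net, hydro, loads, params, BedState.uniform(net, 0.0))
        expected = w_gd / (q * 0.0864)
        assert res["conc_water"][-1, -1] == pytest.approx(expected, rel=1e-3)

    def test_volatilization_only_exponential(self):
        # closed well-mixed cell, f_d=1, k_v=1 m/d, h=0.5 m -> C(1d)/C0 = e^-2
        net, hydro = closed_cell()
        params = FateParams(settling_v=0, volat_v=1.0, porewater_v=0,
                            erodibility=0, burial_v=0, bioturb_d=0)
        res = simulate(net, hydro, {}, params, BedState.uniform(net, 0.0),
                       initial_conc=[100.0], n_days=1)
        assert res["water"].conc[0] / 100.0 == pytest.approx(np.exp(-2), rel=1e-6)

    def test_year_budget_closes(self, site):
        run = build_run(site)
        res = simulate(run["network"], run["hydro"], run["loads"],
                       run["params"], run["bed0"], flows_df=run["flows"],
                       tss_df=run["tss"], n_days=365)
        assert res["budget"]["closure_error"] <= 0.005

    def test_headwater_budget_shares(self, site):
        # settling removes <1% and volatilization a few percent of the annual
        # load delivered to the headwater stream (order-of-magnitude check)
        run = build_run(site)
        res = simulate(run["network"], run["hydro"], run["loads"],
                       run["params"], run["bed0"], flows_df=run["flows"],
                       tss_df=run["tss"], n_days=365)
        cb = run["network"].mile < 0.8
        total_load = sum(l["load_gd"][:365].sum() for l in run["loads"].values())
        settle_share = res["sinks"]["settled"][cb].sum() / total_load
        volat_share = res["sinks"]["volatilized"][cb].sum() / total_load
        assert settle_share < 0.01
        assert 0.005 < volat_share < 0.10

    def test_storm_pulse_flows_through(self, site):
        # storm loads export downstream rather than depositing in the
        # headwater stream (short residence time)
        run = build_run(site)
        res = simulate(run["network"], run["hydro"], run["loads"],
                       run["params"], run["bed0"], flows_df=run["flows"],
                       tss_df=run["tss"], n_days=365)
        cb = run["network"].mile < 0.8
        deposited = res["sinks"]["settled"][cb].sum()
        exported = res["budget"]["export"]
        assert deposited < 0.05 * exported


class TestSuperposition:
    def test_single_source_runs_sum_to_combined(self, site):
        run = build_run(site)
        app = fate_transport.apportion_sources(
            run["network"], run["hydro"], run["loads"], run["params"],
            run["bed0"], flows_df=run["flows"], tss_df=run["tss"], n_days=90)
        combined = app["combined"]["conc_water"]
        total = sum(r["conc_water"] for r in app["runs"].values())
        scale = np.max(np.abs(combined))
        assert np.max(np.abs(total - combined)) <= 1e-6 * scale
        active = app["fraction_water_sum"] > 0
        assert np.allclose(app["fraction_water_sum"][active], 1.0, atol=1e-6)

    def test_doubling_one_source_doubles_contribution(self, site):
        run = build_run(site)
        kw = dict(flows_df=run["flows"], tss_df=run["tss"], n_days=60)
        zero_bed = run["bed0"].copy()
        zero_bed.conc_active *= 0.0
        zero_bed.conc_deep *= 0.0
        one = simulate(run["network"], run["hydro"],
                       {"nsb": run["loads"]["nsb"]}, run["params"], zero_bed, **kw)
        doubled_load = dict(run["loads"]["nsb"])
        doubled_load["load_gd"] = run["loads"]["nsb"]["load_gd"] * 2.0
        two = simulate(run["network"], run["hydro"], {"nsb": doubled_load},
                       run["params"], zero_bed, **kw)
        assert np.allclose(two["conc_water"], 2 * one["conc_water"], rtol=1e-9)
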