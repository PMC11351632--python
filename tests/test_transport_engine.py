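"""Transport engine: initialization, stepping rules, outcome contracts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oviductsim.flow_mechanics import CiliaField, FlowField, PeristalsisWave
from oviductsim.oocyte_model import OocyteModel
from oviductsim.rng import CounterRNG
from oviductsim.transport_engine import (AgentState, EngineParams,
                                         SimulationDesign, init_positions,
                                         run, step_oocyte, step_sperm)
from oviductsim.tube_geometry import build_tube


def small_design(**kw):
    base = dict(age_group="20s", n_sperm=200, n_oocyte_runs=50, seed=3)
    base.update(kw)
    return SimulationDesign(**base)


def zero_flow(tube):
    return FlowField(tube, waves=[PeristalsisWave(amplitude_p=0.0)],
                     cilia=CiliaField(density=0.0))


class TestInitPositions:
    def test_sperm_within_intramural(self, tube20):
        d = small_design(n_sperm=500)
        pos = init_positions(d, tube20)["sperm"]
        intr = tube20.region("intramural")
        assert np.all((pos["s"] >= intr.start_s) & (pos["s"] <= intr.end_s))
        assert np.all((pos["r_frac"] >= 0) & (pos["r_frac"] < 1))

    def test_oocytes_within_infundibulum(self, tube20):
        d = small_design(n_oocyte_runs=200)
        pos = init_positions(d, tube20)["oocyte"]
        inf = tube20.region("infundibulum")
        assert np.all((pos["s"] >= inf.start_s) & (pos["s"] <= inf.end_s))

    def test_same_seed_identical_positions(self, tube20):
        d = small_design()
        a = init_positions(d, tube20)
        b = init_positions(d, tube20)
        for kind in ("sperm", "oocyte"):
            for key in ("s", "r_frac", "theta"):
                np.testing.assert_array_equal(a[kind][key], b[kind][key])


class TestRunContracts:
    def test_determinism_bitwise(self, tube20):
        d = small_design(n_sperm=150, n_oocyte_runs=30)
        r1 = run(d, tube=tube20)
        r2 = run(d, tube=tube20)
        pd.testing.assert_frame_equal(r1.sperm, r2.sperm)
        pd.testing.assert_frame_equal(r1.oocyte, r2.oocyte)

    def test_seed_changes_outcomes(self, tube20):
        d1 = small_design(n_sperm=150, n_oocyte_runs=0)
        d2 = replace(d1, seed=d1.seed + 1)
        r1, r2 = run(d1, tube=tube20), run(d2, tube=tube20)
        assert not r1.sperm["s"].equals(r2.sperm["s"])

    def test_agent_conservation(self, tube20_endo):
        d = small_design(n_sperm=300, n_oocyte_runs=40,
                         with_endometriosis=True)
        res = run(d, tube=tube20_endo)
        for kind, n in (("sperm", 300), ("oocyte", 40)):
            c = res.counts(kind)
            assert sum(c.values()) == n
            assert set(c) == {"swimming", "stuck", "reached_goal"}

    def test_zero_duration_no_outcomes(self, tube20):
        d = small_design(duration_h=0.0)
        res = run(d, tube=tube20)
        assert (res.sperm["status"] == "swimming").all()
        assert (res.oocyte["status"] == "swimming").all()

    def test_terminal_states_have_final_times(self, tube20_endo):
        d = small_design(n_sperm=200, n_oocyte_runs=30, with_endometriosis=True)
        res = run(d, tube=tube20_endo)
        for kind in ("sperm", "oocyte"):
            df = getattr(res, kind)
            done = df[df["status"] != "swimming"]
            assert (done["t_final"] <= d.duration_h).all()
            stuck = df[df["status"] == "stuck"]
            assert (stuck["stuck_at"] >= 0).all()

    def test_design_tube_mismatch_rejected(self, tube20):
        with pytest.raises(ValueError):
            run(small_design(age_group="30s"), tube=tube20)
        with pytest.raises(ValueError):
            run(small_design(with_endometriosis=True), tube=tube20)


class TestSpermBehaviour:
    def test_pure_self_propulsion_increases_s(self, tube20):
        """No flow, no noise, mid-lumen: arclength strictly increases."""
        flow = zero_flow(tube20)
        params = replace(EngineParams(), sigma_r_sperm=0.0,
                         sigma_theta_sperm=0.0,
                         stick_rate_sperm={"20s": 0.0, "30s": 0.0, "40s": 0.0})
        rng = CounterRNG(1, 1)
        agent = AgentState(kind="sperm", s=5.0, r_frac=0.3, theta=0.0,
                           mode="normal", status="swimming", stuck_at=None,
                           t_final=np.nan)
        for k in range(200):
            nxt = step_sperm(agent, tube20, flow, params, dt=10.0, rng=rng,
                             step_index=k)
            if nxt.status == "reached_goal":
                break
            assert nxt.s > agent.s
            agent = nxt

    def test_hyperactivation_on_ampulla_entry(self, tube20):
        d = small_design(n_sperm=200, n_oocyte_runs=0)
        res = run(d, tube=tube20)
        reached = res.sperm[res.sperm["status"] == "reached_goal"]
        assert (reached["mode"] == "hyperactivated").all()
        stuck_early = res.sperm[(res.sperm["status"] == "stuck")
                                & (res.sperm["s"] < tube20.ampulla.start_s)]
        assert (stuck_early["mode"] == "normal").all()

    def test_lesion_nullification_oracle(self):
        """Zero-protrusion lesions with unit hazard multiplier and a capture
        band equal to the wall band are mechanically invisible: outcomes
        match the normal tube bitwise at the same seed."""
        normal = build_tube("20s")
        hollow = build_tube("20s", with_endometriosis=True,
                            overrides={"protrusion_fraction": 0.0})
        params = replace(EngineParams(),
                         capture_band=EngineParams().wall_band,
                         lesion_mult_sperm={"20s": 1.0, "30s": 1.0, "40s": 1.0},
                         lesion_mult_oocyte=1.0)
        d_n = small_design(n_sperm=300, n_oocyte_runs=40)
        d_e = replace(d_n, with_endometriosis=True)
        r_n = run(d_n, tube=normal, params=params)
        r_e = run(d_e, tube=hollow, params=params)
        pd.testing.assert_frame_equal(
            r_n.sperm.drop(columns="stuck_at"),
            r_e.sperm.drop(columns="stuck_at"))
        pd.testing.assert_frame_equal(
            r_n.oocyte.drop(columns="stuck_at"),
            r_e.oocyte.drop(columns="stuck_at"))

    def test_monotone_in_sticking_rate(self, tube20):
        base = EngineParams()
        pcts = []
        for scale in (0.5, 1.0, 4.0):
            params = replace(base, stick_rate_sperm={
                k: v * scale for k, v in base.stick_rate_sperm.items()})
            d = small_design(n_sperm=400, n_oocyte_runs=0)
            pcts.append(run(d, tube=tube20, params=params).pct_reached("sperm"))
        assert pcts[0] > pcts[1] > pcts[2]

    def test_monotone_in_age(self):
        pcts = []
        for age in ("20s", "30s", "40s"):
            vals = [run(SimulationDesign(age_group=age, n_sperm=400,
                                         n_oocyte_runs=0, seed=s)).pct_reached("sperm")
                    for s in (11, 12)]
            pcts.append(np.mean(vals))
        assert pcts[0] > pcts[1] > pcts[2]

    def test_monotone_in_lesion_count(self):
        pcts = []
        for n in (0, 5, 10):
            d = SimulationDesign(age_group="30s", with_endometriosis=n > 0,
                                 lesion_count=max(n, 5) if n else 5,
                                 n_sperm=400, n_oocyte_runs=0, seed=21)
            tube = build_tube("30s", with_endometriosis=n > 0,
                              lesion_count=n if n else 5)
            d = replace(d, lesion_count=n if n else 5)
            pcts.append(run(d, tube=tube).pct_reached("sperm"))
        assert pcts[0] > pcts[1] > pcts[2] - 1e-9

    def test_crowding_increases_trapping(self, tube20_endo):
        d = small_design(n_sperm=600, n_oocyte_runs=0, with_endometriosis=True)
        lo = replace(EngineParams(), crowding_coeff=0.0)
        hi = replace(EngineParams(), crowding_coeff=2.0)
        p_lo = run(d, tube=tube20_endo, params=lo).pct_reached("sperm")
        p_hi = run(d, tube=tube20_endo, params=hi).pct_reached("sperm")
        assert p_hi <= p_lo


class TestOocyteBehaviour:
    def test_zero_flow_never_reaches(self, tube20):
        d = small_design(n_sperm=0, n_oocyte_runs=10, duration_h=20.0)
        res = run(d, tube=tube20, flow=zero_flow(tube20))
        assert (res.oocyte["status"] != "reached_goal").all()

    def test_lateral_motion_minimal(self, tube20):
        d = small_design(n_sperm=0, n_oocyte_runs=50)
        init = init_positions(d, tube20)["oocyte"]
        res = run(d, tube=tube20)
        reached = res.oocyte["status"] == "reached_goal"
        axial = np.abs(res.oocyte["s"].to_numpy() - init["s"])[reached.to_numpy()]
        lateral = (np.abs(res.oocyte["r_frac"].to_numpy() - init["r_frac"])
                   * 3.4)[reached.to_numpy()]   # radius scale, mm
        assert np.sqrt((lateral**2).mean()) < 0.05 * np.sqrt((axial**2).mean())

    def test_transit_completes_within_window(self, tube20):
        d = small_design(n_sperm=0, n_oocyte_runs=100)
        res = run(d, tube=tube20)
        reached = res.oocyte[res.oocyte["status"] == "reached_goal"]
        assert len(reached) >= 92
        assert reached["t_final"].max() < 80.0

    def test_single_step_reaches_goal_at_uterine_end(self, tube20, flow20):
        rng = CounterRNG(5, 1)
        agent = AgentState(kind="oocyte", s=0.001, r_frac=0.85, theta=0.0,
                           mode="n/a", status="swimming", stuck_at=None,
                           t_final=np.nan)
        params = EngineParams()
        out = None
        for k in range(500):
            out = step_oocyte(agent, tube20, flow20, params, OocyteModel(),
                              dt=10.0, rng=rng, step_index=k)
            if out.status != "swimming":
                break
            agent = out
        assert out.status == "reached_goal"

    def test_occluded_by_extreme_protrusion(self):
        """A lesion narrowing the lumen below the squeeze limit traps the
        oocyte mechanically."""
        tube = build_tube("20s", with_endometriosis=True,
                          overrides={"protrusion_fraction": 0.9})
        d = small_design(n_sperm=0, n_oocyte_runs=30, with_endometriosis=True)
        oo = OocyteModel(corona_diameter=2.0, zona_diameter=1.9,
                         corona_shed_time=0.0, elasticity=30.0)
        res = run(d, tube=tube, oocyte=oo)
        stuck = res.oocyte[res.oocyte["status"] == "stuck"]
        assert (stuck["stuck_at"] > 0).any()

    def test_absorbing_states_never_revert(self, tube20_endo):
        d = small_design(n_sperm=0, n_oocyte_runs=60, with_endometriosis=True)
        res = run(d, tube=tube20_endo)
        # an absorbed agent's recorded time must not exceed the horizon and
        # its status is one of the terminal labels
        done = res.oocyte[res.oocyte["status"] != "swimming"]
        assert set(done["status"]) <= {"stuck", "reached_goal"}


def test_scaled_design():
    d = SimulationDesign(n_sperm=10_000, n_oocyte_runs=100).scaled(0.1)
    assert d.n_sperm == 1000
    assert d.n_oocyte_runs == 10


def test_design_validation():
    with pytest.raises(ValueError):
        SimulationDesign(age_group="teens")
    with pytest.raises(ValueError):
        SimulationDesign(dt_sperm=0.0)
    with pytest.raises(ValueError):
        EngineParams(hyperactivation_trigger="sometimes")
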