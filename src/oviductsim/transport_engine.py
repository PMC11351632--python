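"""Stochastic transport of sperm and oocyte agents through a tube model.

Agents live on the tube backbone with state (s, r_frac, theta). Sperm
self-propel pro-ovary at the resistive-force-theory speed of their beat
mode (normal until first ampulla entry, hyperactivated after), are
advected by the peristalsis-ciliary flow, wander laterally with the beat
excursion, and face an absorbing sticking hazard near the wall that is
amplified inside lesion capture zones and by local crowding. Oocytes are
passive spheres advected pro-uterus with wall hindrance, a corona-
roughness sticking multiplier before shedding, and a squeeze rule at
lesion-narrowed sections. Outcomes are absorbing: ``stuck`` or
``reached_goal`` (fertilization-site window for sperm, uterine-cavity
crossing at s = 0 for oocytes).

All randomness flows through counter-based per-agent streams keyed by the
design seed, so identical (seed, config) gives identical outcome records
regardless of batching or execution order.

Sticking hazards are specified as rates per second and converted to
per-step probabilities via 1 - exp(-rate * dt), keeping outcomes stable
under time-step changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .flow_mechanics import FlowField, MucusProperties
from .oocyte_model import OocyteModel
from .rng import CounterRNG, spawn_seed
from .sperm_model import mode_propulsion
from .tube_geometry import AGE_GROUPS, TubeModel, build_tube

STATUS_SWIMMING, STATUS_STUCK, STATUS_REACHED = 0, 1, 2
STATUS_NAMES = {STATUS_SWIMMING: "swimming", STATUS_STUCK: "stuck",
                STATUS_REACHED: "reached_goal"}
WALL_TAG = 0          # stuck_at value for plain mucosal-wall sticking
NOT_STUCK = -1


@dataclass(frozen=True)
class SimulationDesign:
    """One canonical experiment: agent counts, duration, time steps, seed
    and tube condition."""
    age_group: str = "20s"
    with_endometriosis: bool = False
    lesion_count: int = 5
    n_sperm: int = 10_000
    n_oocyte_runs: int = 100
    duration_h: float = 80.0
    dt_sperm: float = 1.0      # s
    dt_oocyte: float = 10.0    # s
    seed: int = 0

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if min(self.n_sperm, self.n_oocyte_runs) < 0 or self.duration_h < 0:
            raise ValueError("counts and duration must be non-negative")
        if self.dt_sperm <= 0 or self.dt_oocyte <= 0:
            raise ValueError("time steps must be positive")

    def scaled(self, factor: float) -> "SimulationDesign":
        """Agent counts multiplied by ``factor`` (desk-scale runs)."""
        return replace(self, n_sperm=max(0, int(round(self.n_sperm * factor))),
                       n_oocyte_runs=max(0, int(round(self.n_oocyte_runs * factor))))


@dataclass(frozen=True)
class EngineParams:
    """Engine constants. The sticking rates, friction factors and lesion
    multipliers are the calibrated operating point of the simulator (see
    docs/methods.md and scripts/calibrate.py)."""

    # -- sperm -----------------------------------------------------------
    wall_band: float = 0.75            # r_frac beyond which wall contact applies
    capture_band: float = 0.70         # r_frac beyond which lesions capture
    sigma_r_sperm: float = 0.06        # radial random walk, fraction / sqrt(s)
    sigma_theta_sperm: float = 0.10    # azimuthal random walk, rad / sqrt(s)
    friction_by_age: dict = field(default_factory=lambda: {
        "20s": 1.0, "30s": 0.80, "40s": 0.65})
    #: wall sticking hazard rate per age, s^-1 (calibrated)
    stick_rate_sperm: dict = field(default_factory=lambda: {
        "20s": 6.98e-5, "30s": 3.00e-4, "40s": 1.065e-3})
    #: lesion hazard multiplier per age (calibrated)
    lesion_mult_sperm: dict = field(default_factory=lambda: {
        "20s": 2.92, "30s": 6.42, "40s": 13.5})
    crowding_coeff: float = 0.2
    crowding_bin_mm: float = 5.0
    goal_ampulla_fraction: float = 0.70
    hyperactivation_trigger: str = "on_ampulla_entry"   # or "always"

    # -- oocyte ----------------------------------------------------------
    oocyte_wall_band: float = 0.55
    sigma_r_oocyte: float = 0.0002
    #: mean-reversion of the oocyte radial position toward the mucosa
    #: (the dense oocyte settles against the wall), s^-1 and target r_frac
    oocyte_r_relax: float = 2.0e-4
    oocyte_r_target: float = 0.85
    sigma_theta_oocyte: float = 0.01
    #: oocyte wall sticking hazard rate, s^-1 (calibrated)
    stick_rate_oocyte: float = 2.19e-7
    #: oocyte lesion hazard multiplier (calibrated)
    lesion_mult_oocyte: float = 23.1

    def __post_init__(self):
        if self.hyperactivation_trigger not in ("on_ampulla_entry", "always"):
            raise ValueError("hyperactivation_trigger must be "
                             "'on_ampulla_entry' or 'always'")


@dataclass
class AgentState:
    kind: str
    s: float
    r_frac: float
    theta: float
    mode: str
    status: str
    stuck_at: int | None
    t_final: float          # h


@dataclass
class SimulationResult:
    design: SimulationDesign
    sperm: pd.DataFrame | None = None
    oocyte: pd.DataFrame | None = None
    trajectories: dict = field(default_factory=dict)

    def counts(self, kind: str) -> dict:
        df = getattr(self, kind)
        if df is None:
            return {}
        c = df["status"].value_counts().to_dict()
        return {name: int(c.get(name, 0)) for name in STATUS_NAMES.values()}

    def pct_reached(self, kind: str) -> float:
        df = getattr(self, kind)
        if df is None or len(df) == 0:
            raise ValueError(f"no {kind} agents in this result")
        return 100.0 * float((df["status"] == "reached_goal").mean())

    def agents(self, kind: str) -> list[AgentState]:
        df = getattr(self, kind)
        return [AgentState(kind=kind, s=row.s, r_frac=row.r_frac, theta=row.theta,
                           mode=row.mode, status=row.status,
                           stuck_at=None if row.stuck_at < 0 else int(row.stuck_at),
                           t_final=row.t_final)
                for row in df.itertuples()]


# ---------------------------------------------------------------------------

def _lesion_arrays(tube: TubeModel):
    if not tube.lesions:
        return None
    c = np.array([l.center_s for l in tube.lesions])
    az = np.array([l.azimuth for l in tube.lesions])
    hl = np.array([0.5 * l.length for l in tube.lesions])
    r0 = np.array([float(tube.resting_radius(l.center_s)) for l in tube.lesions])
    hw_angle = np.array([0.5 * l.width for l in tube.lesions]) / r0
    ids = np.array([l.id for l in tube.lesions])
    return c, az, hl, hw_angle, ids


def _lesion_hazard_mask(s, theta, lesions):
    """(in_any_zone, lesion_id) for each agent."""
    if lesions is None:
        return np.zeros(s.shape, dtype=bool), np.full(s.shape, NOT_STUCK)
    c, az, hl, hw, ids = lesions
    inz = np.zeros(s.shape, dtype=bool)
    lid = np.full(s.shape, NOT_STUCK)
    for j in range(len(c)):
        dth = np.abs(np.angle(np.exp(1j * (theta - az[j]))))
        m = (np.abs(s - c[j]) < hl[j]) & (dth < hw[j])
        lid = np.where(m & ~inz, ids[j], lid)
        inz |= m
    return inz, lid


def init_positions(design: SimulationDesign, tube: TubeModel):
    """Reproducible initial agent states: sperm uniform inside the
    intramural lumen, one oocyte per run uniform inside the infundibulum."""
    out = {}
    if design.n_sperm > 0:
        rng = CounterRNG(spawn_seed(design.seed, 11), design.n_sperm)
        intr = tube.region("intramural")
        out["sperm"] = {
            "s": intr.start_s + rng.uniform(0, 0) * intr.length,
            "r_frac": 0.95 * rng.uniform(0, 1),
            "theta": 2.0 * math.pi * rng.uniform(0, 2),
        }
    if design.n_oocyte_runs > 0:
        rng = CounterRNG(spawn_seed(design.seed, 12), design.n_oocyte_runs)
        inf = tube.region("infundibulum")
        out["oocyte"] = {
            "s": inf.start_s + rng.uniform(0, 0) * inf.length,
            "r_frac": 0.70 + 0.20 * rng.uniform(0, 1),
            "theta": 2.0 * math.pi * rng.uniform(0, 2),
        }
    return out


def _reflect(x, lo, hi):
    """Mirror-reflect values into [lo, hi]."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def _run_sperm(design: SimulationDesign, tube: TubeModel, flow: FlowField,
               params: EngineParams, traj_stride: int = 0, traj_max: int = 50):
    n = design.n_sperm
    rng = CounterRNG(spawn_seed(design.seed, 11), n)
    init = init_positions(design, tube)["sperm"]
    s = init["s"].copy()
    r = init["r_frac"].copy()
    th = init["theta"].copy()
    mode = np.zeros(n, dtype=np.int8)
    if params.hyperactivation_trigger == "always":
        mode[:] = 1
    status = np.zeros(n, dtype=np.int8)
    stuck_at = np.full(n, NOT_STUCK, dtype=np.int32)
    t_final = np.full(n, np.nan)

    prop = mode_propulsion(flow.mucus)
    v_mode = np.array([prop["normal"].mean_path_speed,
                       prop["hyperactivated"].mean_path_speed]) * 1e-3  # mm/s
    exc_ratio = (prop["hyperactivated"].lateral_excursion
                 / max(prop["normal"].lateral_excursion, 1e-9))
    sig_r = np.array([params.sigma_r_sperm, params.sigma_r_sperm * exc_ratio])

    amp = tube.ampulla
    goal_s = amp.start_s + params.goal_ampulla_fraction * amp.length
    friction = params.friction_by_age[design.age_group]
    wall_rate = params.stick_rate_sperm[design.age_group]
    lesion_mult = params.lesion_mult_sperm[design.age_group]
    lesions = _lesion_arrays(tube)
    L = tube.total_length_L
    dt = design.dt_sperm
    sqdt = math.sqrt(dt)
    n_steps = int(round(design.duration_h * 3600.0 / dt))
    n_bins = max(int(L / params.crowding_bin_mm), 1)
    rho_ref = n / n_bins

    traj = []
    for k in range(n_steps):
        act = status == STATUS_SWIMMING
        if not act.any():
            break
        t = k * dt
        u = flow.velocity(s, r, t)
        v = v_mode[mode] * np.where(r > params.wall_band, friction, 1.0)
        s = np.where(act, s + (v + u) * dt, s)
        s = _reflect(s, 0.0, L)
        r = np.where(act, _reflect(r + sig_r[mode] * sqdt * rng.normal(k, 1),
                                   0.0, 0.98), r)
        th = np.where(act, th + params.sigma_theta_sperm * sqdt * rng.normal(k, 2), th)

        if params.hyperactivation_trigger == "on_ampulla_entry":
            mode = np.where(act & (s >= amp.start_s), 1, mode).astype(np.int8)

        # goal crossing first: an agent that exits the hazard field this
        # step has left the wall region
        reached = act & (s >= goal_s)
        status[reached] = STATUS_REACHED
        t_final[reached] = t / 3600.0
        act &= ~reached

        near_wall = act & (r > params.wall_band)
        in_zone, lid = _lesion_hazard_mask(s, th, lesions)
        in_zone &= act & (r > params.capture_band)
        rate = np.where(near_wall, wall_rate, 0.0)
        rate = np.where(in_zone, wall_rate * lesion_mult, rate)
        if params.crowding_coeff > 0:
            bins = np.clip((s / params.crowding_bin_mm).astype(np.int64), 0, n_bins - 1)
            counts = np.bincount(bins[act], minlength=n_bins)
            ratio = counts[bins] / rho_ref
            crowd = 1.0 + params.crowding_coeff * np.maximum(ratio - 1.0, 0.0)
            rate = rate * crowd
        p = 1.0 - np.exp(-rate * dt)
        stuck = act & (rng.uniform(k, 3) < p)
        status[stuck] = STATUS_STUCK
        stuck_at[stuck] = np.where(in_zone[stuck], lid[stuck], WALL_TAG)
        t_final[stuck] = t / 3600.0

        if np.any(np.isnan(s)):
            bad = int(np.flatnonzero(np.isnan(s))[0])
            raise FloatingPointError(
                f"NaN sperm state at step {k}: agent {bad}, "
                f"r={r[bad]}, theta={th[bad]}, status={status[bad]}")
        if traj_stride and k % traj_stride == 0:
            traj.append(s[:traj_max].copy())

    t_final[status == STATUS_SWIMMING] = design.duration_h
    df = pd.DataFrame({
        "s": s, "r_frac": r, "theta": th,
        "mode": np.where(mode == 1, "hyperactivated", "normal"),
        "status": np.array([STATUS_NAMES[x] for x in status]),
        "stuck_at": stuck_at, "t_final": t_final})
    return df, (np.array(traj) if traj_stride else None)


def _run_oocyte(design: SimulationDesign, tube: TubeModel, flow: FlowField,
                params: EngineParams, oocyte: OocyteModel,
                traj_stride: int = 0, traj_max: int = 50):
    n = design.n_oocyte_runs
    rng = CounterRNG(spawn_seed(design.seed, 12), n)
    init = init_positions(design, tube)["oocyte"]
    s = init["s"].copy()
    r = init["r_frac"].copy()
    th = init["theta"].copy()
    status = np.zeros(n, dtype=np.int8)
    stuck_at = np.full(n, NOT_STUCK, dtype=np.int32)
    t_final = np.full(n, np.nan)

    lesions = _lesion_arrays(tube)
    L = tube.total_length_L
    dt = design.dt_oocyte
    sqdt = math.sqrt(dt)
    n_steps = int(round(design.duration_h * 3600.0 / dt))

    # static squeeze table: narrowest open diameter near lesions
    if lesions is not None:
        s_grid = np.linspace(0.0, L, 512)
        min_open_d = 2.0 * tube.min_open_radius(s_grid)
    else:
        s_grid = min_open_d = None

    traj = []
    for k in range(n_steps):
        act = status == STATUS_SWIMMING
        if not act.any():
            break
        t = k * dt
        t_h = t / 3600.0
        D = 2.0 * flow.radius(s, t)
        H = oocyte.hindrance(D, t_h)
        u = flow.velocity(s, r, t)
        s = np.where(act, s + H * u * dt, s)

        reached = act & (s <= 0.0)
        status[reached] = STATUS_REACHED
        t_final[reached] = t_h
        act &= ~reached
        s = np.clip(s, 0.0, L)

        d_eff = oocyte.effective_diameter(t_h)
        r_max = np.maximum(1.0 - d_eff / D, 0.0)
        dr = (params.oocyte_r_relax * (params.oocyte_r_target - r) * dt
              + params.sigma_r_oocyte * sqdt * rng.normal(k, 1))
        r = np.where(act, np.minimum(_reflect(r + dr, 0.0, 0.98), r_max), r)
        th = np.where(act, th + params.sigma_theta_oocyte * sqdt * rng.normal(k, 2), th)

        in_zone, lid = _lesion_hazard_mask(s, th, lesions)
        in_zone &= act
        # squeeze rule: occluded if the squeeze limit exceeds the narrowest
        # open diameter of a lesion section
        if lesions is not None:
            open_d = np.interp(s, s_grid, min_open_d)
            occluded = in_zone & (oocyte.squeeze_limit(t_h) > open_d)
            status[occluded] = STATUS_STUCK
            stuck_at[occluded] = lid[occluded]
            t_final[occluded] = t_h
            act &= ~occluded
            in_zone &= ~occluded

        near_wall = act & (r > params.oocyte_wall_band)
        rate = np.where(near_wall, params.stick_rate_oocyte, 0.0)
        rate = np.where(in_zone & near_wall,
                        params.stick_rate_oocyte * params.lesion_mult_oocyte, rate)
        rate = rate * oocyte.roughness_factor(t_h)
        p = 1.0 - np.exp(-rate * dt)
        stuck = act & (rng.uniform(k, 3) < p)
        status[stuck] = STATUS_STUCK
        stuck_at[stuck] = np.where(in_zone[stuck], lid[stuck], WALL_TAG)
        t_final[stuck] = t_h

        if np.any(np.isnan(s)):
            bad = int(np.flatnonzero(np.isnan(s))[0])
            raise FloatingPointError(
                f"NaN oocyte state at step {k}: agent {bad}, r={r[bad]}")
        if traj_stride and k % traj_stride == 0:
            traj.append(s[:traj_max].copy())

    t_final[status == STATUS_SWIMMING] = design.duration_h
    df = pd.DataFrame({
        "s": s, "r_frac": r, "theta": th, "mode": "n/a",
        "status": np.array([STATUS_NAMES[x] for x in status]),
        "stuck_at": stuck_at, "t_final": t_final})
    return df, (np.array(traj) if traj_stride else None)


def run(design: SimulationDesign, tube: TubeModel | None = None,
        params: EngineParams | None = None,
        oocyte: OocyteModel | None = None,
        flow: FlowField | None = None,
        traj_stride: int = 0) -> SimulationResult:
    """Execute one simulation design: sperm (if ``n_sperm > 0``) and
    oocyte runs (if ``n_oocyte_runs > 0``) in the same tube."""
    params = params or EngineParams()
    tube = tube if tube is not None else build_tube(
        design.age_group, design.with_endometriosis, design.lesion_count)
    if tube.age_group != design.age_group:
        raise ValueError("tube age group does not match the design")
    if design.with_endometriosis and not tube.lesions:
        raise ValueError("endometriosis design requires a tube with lesions")
    flow = flow if flow is not None else FlowField(tube)
    oocyte = oocyte or OocyteModel()

    result = SimulationResult(design=design)
    if design.n_sperm > 0:
        result.sperm, tr = _run_sperm(design, tube, flow, params,
                                      traj_stride=traj_stride)
        if tr is not None:
            result.trajectories["sperm"] = tr
    if design.n_oocyte_runs > 0:
        result.oocyte, tr = _run_oocyte(design, tube, flow, params, oocyte,
                                        traj_stride=traj_stride)
        if tr is not None:
            result.trajectories["oocyte"] = tr
    return result


# -- single-agent stepping (unit-testable slices of the kernels) -----------

def step_sperm(agent: AgentState, tube: TubeModel, flow: FlowField,
               params: EngineParams, dt: float, rng: CounterRNG,
               step_index: int = 0, v_swim_mm_s: float | None = None) -> AgentState:
    """Advance a single swimming sperm agent by one step dt (s). The
    vectorized engine is the production path; this mirrors one slice of it."""
    if agent.status != "swimming":
        raise ValueError("agent must be swimming")
    if v_swim_mm_s is None:
        prop = mode_propulsion(flow.mucus)
        v_swim_mm_s = prop["hyperactivated" if agent.mode == "hyperactivated"
                           else "normal"].mean_path_speed * 1e-3
    friction = params.friction_by_age[tube.age_group]
    v = v_swim_mm_s * (friction if agent.r_frac > params.wall_band else 1.0)
    u = float(flow.velocity(agent.s, agent.r_frac, step_index * dt))
    s = float(_reflect(np.array(agent.s + (v + u) * dt), 0.0, tube.total_length_L))
    r = float(_reflect(np.array(
        agent.r_frac + params.sigma_r_sperm * math.sqrt(dt)
        * rng.normal(step_index, 1)[0]), 0.0, 0.98))
    th = agent.theta + params.sigma_theta_sperm * math.sqrt(dt) \
        * float(rng.normal(step_index, 2)[0])
    amp = tube.ampulla
    mode = agent.mode
    if params.hyperactivation_trigger == "on_ampulla_entry" and s >= amp.start_s:
        mode = "hyperactivated"
    goal_s = amp.start_s + params.goal_ampulla_fraction * amp.length
    status, stuck_at, t_final = "swimming", agent.stuck_at, agent.t_final
    if s >= goal_s:
        status = "reached_goal"
        t_final = (step_index + 1) * dt / 3600.0
    else:
        in_zone, lid = _lesion_hazard_mask(np.array([s]), np.array([th]),
                                           _lesion_arrays(tube))
        rate = 0.0
        if r > params.wall_band:
            rate = params.stick_rate_sperm[tube.age_group]
            if in_zone[0] and r > params.capture_band:
                rate *= params.lesion_mult_sperm[tube.age_group]
        if rng.uniform(step_index, 3)[0] < 1.0 - math.exp(-rate * dt):
            status = "stuck"
            stuck_at = int(lid[0]) if in_zone[0] else WALL_TAG
            t_final = (step_index + 1) * dt / 3600.0
    return AgentState(kind="sperm", s=s, r_frac=r, theta=th, mode=mode,
                      status=status, stuck_at=stuck_at, t_final=t_final)


def step_oocyte(agent: AgentState, tube: TubeModel, flow: FlowField,
                params: EngineParams, oocyte: OocyteModel, dt: float,
                rng: CounterRNG, step_index: int = 0) -> AgentState:
    """Advance a single swimming oocyte agent by one step dt (s)."""
    if agent.status != "swimming":
        raise ValueError("agent must be swimming")
    t = step_index * dt
    t_h = t / 3600.0
    D = 2.0 * float(flow.radius(agent.s, t))
    H = oocyte.hindrance(D, t_h)
    u = float(flow.velocity(agent.s, agent.r_frac, t))
    s = agent.s + H * u * dt
    status, stuck_at, t_final = "swimming", agent.stuck_at, agent.t_final
    if s <= 0.0:
        return AgentState(kind="oocyte", s=0.0, r_frac=agent.r_frac,
                          theta=agent.theta, mode="n/a", status="reached_goal",
                          stuck_at=stuck_at, t_final=(step_index + 1) * dt / 3600.0)
    s = min(s, tube.total_length_L)
    r_max = max(1.0 - oocyte.effective_diameter(t_h) / D, 0.0)
    r = min(float(_reflect(np.array(
        agent.r_frac + params.sigma_r_oocyte * math.sqrt(dt)
        * rng.normal(step_index, 1)[0]), 0.0, 0.98)), r_max)
    th = agent.theta + params.sigma_theta_oocyte * math.sqrt(dt) \
        * float(rng.normal(step_index, 2)[0])
    in_zone, lid = _lesion_hazard_mask(np.array([s]), np.array([th]),
                                       _lesion_arrays(tube))
    if in_zone[0] and oocyte.squeeze_limit(t_h) > 2.0 * float(tube.min_open_radius(s)):
        return AgentState(kind="oocyte", s=s, r_frac=r, theta=th, mode="n/a",
                          status="stuck", stuck_at=int(lid[0]),
                          t_final=(step_index + 1) * dt / 3600.0)
    rate = 0.0
    if r > params.oocyte_wall_band:
        rate = params.stick_rate_oocyte
        if in_zone[0]:
            rate *= params.lesion_mult_oocyte
    rate *= oocyte.roughness_factor(t_h)
    if rng.uniform(step_index, 3)[0] < 1.0 - math.exp(-rate * dt):
        status = "stuck"
        stuck_at = int(lid[0]) if in_zone[0] else WALL_TAG
        t_final = (step_index + 1) * dt / 3600.0
    return AgentState(kind="oocyte", s=s, r_frac=r, theta=th, mode="n/a",
                      status=status, stuck_at=stuck_at, t_final=t_final)
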