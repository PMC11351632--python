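"""Summary statistics and report artifacts.

Aggregates simulation results into arrival percentages with SEM across
seed replicates, per-lesion stuck counts, and the endometriosis reduction
rate (normal - endo) / normal x 100; writes the CSV tables, bar charts
with SEM whiskers and trajectory-density figures that summarize a full
condition grid (3 ages x {normal, endometriosis} x {sperm, oocyte}).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tube_geometry import AGE_GROUPS
from .transport_engine import SimulationResult

CONDITION_GRID = [(age, endo, kind)
                  for age in AGE_GROUPS
                  for endo in (False, True)
                  for kind in ("sperm", "oocyte")]


@dataclass(frozen=True)
class SummaryStats:
    age_group: str
    with_endometriosis: bool
    kind: str
    pct_reached: float
    sem: float
    n_agents: int
    n_replicates: int
    per_lesion_stuck: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.pct_reached <= 100.0 or self.sem < 0:
            raise ValueError("invalid summary percentages")


@dataclass(frozen=True)
class ReductionRate:
    age_group: str
    kind: str
    rate: float    # %


def summarize(results: list[SimulationResult], kind: str) -> SummaryStats:
    """Pool replicate results of one condition: pooled arrival percentage,
    SEM of the per-replicate percentages, and lesion-attributed stuck
    counts."""
    if not results:
        raise ValueError("need at least one result")
    key = {(r.design.age_group, r.design.with_endometriosis) for r in results}
    if len(key) != 1:
        raise ValueError(f"mixed conditions in summarize: {sorted(key)}")
    age, endo = key.pop()
    frames = [getattr(r, kind) for r in results]
    if any(f is None for f in frames):
        raise ValueError(f"some results carry no {kind} agents")
    pcts = np.array([100.0 * (f["status"] == "reached_goal").mean() for f in frames])
    total = sum(len(f) for f in frames)
    reached = sum(int((f["status"] == "reached_goal").sum()) for f in frames)
    sem = float(pcts.std(ddof=1) / np.sqrt(len(pcts))) if len(pcts) > 1 else 0.0
    stuck = pd.concat(frames)
    stuck = stuck[(stuck["status"] == "stuck") & (stuck["stuck_at"] > 0)]
    per_lesion = stuck["stuck_at"].value_counts().sort_index().to_dict()
    return SummaryStats(age_group=age, with_endometriosis=endo, kind=kind,
                        pct_reached=100.0 * reached / total, sem=sem,
                        n_agents=total, n_replicates=len(results),
                        per_lesion_stuck={int(k): int(v) for k, v in per_lesion.items()})


def reduction_rate(normal: SummaryStats, endo: SummaryStats) -> ReductionRate:
    """Relative loss due to endometriosis: (pct_normal - pct_endo) /
    pct_normal x 100."""
    if normal.age_group != endo.age_group or normal.kind != endo.kind:
        raise ValueError("reduction rate needs matching age group and kind")
    if normal.with_endometriosis or not endo.with_endometriosis:
        raise ValueError("arguments must be (normal, endometriosis) in that order")
    if normal.pct_reached <= 0:
        raise ValueError("normal-condition percentage must be positive")
    rate = (normal.pct_reached - endo.pct_reached) / normal.pct_reached * 100.0
    return ReductionRate(age_group=normal.age_group, kind=normal.kind, rate=rate)


def stats_table(stats: list[SummaryStats]) -> pd.DataFrame:
    rows = [{
        "age_group": s.age_group,
        "condition": "endometriosis" if s.with_endometriosis else "normal",
        "kind": s.kind, "pct_reached": s.pct_reached, "sem": s.sem,
        "n_agents": s.n_agents, "n_replicates": s.n_replicates,
    } for s in stats]
    return pd.DataFrame(rows)


def reduction_table(stats: list[SummaryStats]) -> pd.DataFrame:
    by_key = {(s.age_group, s.kind, s.with_endometriosis): s for s in stats}
    rows = []
    for age, kind in itertools.product(AGE_GROUPS, ("sperm", "oocyte")):
        n, e = by_key.get((age, kind, False)), by_key.get((age, kind, True))
        if n is not None and e is not None and n.pct_reached > 0:
            rows.append({"age_group": age, "kind": kind,
                         "reduction_rate_pct": reduction_rate(n, e).rate})
    return pd.DataFrame(rows)


def report(stats: list[SummaryStats], out_dir, results=None,
           formats: tuple[str, ...] = ("csv", "png")) -> dict:
    """Write the condition-grid report: per-kind stat tables, per-kind
    reduction tables, bar charts with SEM whiskers and (when results with
    trajectories are given) trajectory density maps.

    Missing conditions are reported; partial output is still written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    have = {(s.age_group, s.with_endometriosis, s.kind) for s in stats}
    missing = [c for c in CONDITION_GRID if c not in have]
    if len(missing) == len(CONDITION_GRID):
        raise ValueError("empty condition grid; missing all of: " + ", ".join(
            f"{a}/{'endo' if e else 'normal'}/{k}" for a, e, k in missing))

    written = {"tables": [], "figures": [], "missing": missing}
    if "csv" in formats:
        for kind in ("sperm", "oocyte"):
            sk = [s for s in stats if s.kind == kind]
            if sk:
                p = out_dir / f"stats_{kind}.csv"
                stats_table(sk).to_csv(p, index=False)
                written["tables"].append(p)
                rt = reduction_table(sk)
                if len(rt):
                    p = out_dir / f"reduction_{kind}.csv"
                    rt.to_csv(p, index=False)
                    written["tables"].append(p)
    if "png" in formats:
        written["figures"] += _bar_charts(stats, out_dir)
        if results:
            written["figures"] += _trajectory_maps(results, out_dir)
    return written


def _bar_charts(stats, out_dir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    for kind, goal in (("sperm", "reaching the ampulla"),
                       ("oocyte", "reaching the uterine cavity")):
        sk = [s for s in stats if s.kind == kind]
        if not sk:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
        x = np.arange(len(AGE_GROUPS))
        for endo, off, color in ((False, -0.18, "#4878a8"), (True, 0.18, "#b0504f")):
            vals = [next((s.pct_reached for s in sk
                          if s.age_group == a and s.with_endometriosis == endo),
                         np.nan) for a in AGE_GROUPS]
            errs = [next((s.sem for s in sk
                          if s.age_group == a and s.with_endometriosis == endo),
                         0.0) for a in AGE_GROUPS]
            axes[0].bar(x + off, vals, 0.34, yerr=errs, capsize=3, color=color,
                        label="endometriosis" if endo else "normal")
        axes[0].set_xticks(x, AGE_GROUPS)
        axes[0].set_ylabel(f"% {goal}")
        axes[0].legend(frameon=False, fontsize=8)
        rt = reduction_table(sk)
        if len(rt):
            axes[1].bar(rt["age_group"], rt["reduction_rate_pct"], 0.5,
                        color="#777777")
            axes[1].set_ylabel("reduction rate (%)")
        fig.tight_layout()
        p = out_dir / f"percentages_{kind}.png"
        fig.savefig(p, dpi=130)
        plt.close(fig)
        out.append(p)
    return out


def _trajectory_maps(results, out_dir: Path):
    """2D trajectory maps in the anterior (x-y) plane with lesion markers;
    trajectories are the stored arclength samples projected through the
    tube centerline."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .tube_geometry import build_tube

    out = []
    for res in results:
        for kind, traj in res.trajectories.items():
            d = res.design
            tube = build_tube(d.age_group, d.with_endometriosis, d.lesion_count)
            fig, ax = plt.subplots(figsize=(7, 3))
            pts, _ = tube.centerline(np.linspace(0, tube.total_length_L, 300))
            ax.plot(pts[:, 0], pts[:, 1], color="#cccccc", lw=6, alpha=0.6,
                    solid_capstyle="round", zorder=0)
            for i in range(min(traj.shape[1], 25)):
                p, _ = tube.centerline(traj[:, i])
                ax.plot(p[:, 0], p[:, 1], lw=0.6, alpha=0.7)
            for les in tube.lesions:
                p, _ = tube.centerline(np.array([les.center_s]))
                ax.plot(p[0, 0], p[0, 1], "r^", ms=7, zorder=3)
            cond = "endometriosis" if d.with_endometriosis else "normal"
            ax.set_xlabel("x (mm)")
            ax.set_ylabel("y (mm)")
            ax.set_title(f"{kind}, {d.age_group} {cond} (anterior view)", fontsize=9)
            fig.tight_layout()
            p = out_dir / f"trajectories_{kind}_{d.age_group}_{cond}.png"
            fig.savefig(p, dpi=130)
            plt.close(fig)
            out.append(p)
    return out
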