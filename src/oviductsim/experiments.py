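"""Canonical replicated experiments.

These are the study's headline computations: the oocyte uterine-cavity
arrival percentage (100 single-oocyte runs per seed, 80 h) and the
sperm fertilization-site percentage with its endometriosis reduction
rate, replicated over master seeds. Both reuse one tube and flow field
per condition and report the replicate mean (the pooled percentage) so
that repeated calls with the same seeds are fully deterministic.
"""

from __future__ import annotations

import numpy as np

from .flow_mechanics import FlowField
from .oocyte_model import OocyteModel
from .rng import spawn_seed
from .transport_engine import EngineParams, SimulationDesign, run
from .tube_geometry import build_tube


def seed_list(base_seed: int, n: int, tag: int) -> list[int]:
    """Independent sub-seeds (< 2**31) for replicate runs."""
    return [spawn_seed(base_seed, tag, i) for i in range(n)]


def oocyte_percentages(age_group: str, with_endometriosis: bool,
                       base_seed: int = 0, n_seeds: int = 20,
                       n_runs: int = 100, duration_h: float = 80.0,
                       params: EngineParams | None = None) -> np.ndarray:
    """Per-seed percentages of oocyte runs reaching the uterine cavity."""
    params = params or EngineParams()
    tube = build_tube(age_group, with_endometriosis)
    flow = FlowField(tube)
    oocyte = OocyteModel()
    out = []
    for seed in seed_list(base_seed, n_seeds, tag=101):
        d = SimulationDesign(age_group=age_group,
                             with_endometriosis=with_endometriosis,
                             n_sperm=0, n_oocyte_runs=n_runs,
                             duration_h=duration_h, seed=seed)
        out.append(run(d, tube=tube, params=params, oocyte=oocyte,
                       flow=flow).pct_reached("oocyte"))
    return np.asarray(out)


def sperm_percentages(age_group: str, with_endometriosis: bool,
                      base_seed: int = 0, n_seeds: int = 10,
                      n_sperm: int = 1000, duration_h: float = 80.0,
                      params: EngineParams | None = None) -> np.ndarray:
    """Per-seed percentages of sperm agents reaching the fertilization
    site."""
    params = params or EngineParams()
    tube = build_tube(age_group, with_endometriosis)
    flow = FlowField(tube)
    out = []
    for seed in seed_list(base_seed, n_seeds, tag=202):
        d = SimulationDesign(age_group=age_group,
                             with_endometriosis=with_endometriosis,
                             n_sperm=n_sperm, n_oocyte_runs=0,
                             duration_h=duration_h, seed=seed)
        out.append(run(d, tube=tube, params=params,
                       flow=flow).pct_reached("sperm"))
    return np.asarray(out)


def sperm_reduction_rate(age_group: str, base_seed: int = 0,
                         n_seeds: int = 10, n_sperm: int = 1000,
                         params: EngineParams | None = None
                         ) -> tuple[float, float, float]:
    """(reduction rate %, pct normal, pct endo) from paired normal and
    endometriosis runs at the same seeds."""
    p_n = float(np.mean(sperm_percentages(age_group, False, base_seed,
                                          n_seeds, n_sperm, params=params)))
    p_e = float(np.mean(sperm_percentages(age_group, True, base_seed,
                                          n_seeds, n_sperm, params=params)))
    rate = (p_n - p_e) / p_n * 100.0
    return rate, p_n, p_e
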