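"""Fit the simulator's sticking-hazard operating point.

The wall-sticking rates, lesion multipliers and ciliary calibration
constant are the free parameters of the reduced-order model; the
fertilization-site / uterine-cavity arrival percentages of the six
canonical configurations define its operating point. This script fits
them by monotone bisection in log-rate space using common random numbers,
and prints a block ready to paste into ``EngineParams``.

Targets:
  oocyte  : 98% reached (20s normal), 91% (20s endometriosis)
  sperm   : 90 / 70 / 40% reached in the normal tubes (20s/30s/40s) and
            endometriosis percentages implied by the relative reduction
            rates 4.8 / 33.3 / 81.8%.

Usage: python scripts/calibrate.py [--fast]
"""

from __future__ import annotations

import argparse
import math
from dataclasses import replace

import numpy as np

from oviductsim.transport_engine import EngineParams, SimulationDesign, run

SPERM_NORMAL_TARGETS = {"20s": 90.0, "30s": 70.0, "40s": 40.0}
SPERM_REDUCTION_RATES = {"20s": 4.8, "30s": 33.3, "40s": 81.8}
OOCYTE_TARGETS = {"normal": 98.0, "endo": 91.0}


def pct_oocyte(params, age, endo, n_runs, seeds):
    vals = []
    for seed in seeds:
        d = SimulationDesign(age_group=age, with_endometriosis=endo,
                             n_sperm=0, n_oocyte_runs=n_runs, seed=seed)
        vals.append(run(d, params=params).pct_reached("oocyte"))
    return float(np.mean(vals))


def pct_sperm(params, age, endo, n_sperm, seeds):
    vals = []
    for seed in seeds:
        d = SimulationDesign(age_group=age, with_endometriosis=endo,
                             n_sperm=n_sperm, n_oocyte_runs=0, seed=seed)
        vals.append(run(d, params=params).pct_reached("sperm"))
    return float(np.mean(vals))


def bisect_log(f, lo, hi, target, iters=8, tol=0.3):
    """Bisection on log-x for a decreasing f(x); returns the fitted x."""
    flo, fhi = f(lo), f(hi)
    if not (fhi <= target <= flo):
        raise RuntimeError(f"target {target} outside bracket "
                           f"[{fhi:.2f}, {flo:.2f}] for x in [{lo:g}, {hi:g}]")
    for _ in range(iters):
        mid = math.exp(0.5 * (math.log(lo) + math.log(hi)))
        fm = f(mid)
        if abs(fm - target) < tol:
            return mid
        if fm > target:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (math.log(lo) + math.log(hi)))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true",
                    help="smaller agent counts (rough fit)")
    args = ap.parse_args()
    n_oo = 100 if args.fast else 200
    n_sp = 500 if args.fast else 2000
    seeds = list(range(101, 105)) if args.fast else list(range(101, 109))

    params = EngineParams()

    # -- oocyte wall rate -------------------------------------------------
    def f_oo(rate):
        p = replace(params, stick_rate_oocyte=rate)
        v = pct_oocyte(p, "20s", False, n_oo, seeds)
        print(f"    oocyte wall rate {rate:.3e} -> {v:.2f}%")
        return v

    rate_oo = bisect_log(f_oo, 3e-8, 3e-6, OOCYTE_TARGETS["normal"], tol=0.15)
    params = replace(params, stick_rate_oocyte=rate_oo)
    print(f"stick_rate_oocyte = {rate_oo:.4e}")

    # -- oocyte lesion multiplier ----------------------------------------
    def f_oo_mult(mult):
        p = replace(params, lesion_mult_oocyte=mult)
        v = pct_oocyte(p, "20s", True, n_oo, seeds)
        print(f"    oocyte lesion mult {mult:.1f} -> {v:.2f}%")
        return v

    mult_oo = bisect_log(f_oo_mult, 3.0, 600.0, OOCYTE_TARGETS["endo"], tol=0.15)
    params = replace(params, lesion_mult_oocyte=mult_oo)
    print(f"lesion_mult_oocyte = {mult_oo:.1f}")

    # -- sperm wall rates per age ----------------------------------------
    rates = dict(params.stick_rate_sperm)
    for age, target in SPERM_NORMAL_TARGETS.items():
        def f_sp(rate, age=age):
            r = dict(rates); r[age] = rate
            p = replace(params, stick_rate_sperm=r)
            v = pct_sperm(p, age, False, n_sp, seeds)
            print(f"    sperm wall rate[{age}] {rate:.3e} -> {v:.2f}%")
            return v
        rates[age] = bisect_log(f_sp, 1e-5, 1e-2, target, tol=0.3)
        print(f"stick_rate_sperm[{age}] = {rates[age]:.4e}")
    params = replace(params, stick_rate_sperm=rates)

    # -- sperm lesion multipliers per age --------------------------------
    mults = dict(params.lesion_mult_sperm)
    for age, rr in SPERM_REDUCTION_RATES.items():
        target = SPERM_NORMAL_TARGETS[age] * (1.0 - rr / 100.0)
        def f_mult(mult, age=age):
            m = dict(mults); m[age] = mult
            p = replace(params, lesion_mult_sperm=m)
            v = pct_sperm(p, age, True, n_sp, seeds)
            print(f"    sperm lesion mult[{age}] {mult:.2f} -> {v:.2f}% "
                  f"(target {target:.2f})")
            return v
        mults[age] = bisect_log(f_mult, 1.05, 400.0, target, tol=0.3)
        print(f"lesion_mult_sperm[{age}] = {mults[age]:.2f}")
    params = replace(params, lesion_mult_sperm=mults)

    print("\nFitted operating point:")
    print(f"  stick_rate_oocyte = {params.stick_rate_oocyte:.4e}")
    print(f"  lesion_mult_oocyte = {params.lesion_mult_oocyte:.1f}")
    print(f"  stick_rate_sperm = {params.stick_rate_sperm}")
    print(f"  lesion_mult_sperm = {params.lesion_mult_sperm}")


if __name__ == "__main__":
    main()
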