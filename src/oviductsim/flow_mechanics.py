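"""Peristalsis-ciliary mucus flow inside a tube model.

The full fluid problem is reduced to a lubrication-theory description on
the tube backbone: traveling contraction waves squeeze the wall inward,
and the incompressible mucus responds with an axial mean velocity fixed by
mass conservation through the time-varying cross-section, carried on a
Poiseuille radial profile. Coordinated ciliary beating enters as a
near-wall slip velocity directed pro-uterus (toward s = 0), decaying away
from the wall. The wall obeys a compressible neo-Hookean constitutive law
(strain energy in I1 and J with Lamé parameters derived from the printed
stiffness formulas); the pressure-to-displacement map uses a linear
compliance derived from the shear Lamé parameter rather than solving the
full boundary-value problem.

Sign convention: positive axial velocity points pro-ovary (+s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tube_geometry import TubeModel
from .units import mmhg_to_kpa

PERISTALSIS_INTENSITY_MMHG = 20.0   # contraction intensity
PERISTALSIS_FREQ_PER_MIN = 1.5      # contraction frequency
CILIA_BEAT_HZ = 5.4                 # ciliary beat frequency
DEFAULT_POISSON = 0.49
DEFAULT_KAPPA_KPA = 13.0            # mid of the 12-14 kPa stiffness range

#: calibration constant of the ciliary slip law (see docs/methods.md);
#: fitted so a normal 20s-tube oocyte transit completes well inside 80 h
DEFAULT_C_CAL = 7.2e-3

#: geometric factor of the linear wall compliance (dimensionless)
WALL_STIFFNESS_FACTOR = 3.0

#: radial extent of the ciliary slip layer: slip decays linearly from the
#: wall (r_frac = 1) to zero at r_frac = CILIA_LAYER_EDGE
CILIA_LAYER_EDGE = 0.6


def lame_parameters(kappa: float, L_ref: float, A_ref: float, nu: float
                    ) -> tuple[float, float]:
    """Lamé parameters (mu, lambda) in kPa from wall stiffness kappa (kPa),
    reference length L_ref (mm), reference area A_ref (mm^2) and Poisson
    ratio nu:

        mu     = L * kappa / (2 * A * (1 + nu))
        lambda = nu * L * kappa / ((1 + nu) * (1 - 2 nu) * A)
    """
    if not (kappa > 0 and L_ref > 0 and A_ref > 0):
        raise ValueError("kappa, L_ref and A_ref must be positive")
    if not 0.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (0, 0.5); nu = 0.5 is the "
                         "incompressible limit and has no finite lambda")
    mu = L_ref * kappa / (2.0 * A_ref * (1.0 + nu))
    lam = nu * L_ref * kappa / ((1.0 + nu) * (1.0 - 2.0 * nu) * A_ref)
    return mu, lam


@dataclass(frozen=True)
class StrainState:
    """First invariant of the right Cauchy-Green tensor and the determinant
    of the deformation gradient."""
    I1: float
    J: float

    def __post_init__(self):
        if self.J <= 0:
            raise ValueError("J must be positive")


@dataclass(frozen=True)
class WallMaterial:
    kappa: float = DEFAULT_KAPPA_KPA
    L_ref: float = 95.0
    A_ref: float = 20.0
    nu: float = DEFAULT_POISSON

    def __post_init__(self):
        if not 12.0 <= self.kappa <= 14.0:
            raise ValueError("wall stiffness must lie in the 12-14 kPa range")
        lame_parameters(self.kappa, self.L_ref, self.A_ref, self.nu)  # validates

    @property
    def mu_lame(self) -> float:
        return lame_parameters(self.kappa, self.L_ref, self.A_ref, self.nu)[0]

    @property
    def lambda_lame(self) -> float:
        return lame_parameters(self.kappa, self.L_ref, self.A_ref, self.nu)[1]

    def strain_energy(self, state: StrainState) -> float:
        return strain_energy(state, self.mu_lame, self.lambda_lame)


def strain_energy(state: StrainState, mu: float, lam: float) -> float:
    """Neo-Hookean strain-energy density (kPa),

        W = (mu/2)(I1 - 3) + mu ln J + (lam/2)(ln J)^2

    implemented with the +mu ln J term exactly as the constitutive law is
    stated for this wall model (the textbook compressible form carries
    -mu ln J; see docs/methods.md)."""
    if state.J <= 0:
        raise ValueError("J must be positive")
    lnJ = math.log(state.J)
    return 0.5 * mu * (state.I1 - 3.0) + mu * lnJ + 0.5 * lam * lnJ**2


@dataclass(frozen=True)
class PeristalsisWave:
    """One traveling contraction wave. ``pro_ovary`` propagates toward
    increasing s (uterus -> ampulla); ``pro_uterus`` from the fimbrial end
    toward the isthmus."""
    amplitude_p: float = PERISTALSIS_INTENSITY_MMHG   # mmHg
    frequency: float = PERISTALSIS_FREQ_PER_MIN       # min^-1
    direction: str = "pro_ovary"
    wavelength: float = 32.0                          # mm
    origin_s: float = 0.0
    phase0: float = 0.0

    def __post_init__(self):
        if self.direction not in ("pro_ovary", "pro_uterus"):
            raise ValueError("direction must be pro_ovary or pro_uterus")
        if self.amplitude_p < 0 or self.frequency <= 0 or self.wavelength <= 0:
            raise ValueError("invalid wave parameters")

    @property
    def period_s(self) -> float:
        return 60.0 / self.frequency

    def phase(self, s, t):
        k = 2.0 * math.pi / self.wavelength
        omega = 2.0 * math.pi / self.period_s
        if self.direction == "pro_ovary":
            return k * (np.asarray(s) - self.origin_s) - omega * t + self.phase0
        return k * (self.origin_s - np.asarray(s)) - omega * t + self.phase0


def default_waves(tube: TubeModel) -> tuple[PeristalsisWave, PeristalsisWave]:
    """The two simultaneous waves: pro-ovary from the intramural end and
    pro-uterus from the infundibulum; wavelength = half the ampulla length."""
    wl = 0.5 * tube.ampulla.length
    return (PeristalsisWave(direction="pro_ovary", wavelength=wl, origin_s=0.0),
            PeristalsisWave(direction="pro_uterus", wavelength=wl,
                            origin_s=tube.total_length_L))


def wall_displacement(tube: TubeModel, material: WallMaterial, wave, s, t,
                      stiffness_factor: float = WALL_STIFFNESS_FACTOR):
    """Inward radial wall displacement (mm) at (s, t) under one traveling
    contraction wave or a sequence of them (superposed), clamped to 90% of
    the local resting radius.

    Amplitude = contraction pressure (kPa) x local compliance
    R0 / (stiffness_factor * mu); the (1 + cos)/2 waveform keeps the
    squeeze inward (non-negative) and periodic in the contraction period.
    """
    waves = wave if isinstance(wave, (tuple, list)) else (wave,)
    s = np.asarray(s, dtype=float)
    r0 = np.sqrt(np.atleast_1d(tube.luminal_area(s)) / math.pi)
    r0 = r0.reshape(np.shape(s)) if np.shape(s) else float(r0[0])
    total = np.zeros(np.shape(s))
    for w in waves:
        amp = mmhg_to_kpa(w.amplitude_p) * r0 / (stiffness_factor * material.mu_lame)
        total = total + amp * 0.5 * (1.0 + np.cos(w.phase(s, t)))
    return np.minimum(total, 0.9 * r0)


@dataclass(frozen=True)
class CiliaField:
    density: float = 2000.0          # mm^-2
    beat_frequency: float = CILIA_BEAT_HZ
    cilium_length: float = 7.0       # µm
    stroke_efficiency: float = 1.0
    c_cal: float = DEFAULT_C_CAL     # calibration constant (absorbs units)

    def __post_init__(self):
        if not 0.0 < self.stroke_efficiency <= 1.0:
            raise ValueError("stroke_efficiency must lie in (0, 1]")
        if self.density < 0 or self.beat_frequency <= 0 or self.cilium_length <= 0:
            raise ValueError("invalid cilia parameters")

    def slip_speed(self) -> float:
        """Near-wall ciliary transport speed magnitude, mm/s:
        c_cal * efficiency * density * beat_frequency * length^2."""
        ell_mm = self.cilium_length * 1e-3
        return (self.c_cal * self.stroke_efficiency * self.density
                * self.beat_frequency * ell_mm**2)


@dataclass(frozen=True)
class MucusProperties:
    """Cervical-mucus thermophysical properties. The thermal fields are
    stored for completeness but unused (isothermal model)."""
    density: float = 1007.0              # kg/m^3
    specific_heat: float = 4140.0        # J/(kg K), unused
    thermal_conductivity: float = 0.627  # W/(m K), unused
    viscosity_slope: float = 0.02        # Pa*s per unit shear rate
    viscosity_intercept: float = 0.98    # Pa*s

    def viscosity(self, shear_rate):
        """Dynamic viscosity, Pa*s: intercept + slope * shear_rate."""
        shear_rate = np.asarray(shear_rate, dtype=float)
        if np.any(shear_rate < 0):
            raise ValueError("shear rate must be non-negative")
        out = self.viscosity_intercept + self.viscosity_slope * shear_rate
        return float(out) if out.ndim == 0 else out


def cilia_radial_profile(r_frac):
    """Linear decay of the ciliary slip from the wall (r_frac = 1) to zero
    at the edge of the slip layer."""
    r = np.asarray(r_frac, dtype=float)
    return np.clip((r - CILIA_LAYER_EDGE) / (1.0 - CILIA_LAYER_EDGE), 0.0, 1.0)


class FlowField:
    """Precomputed peristalsis-ciliary velocity field for one tube.

    The peristaltic mean velocity is tabulated on an (s, t) grid over one
    contraction period from mass conservation, Q(s, t) =
    -int_0^s dA/dt ds' with Q(0, t) = 0, and interpolated bilinearly
    (periodic in t). The ciliary slip is steady (beat-cycle averaged).
    """

    def __init__(self, tube: TubeModel, material: WallMaterial | None = None,
                 waves=None, cilia: CiliaField | None = None,
                 mucus: MucusProperties | None = None,
                 stiffness_factor: float = WALL_STIFFNESS_FACTOR,
                 n_s: int = 257, n_phase: int = 64):
        self.tube = tube
        self.material = material or WallMaterial(L_ref=tube.total_length_L)
        self.waves = tuple(waves) if waves is not None else default_waves(tube)
        self.cilia = cilia if cilia is not None else CiliaField(density=tube.cilia_density)
        self.mucus = mucus or MucusProperties()
        self.stiffness_factor = stiffness_factor

        periods = {w.period_s for w in self.waves}
        if len(periods) > 1:
            raise ValueError("waves must share one contraction period")
        self.period = periods.pop() if periods else 40.0

        self.s_grid = np.linspace(0.0, tube.total_length_L, n_s)
        self.t_grid = np.linspace(0.0, self.period, n_phase, endpoint=False)
        r0 = np.sqrt(tube.luminal_area(self.s_grid) / math.pi)   # (n_s,)
        disp = np.stack([
            wall_displacement(tube, self.material, self.waves, self.s_grid, t,
                              self.stiffness_factor)
            for t in self.t_grid], axis=1) if self.waves else np.zeros((n_s, n_phase))
        R = r0[:, None] - disp                                  # (n_s, n_phase)
        A = math.pi * R**2
        dt = self.period / n_phase
        dAdt = (np.roll(A, -1, axis=1) - np.roll(A, 1, axis=1)) / (2.0 * dt)
        # Q(s, t) = -int_0^s dA/dt ds'
        ds = self.s_grid[1] - self.s_grid[0]
        Q = -np.concatenate([np.zeros((1, n_phase)),
                             np.cumsum(0.5 * (dAdt[1:] + dAdt[:-1]) * ds, axis=0)],
                            axis=0)
        self._R = R
        self._A = A
        self._Q = Q
        self._u_mean = Q / A
        self._slip = self.cilia.slip_speed()

    # -- bilinear periodic-time interpolation -----------------------------
    def _interp(self, table, s, t):
        s = np.asarray(s, dtype=float)
        n_phase = table.shape[1]
        tau = (t % self.period) / self.period * n_phase
        i0 = int(np.floor(tau)) % n_phase
        i1 = (i0 + 1) % n_phase
        w = tau - np.floor(tau)
        col = (1.0 - w) * table[:, i0] + w * table[:, i1]
        return np.interp(s, self.s_grid, col)

    def mean_velocity(self, s, t):
        """Cross-section-averaged peristaltic axial velocity, mm/s (+s pro-ovary)."""
        return self._interp(self._u_mean, s, t)

    def radius(self, s, t):
        """Instantaneous effective luminal radius, mm."""
        return self._interp(self._R, s, t)

    def area(self, s, t):
        return self._interp(self._A, s, t)

    def flux(self, s, t):
        """Instantaneous volume flux, mm^3/s."""
        return self._interp(self._Q, s, t)

    def cilia_velocity(self, r_frac):
        """Ciliary axial velocity, mm/s; negative (pro-uterus) in the wall layer."""
        return -self._slip * cilia_radial_profile(r_frac)

    def velocity(self, s, r_frac, t):
        """Total axial mucus velocity at (s, r_frac, t), mm/s."""
        r = np.asarray(r_frac, dtype=float)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("r_frac must lie in [0, 1]")
        return 2.0 * self.mean_velocity(s, t) * (1.0 - r**2) + self.cilia_velocity(r)

    def wall_shear_rate(self, s, t):
        """Poiseuille wall shear-rate magnitude |4 u_mean / R|, s^-1."""
        return np.abs(4.0 * self.mean_velocity(s, t) / self.radius(s, t))

    def viscosity_at(self, s, t):
        """Mucus viscosity (Pa*s) evaluated at the local wall shear rate."""
        return self.mucus.viscosity(self.wall_shear_rate(s, t))


def flow_velocity(tube: TubeModel, flow_inputs, s, r_frac, t):
    """Thin functional wrapper: flow_inputs = (material, waves, cilia, mucus)."""
    material, waves, cilia, mucus = flow_inputs
    return FlowField(tube, material, waves, cilia, mucus).velocity(s, r_frac, t)
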