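"""Flagellar beat generation and resistive-force-theory propulsion.

The axonemal beat is generated from discrete dynein sliding forces: 100
motor sites at equal intervals along the flagellum each impose a local
curvature proportional to the sliding force, modulated by a traveling
wave in the beat phase. The 3D flagellar shape follows by integrating the
Frenet-Serret system along arclength with the sampled curvature and a
small constant torsion, which preserves arclength exactly
(inextensibility). Hyperactivation raises the sliding force from 2e-6 to
5e-6 µN and adds a static curvature offset, producing the large,
asymmetric beat envelope characteristic of fertilization-site behavior.

Propulsion converts the beat cycle into swimming via Gray-Hancock
resistive-force theory: slender-body tangential/normal drag coefficients,
instantaneous force and torque balance for the rigid-body motion, and
averaging over one beat for the mean path speed and lateral excursion.

Units in this module: µm, s, Pa·s.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np

from .flow_mechanics import MucusProperties

SLIDING_FORCE_NORMAL_UN = 2e-6       # µN, non-hyperactivated
SLIDING_FORCE_HYPER_UN = 5e-6        # µN, hyperactivated

#: force -> curvature gain, µm^-1 per µN (calibration: normal-mode
#: progressive speed lands in the physiological 25-50 µm/s range)
DEFAULT_KF = 7.0e4
DEFAULT_N_WAVES = 1.5                # wavelengths on the flagellum
DEFAULT_TORSION = 0.01               # µm^-1, small out-of-plane component
DEFAULT_BEAT_HZ = 10.0               # flagellar beat frequency
HYPER_ASYMMETRY = 0.02               # µm^-1 static curvature offset


@dataclass(frozen=True)
class SpermGeometry:
    head_length: float = 4.2
    head_width: float = 2.85
    head_tip: float = 0.46
    midpiece_length: float = 4.0
    midpiece_diameter: float = 1.0
    flagellum_length: float = 55.0
    flagellum_diameter_base: float = 1.0
    flagellum_diameter_tip: float = 0.1

    @property
    def mean_flagellum_radius(self) -> float:
        return 0.25 * (self.flagellum_diameter_base + self.flagellum_diameter_tip)

    @property
    def head_equivalent_radius(self) -> float:
        """Stokes-equivalent sphere radius of the prolate head (µm)."""
        a = 0.5 * self.head_length
        b = 0.5 * self.head_width
        return (a * b * b) ** (1.0 / 3.0)


@dataclass(frozen=True)
class DyneinMotorArray:
    n_motors: int = 100
    sliding_force: float = SLIDING_FORCE_NORMAL_UN   # µN
    positions: np.ndarray = field(default=None)      # arclength fractions

    def __post_init__(self):
        if self.n_motors < 10:
            raise ValueError("need at least 10 dynein motor sites")
        if self.positions is None:
            object.__setattr__(self, "positions",
                               (np.arange(self.n_motors) + 0.5) / self.n_motors)

    @classmethod
    def hyperactivated(cls, n_motors: int = 100) -> "DyneinMotorArray":
        return cls(n_motors=n_motors, sliding_force=SLIDING_FORCE_HYPER_UN)


@dataclass
class BeatPattern:
    """One full beat cycle of flagellar shapes in the body frame (base at
    the origin, base tangent +x)."""
    phases: np.ndarray                # (n_phases,)
    shapes: np.ndarray                # (n_phases, n_motors, 3), µm
    curvatures: np.ndarray            # (n_phases, n_motors), µm^-1
    beat_frequency: float
    flagellum_length: float
    asymmetry: float

    def arclengths(self) -> np.ndarray:
        """Polyline arclength of each phase's shape, µm."""
        d = np.diff(self.shapes, axis=1)
        seg = np.linalg.norm(d, axis=2).sum(axis=1)
        # the polyline starts at the base point, so add the leading segment
        first = np.linalg.norm(self.shapes[:, 0, :], axis=1)
        return seg + first


def motor_curvatures(motors: DyneinMotorArray, phase: float,
                     k_F: float = DEFAULT_KF, n_waves: float = DEFAULT_N_WAVES,
                     asymmetry: float = 0.0) -> np.ndarray:
    """Curvature at each motor site (µm^-1):
    kappa_i = k_F * F * sin(2*pi*n_waves*xi_i - phase) + kappa_asym.

    ``phase`` is the temporal beat phase: the curvature wave travels one
    wavelength base-to-tip per beat period, and the pattern is 2*pi-periodic
    in phase for any (non-integer) wave count."""
    xi = motors.positions
    return (k_F * motors.sliding_force
            * np.sin(2.0 * math.pi * n_waves * xi - phase)
            + asymmetry)


def _integrate_frenet(curv: np.ndarray, torsion: float, length: float) -> np.ndarray:
    """Integrate the Frenet-Serret frame along the flagellum for the given
    per-motor curvature samples; returns motor positions (n, 3).

    Each motor interval is subdivided; the frame is advanced with an
    explicit midpoint rule and re-orthonormalized (Gram-Schmidt) every
    step, so |T| = 1 holds and arclength is preserved by construction.
    """
    n = len(curv)
    sub = 4
    h = length / (n * sub)
    T = np.array([1.0, 0.0, 0.0])
    N = np.array([0.0, 1.0, 0.0])
    B = np.array([0.0, 0.0, 1.0])
    x = np.zeros(3)
    out = np.empty((n, 3))
    for i in range(n):
        k = curv[i]
        for _ in range(sub):
            dT = k * N
            dN = -k * T + torsion * B
            dB = -torsion * N
            Tm = T + 0.5 * h * dT
            Nm = N + 0.5 * h * dN
            Bm = B + 0.5 * h * dB
            T = T + h * k * Nm
            N = N + h * (-k * Tm + torsion * Bm)
            B = B + h * (-torsion * Nm)
            # Gram-Schmidt re-orthonormalization
            T /= np.linalg.norm(T)
            N -= T * (T @ N)
            N /= np.linalg.norm(N)
            B = np.cross(T, N)
            x = x + h * T
        out[i] = x
    return out


def beat_pattern(geometry: SpermGeometry, motors: DyneinMotorArray,
                 phase: float = 0.0, *, k_F: float = DEFAULT_KF,
                 n_waves: float = DEFAULT_N_WAVES,
                 torsion: float = DEFAULT_TORSION,
                 beat_frequency: float = DEFAULT_BEAT_HZ,
                 hyperactivated: bool = False,
                 n_phases: int = 1) -> BeatPattern:
    """Flagellar beat shapes from dynein sliding forces.

    With ``n_phases = 1`` a single phase sample is produced; larger
    ``n_phases`` tabulates a full beat cycle for the propulsion
    calculation.
    """
    if geometry.flagellum_length <= 0:
        raise ValueError("flagellum length must be positive")
    asym = HYPER_ASYMMETRY if hyperactivated else 0.0
    phases = phase + 2.0 * math.pi * np.arange(n_phases) / max(n_phases, 1)
    shapes = np.empty((len(phases), motors.n_motors, 3))
    curvs = np.empty((len(phases), motors.n_motors))
    for j, ph in enumerate(phases):
        curvs[j] = motor_curvatures(motors, ph, k_F=k_F, n_waves=n_waves,
                                    asymmetry=asym)
        shapes[j] = _integrate_frenet(curvs[j], torsion, geometry.flagellum_length)
    return BeatPattern(phases=phases, shapes=shapes, curvatures=curvs,
                       beat_frequency=beat_frequency,
                       flagellum_length=geometry.flagellum_length,
                       asymmetry=asym)


def drag_coefficients(geometry: SpermGeometry, viscosity: float
                      ) -> tuple[float, float]:
    """Gray-Hancock tangential/normal drag coefficients (force per length
    per speed) for the flagellum."""
    a = geometry.mean_flagellum_radius
    L = geometry.flagellum_length
    log = math.log(2.0 * L / a)
    C_t = 2.0 * math.pi * viscosity / (log - 0.5)
    C_n = 4.0 * math.pi * viscosity / (log + 0.5)
    return C_t, C_n


@dataclass(frozen=True)
class Propulsion:
    mean_path_speed: float      # µm/s along the net displacement direction
    lateral_excursion: float    # µm, half peak-to-peak transverse motion
    turning_rate: float         # rad/s mean body rotation


def propulsion_velocity(pattern: BeatPattern, mucus: MucusProperties,
                        geometry: SpermGeometry | None = None,
                        include_head: bool = True,
                        shear_rate: float = 0.0,
                        n_beats: int = 4) -> Propulsion:
    """Swimming velocity of the beat cycle via resistive-force theory.

    At each phase the instantaneous rigid-body motion (Ux, Uy, Omega) in
    the beat plane is solved from zero net force and torque; the body
    trajectory is then integrated over ``n_beats`` cycles and summarized
    as mean path speed, lateral excursion, and mean turning rate.
    """
    geometry = geometry or SpermGeometry()
    visc = mucus.viscosity(shear_rate)
    C_t, C_n = drag_coefficients(geometry, visc)

    n_phases = len(pattern.phases)
    if n_phases < 8:
        raise ValueError("propulsion needs a tabulated cycle (n_phases >= 8)")
    period = 1.0 / pattern.beat_frequency
    dt = period / n_phases
    xy = pattern.shapes[:, :, :2]                       # planar projection
    # shape-change velocity in the body frame. The mean swimming speed is
    # second order in beat amplitude, so the differentiation in phase must
    # be spectral: finite differences leave O(h^2) noise comparable to the
    # drift itself at small amplitude.
    omega_beat = 2.0 * math.pi / period
    fhat = np.fft.rfft(xy, axis=0)
    wavenum = np.arange(fhat.shape[0])
    v_shape = np.fft.irfft(1j * wavenum[:, None, None] * fhat, n=n_phases,
                           axis=0) * omega_beat
    seg = pattern.flagellum_length / pattern.shapes.shape[1]

    head_r = geometry.head_equivalent_radius
    head_x = np.array([-(geometry.midpiece_length + 0.5 * geometry.head_length), 0.0])
    head_trans = 6.0 * math.pi * visc * head_r if include_head else 0.0
    head_rot = 8.0 * math.pi * visc * head_r**3 if include_head else 0.0

    # lab-frame trajectory of the body origin
    pos = np.zeros(2)
    psi = 0.0
    traj = np.empty((n_beats * n_phases, 2))
    omegas = np.empty(n_beats * n_phases)
    for step in range(n_beats * n_phases):
        j = step % n_phases
        x = xy[j]                                       # (n, 2)
        tang = np.empty_like(x)
        tang[1:] = x[1:] - x[:-1]
        tang[0] = x[0]                                   # base segment from origin
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)

        # velocity of segment i: U + Omega x r + v_shape; unknown q = (Ux, Uy, Om)
        # drag matrix per segment: D = C_t t t^T + C_n (I - t t^T)
        tt = tang[:, :, None] * tang[:, None, :]
        D = C_n * (np.eye(2)[None] - tt) + C_t * tt      # (n, 2, 2)
        rx, ry = x[:, 0], x[:, 1]
        # A q = b with A = sum of drag couplings, b = -sum D v_shape terms
        A = np.zeros((3, 3))
        b = np.zeros(3)
        rot = np.stack([-ry, rx], axis=1)                # Omega x r (2D)
        A[:2, :2] = seg * D.sum(axis=0)
        Drot = seg * np.einsum("nij,nj->ni", D, rot)
        A[:2, 2] = Drot.sum(axis=0)
        Dv = seg * np.einsum("nij,nj->ni", D, v_shape[j])
        b[:2] = -Dv.sum(axis=0)
        # torque rows: sum r x (D (U + Om x r + v_shape))
        DU = seg * D                                      # coupling to U
        A[2, 0] = (rx * DU[:, 1, 0] - ry * DU[:, 0, 0]).sum()
        A[2, 1] = (rx * DU[:, 1, 1] - ry * DU[:, 0, 1]).sum()
        A[2, 2] = (rx * Drot[:, 1] - ry * Drot[:, 0]).sum()
        b[2] = -(rx * Dv[:, 1] - ry * Dv[:, 0]).sum()
        if include_head:
            A[0, 0] += head_trans
            A[1, 1] += head_trans
            A[0, 2] += head_trans * (-head_x[1])
            A[1, 2] += head_trans * head_x[0]
            A[2, 0] += head_trans * (-head_x[1])
            A[2, 1] += head_trans * head_x[0]
            A[2, 2] += head_trans * (head_x @ head_x) + head_rot
        Ux, Uy, Om = np.linalg.solve(A, b)

        pm = psi + 0.5 * dt * Om     # midpoint orientation for the push
        c, s_ = math.cos(pm), math.sin(pm)
        pos = pos + dt * np.array([c * Ux - s_ * Uy, s_ * Ux + c * Uy])
        psi += dt * Om
        traj[step] = pos
        omegas[step] = Om

    disp = traj[-1] - traj[0]
    mean_speed = float(np.linalg.norm(disp) / (n_beats * period))
    # lateral excursion: half peak-to-peak deviation from the mean path line
    if np.linalg.norm(disp) > 1e-12:
        e = disp / np.linalg.norm(disp)
        lateral = traj @ np.array([-e[1], e[0]])
    else:
        lateral = traj[:, 1]
    excursion = float(0.5 * (lateral.max() - lateral.min()))
    return Propulsion(mean_path_speed=mean_speed, lateral_excursion=excursion,
                      turning_rate=float(np.mean(omegas)))


@functools.lru_cache(maxsize=16)
def mode_propulsion(mucus: MucusProperties | None = None,
                    geometry: SpermGeometry | None = None,
                    beat_frequency: float = DEFAULT_BEAT_HZ,
                    k_F: float = DEFAULT_KF,
                    n_phases: int = 32) -> dict[str, Propulsion]:
    """Propulsion summary for the normal and hyperactivated modes at the
    default beat parameters (used by the transport engine). Cached: the
    frozen-dataclass arguments hash by value."""
    mucus = mucus or MucusProperties()
    geometry = geometry or SpermGeometry()
    out = {}
    for name, motors, hyper in (
            ("normal", DyneinMotorArray(), False),
            ("hyperactivated", DyneinMotorArray.hyperactivated(), True)):
        pat = beat_pattern(geometry, motors, hyperactivated=hyper,
                           beat_frequency=beat_frequency, k_F=k_F,
                           n_phases=n_phases)
        out[name] = propulsion_velocity(pat, mucus, geometry)
    return out
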