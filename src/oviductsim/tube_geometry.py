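"""Parametric 3D fallopian-tube models for three age groups.

The tube is described on a 1D arclength backbone ``s`` running from the
uterine (intramural) end at ``s = 0`` to the fimbrial (infundibulum) end at
``s = L``, with azimuth ``theta`` about the centerline. Four portions tile
the backbone in anatomical order — intramural, isthmus, ampulla,
infundibulum — each with a linearly interpolated resting radius.
Longitudinal mucosal folds are a sinusoidal inward perturbation of the
radius; endometriosis lesions are elliptical luminal protrusions (10 x 5 mm
footprint) that locally narrow the lumen.

Age enters through total length (tubes shorten with age), a radius scale
(the lumen narrows as the muscle layer stiffens), reduced fold depth
(columnar-to-cuboidal mucosal change), and ciliated-cell density
(2000 / 1600 / 1400 per mm^2 for the 20s / 30s / 40s groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

AGE_GROUPS = ("20s", "30s", "40s")
REGION_ORDER = ("intramural", "isthmus", "ampulla", "infundibulum")

#: ciliated-cell density per age group, mm^-2
CILIA_DENSITY = {"20s": 2000.0, "30s": 1600.0, "40s": 1400.0}

#: total tube length per age group, mm (within the anatomical 85-105 mm range)
TOTAL_LENGTH = {"20s": 105.0, "30s": 95.0, "40s": 85.0}

#: lumen radius scale per age group (aging narrows the inner diameter)
RADIUS_SCALE = {"20s": 1.0, "30s": 0.95, "40s": 0.90}

#: mucosal fold depth per age group, mm
FOLD_DEPTH = {"20s": 0.10, "30s": 0.08, "40s": 0.06}

#: fraction of total length per region (intramural, isthmus, ampulla, infundibulum)
REGION_FRACTIONS = (0.08, 0.20, 0.62, 0.10)

#: resting radius (mm) at region start/end for the 20s reference tube
BASE_RADII = {
    "intramural": (1.45, 1.60),
    "isthmus": (1.60, 1.80),
    "ampulla": (1.80, 3.40),
    "infundibulum": (3.40, 2.80),
}

LESION_LENGTH_MM = 10.0   # major axis, along the tube
LESION_WIDTH_MM = 5.0     # minor axis, circumferential
DEFAULT_PROTRUSION_FRACTION = 0.40  # of the local resting radius


@dataclass(frozen=True)
class RegionSpec:
    name: str
    start_s: float
    end_s: float
    radius_start: float
    radius_end: float
    fold_count: int = 6
    fold_depth: float = 0.0

    def __post_init__(self):
        if self.name not in REGION_ORDER:
            raise ValueError(f"unknown region name {self.name!r}")
        if not self.start_s < self.end_s:
            raise ValueError("region must have start_s < end_s")
        if min(self.radius_start, self.radius_end) <= 0:
            raise ValueError("region radii must be positive")

    @property
    def length(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Lesion:
    id: int
    center_s: float
    azimuth: float
    length: float = LESION_LENGTH_MM
    width: float = LESION_WIDTH_MM
    protrusion: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.azimuth < 2.0 * math.pi:
            raise ValueError("azimuth must lie in [0, 2*pi)")
        if self.length <= 0 or self.width <= 0 or self.protrusion < 0:
            raise ValueError("lesion dimensions must be positive")


@dataclass(frozen=True)
class CurvatureProfile:
    """Centerline curvature vs arclength: straight proximal tube, sinusoidal
    convolutions confined to the ampulla."""

    amplitude: float = 0.08   # mm^-1
    n_turns: int = 3

    def kappa(self, s, ampulla_start: float, ampulla_end: float):
        s = np.asarray(s, dtype=float)
        span = ampulla_end - ampulla_start
        inside = (s >= ampulla_start) & (s <= ampulla_end)
        phase = 2.0 * math.pi * self.n_turns * (s - ampulla_start) / span
        return np.where(inside, self.amplitude * np.sin(phase), 0.0)


@dataclass(frozen=True)
class TubeModel:
    age_group: str
    total_length_L: float
    regions: tuple[RegionSpec, ...]
    lesions: tuple[Lesion, ...] = ()
    cilia_density: float = 2000.0
    curvature_profile: CurvatureProfile = field(default_factory=CurvatureProfile)

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if not 85.0 <= self.total_length_L <= 105.0:
            raise ValueError("total length must lie in the 85-105 mm range")
        names = tuple(r.name for r in self.regions)
        if names != REGION_ORDER:
            raise ValueError(f"regions must be ordered {REGION_ORDER}, got {names}")
        if abs(self.regions[0].start_s) > 1e-12:
            raise ValueError("first region must start at s = 0")
        for a, b in zip(self.regions, self.regions[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError("regions must tile [0, L] without gaps or overlap")
        if abs(self.regions[-1].end_s - self.total_length_L) > 1e-9:
            raise ValueError("regions must end exactly at total_length_L")
        for les in self.lesions:
            if not 0.0 <= les.center_s <= self.total_length_L:
                raise ValueError(f"lesion {les.id} center outside [0, L]")

    # -- region helpers ---------------------------------------------------
    def region(self, name: str) -> RegionSpec:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def ampulla(self) -> RegionSpec:
        return self.region("ampulla")

    # -- geometric queries ------------------------------------------------
    def resting_radius(self, s):
        """Piecewise-linear fold-free resting radius r0(s), mm."""
        s = np.asarray(s, dtype=float)
        if np.any((s < -1e-9) | (s > self.total_length_L + 1e-9)):
            raise ValueError("arclength s outside [0, L]")
        out = np.empty_like(s, dtype=float)
        out.fill(np.nan)
        for r in self.regions:
            # include both boundaries; later regions overwrite shared edges
            # with an identical value (profile is continuous)
            m = (s >= r.start_s - 1e-9) & (s <= r.end_s + 1e-9)
            frac = np.clip((s - r.start_s) / r.length, 0.0, 1.0)
            out = np.where(m, r.radius_start + frac * (r.radius_end - r.radius_start), out)
        return out

    def _fold_term(self, s, theta):
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        depth = np.zeros_like(s)
        count = np.zeros_like(s)
        for r in self.regions:
            m = (s >= r.start_s - 1e-9) & (s <= r.end_s + 1e-9)
            depth = np.where(m, r.fold_depth, depth)
            count = np.where(m, r.fold_count, count)
        return depth * 0.5 * (1.0 + np.cos(count * theta))

    def _lesion_encroachment(self, s, theta):
        """Radial encroachment (mm) of all lesions at (s, theta): an
        elliptic-paraboloid bump of height ``protrusion`` over the printed
        10 x 5 mm footprint."""
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        enc = np.zeros(np.broadcast(s, theta).shape)
        if not self.lesions:
            return enc
        r0 = self.resting_radius(s)
        for les in self.lesions:
            ds = (s - les.center_s) / (0.5 * les.length)
            dth = np.angle(np.exp(1j * (theta - les.azimuth)))
            darc = dth * r0 / (0.5 * les.width)
            bump = 1.0 - ds**2 - darc**2
            enc = enc + les.protrusion * np.clip(bump, 0.0, None)
        return enc

    def local_radius(self, s, theta, t: float = 0.0):
        """Resting luminal radius at (s, theta), mm: region interpolation
        minus mucosal folds minus lesion encroachment. Time-dependent wall
        motion is handled by the flow model on top of this resting value."""
        r = self.resting_radius(s) - self._fold_term(s, theta) \
            - self._lesion_encroachment(s, theta)
        if np.any(r <= 0):
            raise ValueError("non-positive luminal radius; check lesion protrusion")
        return r

    def luminal_area(self, s, n_theta: int = 256):
        """Open cross-sectional area at s, mm^2 (trapezoid over theta,
        spectrally accurate for the periodic integrand)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
        r = self.local_radius(s[:, None], theta[None, :])
        area = 0.5 * np.mean(r**2, axis=1) * 2.0 * math.pi
        return area if area.size > 1 else float(area[0])

    def min_open_radius(self, s, theta_samples: int = 64):
        """Narrowest radius over theta at each s (squeeze-through bound)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        theta = np.linspace(0.0, 2.0 * math.pi, theta_samples, endpoint=False)
        r = self.local_radius(s[:, None], theta[None, :])
        out = r.min(axis=1)
        return out if out.size > 1 else float(out[0])

    # -- centerline -------------------------------------------------------
    def centerline(self, s):
        """3D centerline points (mm): planar curve whose curvature follows
        the convolution profile (ampulla only); +x is the tube axis in the
        straight limit."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        grid = np.linspace(0.0, self.total_length_L, 2048)
        amp = self.ampulla
        kap = self.curvature_profile.kappa(grid, amp.start_s, amp.end_s)
        h = grid[1] - grid[0]
        phi = np.concatenate([[0.0], np.cumsum(0.5 * (kap[1:] + kap[:-1]) * h)])
        x = np.concatenate([[0.0], np.cumsum(0.5 * (np.cos(phi)[1:] + np.cos(phi)[:-1]) * h)])
        y = np.concatenate([[0.0], np.cumsum(0.5 * (np.sin(phi)[1:] + np.sin(phi)[:-1]) * h)])
        xi = np.interp(s, grid, x)
        yi = np.interp(s, grid, y)
        phii = np.interp(s, grid, phi)
        pts = np.stack([xi, yi, np.zeros_like(xi)], axis=-1)
        return pts, phii


def _lesion_layout(tube_L: float, regions: dict, lesion_count: int) -> list[tuple[float, float]]:
    """(center_s, azimuth) pairs for the canonical layouts.

    Five lesions: one centered in the isthmus and four equidistant in the
    ampulla with consecutive spacing exactly 17 mm, alternating sides.
    The 3/7/10-lesion variants keep one (or two) isthmic lesions and spread
    the remainder across the ampulla.
    """
    isth, amp = regions["isthmus"], regions["ampulla"]
    isth_mid = 0.5 * (isth.start_s + isth.end_s)
    amp_mid = 0.5 * (amp.start_s + amp.end_s)
    if lesion_count == 0:
        return []
    if lesion_count == 3:
        centers = [isth_mid, amp_mid - 8.5, amp_mid + 8.5]
    elif lesion_count == 5:
        centers = [isth_mid] + [amp_mid + off for off in (-25.5, -8.5, 8.5, 25.5)]
    elif lesion_count == 7:
        amp_centers = np.linspace(amp.start_s + 0.08 * amp.length,
                                  amp.end_s - 0.08 * amp.length, 6)
        centers = [isth_mid] + list(amp_centers)
    elif lesion_count == 10:
        amp_centers = np.linspace(amp.start_s + 0.06 * amp.length,
                                  amp.end_s - 0.06 * amp.length, 8)
        centers = [isth_mid - 0.2 * isth.length, isth_mid + 0.2 * isth.length] \
            + list(amp_centers)
    else:
        raise ValueError("lesion_count must be one of {0, 3, 5, 7, 10}")
    return [(float(c), 0.0 if i % 2 == 0 else math.pi) for i, c in enumerate(centers)]


def build_tube(age_group: str, with_endometriosis: bool = False,
               lesion_count: int = 5, overrides: dict | None = None) -> TubeModel:
    """Build a validated canonical tube model for one age group.

    ``overrides`` may replace ``total_length``, ``radius_scale``,
    ``fold_depth``, ``fold_count``, ``cilia_density``, ``protrusion_fraction``,
    ``region_fractions``, ``curvature_amplitude`` or supply an explicit
    ``lesions`` list of (center_s, azimuth) pairs.
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}; expected one of {AGE_GROUPS}")
    ov = dict(overrides or {})
    L = float(ov.pop("total_length", TOTAL_LENGTH[age_group]))
    rscale = float(ov.pop("radius_scale", RADIUS_SCALE[age_group]))
    fdepth = float(ov.pop("fold_depth", FOLD_DEPTH[age_group]))
    fcount = int(ov.pop("fold_count", 6))
    density = float(ov.pop("cilia_density", CILIA_DENSITY[age_group]))
    pfrac = float(ov.pop("protrusion_fraction", DEFAULT_PROTRUSION_FRACTION))
    fractions = tuple(ov.pop("region_fractions", REGION_FRACTIONS))
    camp = float(ov.pop("curvature_amplitude", 0.08))
    lesion_spec = ov.pop("lesions", None)
    if ov:
        raise ValueError(f"unknown overrides: {sorted(ov)}")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 4:
        raise ValueError("region_fractions must be 4 values summing to 1")

    bounds = np.concatenate([[0.0], np.cumsum(np.asarray(fractions) * L)])
    bounds[-1] = L
    regions = tuple(
        RegionSpec(name=name, start_s=float(bounds[i]), end_s=float(bounds[i + 1]),
                   radius_start=BASE_RADII[name][0] * rscale,
                   radius_end=BASE_RADII[name][1] * rscale,
                   fold_count=fcount, fold_depth=fdepth)
        for i, name in enumerate(REGION_ORDER))
    region_map = {r.name: r for r in regions}

    if not with_endometriosis:
        lesions: tuple[Lesion, ...] = ()
    else:
        layout = (list(lesion_spec) if lesion_spec is not None
                  else _lesion_layout(L, region_map, lesion_count))
        base = TubeModel(age_group=age_group, total_length_L=L, regions=regions,
                         cilia_density=density,
                         curvature_profile=CurvatureProfile(amplitude=camp))
        lesions = tuple(
            Lesion(id=i + 1, center_s=c, azimuth=az,
                   protrusion=pfrac * float(base.resting_radius(c)))
            for i, (c, az) in enumerate(layout))

    return TubeModel(age_group=age_group, total_length_L=L, regions=regions,
                     lesions=lesions, cilia_density=density,
                     curvature_profile=CurvatureProfile(amplitude=camp))


def without_lesions(tube: TubeModel) -> TubeModel:
    """The same tube with all lesions removed (nullification oracle)."""
    return replace(tube, lesions=())


def export_mesh(tube: TubeModel, resolution: int = 32, path: str | None = None):
    """Triangulated, capped (watertight) tube surface in mm.

    ``resolution`` sets the azimuthal vertex count; the axial count scales
    with it. Written to OBJ or PLY when ``path`` is given (by extension);
    the trimesh object is returned either way.
    """
    import trimesh

    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    n_theta = int(resolution)
    n_s = int(resolution * 6)
    s = np.linspace(0.0, tube.total_length_L, n_s)
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    pts, phi = tube.centerline(s)
    normal = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=-1)
    binormal = np.array([0.0, 0.0, 1.0])[None, :]
    r = tube.local_radius(s[:, None], theta[None, :])
    verts = (pts[:, None, :]
             + r[:, :, None] * (np.cos(theta)[None, :, None] * normal[:, None, :]
                                + np.sin(theta)[None, :, None] * binormal[None, :, :]))
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_s - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps: fan to the centerline point
    verts = np.vstack([verts, pts[0], pts[-1]])
    c0, c1 = len(verts) - 2, len(verts) - 1
    for j in range(n_theta):
        faces.append((c0, (j + 1) % n_theta, j))
        base = (n_s - 1) * n_theta
        faces.append((c1, base + j, base + (j + 1) % n_theta))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if not mesh.is_watertight:
        raise RuntimeError("generated tube mesh is not watertight (degenerate geometry)")
    if path is not None:
        mesh.export(path)
    return mesh
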