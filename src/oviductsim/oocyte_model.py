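"""Passive-sphere oocyte model.

The oocyte is advected by the peristalsis-ciliary mucus flow as a rigid
sphere: zona pellucida 0.12 mm diameter inside a corona radiata shell of
0.4 mm that sheds about 12 h after ovulation, leaving the bare zona for
the remainder of the 80 h tracking window. The corona's cumulus cells
also roughen the surface, raising the probability of sticking to the
mucosal wall until shedding. Elasticity (10 ± 5 kPa) does not alter the
rigid-sphere advection; it sets how much the oocyte can squeeze through a
lesion-narrowed section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow_mechanics import MucusProperties

CORONA_SHED_TIME_H = 12.0
ZONA_DIAMETER_MM = 0.12
CORONA_DIAMETER_MM = 0.4
ELASTICITY_KPA = 10.0


@dataclass(frozen=True)
class OocyteModel:
    zona_diameter: float = ZONA_DIAMETER_MM        # mm
    corona_diameter: float = CORONA_DIAMETER_MM    # mm
    corona_shed_time: float = CORONA_SHED_TIME_H   # h
    elasticity: float = ELASTICITY_KPA             # kPa, 10 +/- 5 configurable
    corona_roughness: float = 2.0                  # sticking multiplier pre-shed
    hindrance_exponent: float = 1.5
    squeeze_tolerance: float = 0.2                 # epsilon at reference elasticity
    fertilized: bool = False                       # bookkeeping only

    def __post_init__(self):
        if not 0 < self.zona_diameter < self.corona_diameter:
            raise ValueError("need 0 < zona_diameter < corona_diameter")
        if self.elasticity <= 0 or self.corona_shed_time < 0:
            raise ValueError("elasticity and shed time must be positive")

    def effective_diameter(self, t_h):
        """Diameter (mm) at time t (hours): corona before shedding, bare
        zona after."""
        t_h = np.asarray(t_h, dtype=float)
        out = np.where(t_h < self.corona_shed_time,
                       self.corona_diameter, self.zona_diameter)
        return float(out) if out.ndim == 0 else out

    def roughness_factor(self, t_h):
        """Sticking-probability multiplier: corona_roughness (> 1) while the
        corona radiata is attached, 1 after shedding."""
        t_h = np.asarray(t_h, dtype=float)
        if np.any(t_h < 0):
            raise ValueError("time must be non-negative")
        out = np.where(t_h < self.corona_shed_time, self.corona_roughness, 1.0)
        return float(out) if out.ndim == 0 else out

    def hindrance(self, local_tube_diameter, t_h):
        """Wall-hindrance mobility factor H(d/D) in (0, 1]:
        H = (1 - (d/D)^2)^p, a standard confined-sphere mobility shape."""
        d = self.effective_diameter(t_h)
        D = np.asarray(local_tube_diameter, dtype=float)
        ratio = d / D
        if np.any(ratio >= 1.0):
            raise OcclusionError("oocyte larger than the local lumen")
        out = (1.0 - ratio**2) ** self.hindrance_exponent
        return float(out) if out.ndim == 0 else out

    def squeeze_limit(self, t_h) -> float:
        """Largest open diameter deficit the oocyte can squeeze through:
        passes a constriction of open diameter D_open if
        d <= D_open * (1 + eps), with eps shrinking as elasticity rises."""
        eps = self.squeeze_tolerance * (ELASTICITY_KPA / self.elasticity)
        d = self.effective_diameter(t_h)
        return d / (1.0 + eps)


class OcclusionError(ValueError):
    """The oocyte cannot fit through the local lumen (mechanical occlusion)."""


def drag_velocity(oocyte: OocyteModel, local_flow, mucus: MucusProperties,
                  t_h, local_tube_diameter):
    """Advection velocity (mm/s) of the oocyte in the local flow: the flow
    velocity reduced by the wall-hindrance factor. Raises
    :class:`OcclusionError` when the oocyte is larger than the lumen."""
    H = oocyte.hindrance(local_tube_diameter, t_h)
    return H * np.asarray(local_flow, dtype=float)
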