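"""Channel geometry, fluid properties, and bulk flow quantities.

The sorting device is a serpentine of rectangular curved ducts.  Everything
downstream (lift forces, Dean drag, outlet assignment) is parameterised by a
handful of dimensionless and bulk quantities derived here:

* hydraulic diameter ``Dh = 2wh/(w+h)`` of the rectangular cross-section,
* mean axial velocity ``U = Q/(wh)``,
* channel Reynolds number ``Re = rho*U*Dh/mu``,
* Dean number ``De = Re*sqrt(Dh/(2R))`` for radius of curvature ``R``,
* wall shear stress ``tau = 6*mu*Q/(w*h^2)`` (parallel-plate limit, apt for
  the device's 0.165 aspect ratio).

Geometry is stored in micrometres and converted to SI once, at construction;
all stresses and forces are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import InvalidGeometryError

#: Conversion: 1 uL/min in m^3/s.
UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0

#: Shear stress (Pa) above which yeast begin to suffer mechanical damage.
DAMAGE_THRESHOLD_PA = 1292.0


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular curved duct.

    Parameters
    ----------
    width_um : float
        Lateral (radial) width ``w`` of the duct in micrometres.
    height_um : float
        Height ``h`` in micrometres.
    radius_um : float
        Radius of curvature ``R`` of the arc centreline in micrometres.
        ``math.inf`` denotes a straight channel.
    n_arcs : int
        Number of half-circle arcs in the serpentine.
    n_outlets : int
        Number of exit ports at the drainage cone.
    """

    width_um: float = 200.0
    height_um: float = 33.0
    radius_um: float = 900.0
    n_arcs: int = 4
    n_outlets: int = 5

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise InvalidGeometryError(
                f"duct dimensions must be positive, got w={self.width_um}, h={self.height_um}"
            )
        if not self.radius_um > self.width_um / 2:
            raise InvalidGeometryError(
                f"radius of curvature ({self.radius_um} um) must exceed half the width"
            )
        if self.n_outlets < 1:
            raise InvalidGeometryError("need at least one outlet")

    # SI accessors
    @property
    def width_m(self) -> float:
        return self.width_um * 1e-6

    @property
    def height_m(self) -> float:
        return self.height_um * 1e-6

    @property
    def radius_m(self) -> float:
        return self.radius_um * 1e-6

    @property
    def cross_section_m2(self) -> float:
        return self.width_m * self.height_m

    @property
    def hydraulic_diameter_um(self) -> float:
        return hydraulic_diameter(self)


@dataclass(frozen=True)
class Fluid:
    """Newtonian carrier fluid. Defaults are water near 20 C.

    The default dynamic viscosity (0.9983e-3 Pa s, i.e. a kinematic
    viscosity of 1.0003e-6 m^2/s, water at ~20.2 C) is the value under
    which the device's two reported operating points round to the reported
    Reynolds numbers.
    """

    density: float = 998.0          # kg/m^3
    dynamic_viscosity: float = 0.9983e-3  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise InvalidGeometryError("fluid density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


#: Module-wide default fluid.
WATER = Fluid()


def hydraulic_diameter(geom: ChannelGeometry) -> float:
    """Hydraulic diameter ``2wh/(w+h)`` of the duct, in micrometres.

    Symmetric under swapping width and height.
    """
    w, h = geom.width_um, geom.height_um
    return 2.0 * w * h / (w + h)


def mean_velocity(q_ul_min: float, geom: ChannelGeometry) -> float:
    """Mean axial velocity ``U = Q/(w h)`` in m/s."""
    if q_ul_min < 0:
        raise ValueError("flow rate must be non-negative")
    return q_ul_min * UL_PER_MIN_TO_M3_PER_S / geom.cross_section_m2


def reynolds(q_ul_min: float, geom: ChannelGeometry, fluid: Fluid = WATER) -> float:
    """Channel Reynolds number ``Re = rho U Dh / mu``.

    Linear in Q at fixed geometry and fluid.  Full precision is returned;
    round to integer for report-style summaries.
    """
    u = mean_velocity(q_ul_min, geom)
    dh = hydraulic_diameter(geom) * 1e-6
    return fluid.density * u * dh / fluid.dynamic_viscosity


def dean_number(q_ul_min: float, geom: ChannelGeometry, fluid: Fluid = WATER) -> float:
    """Dean number ``De = Re sqrt(Dh / 2R)``; 0 for a straight channel (R = inf)."""
    if math.isinf(geom.radius_um):
        return 0.0
    if geom.radius_um <= 0:
        raise InvalidGeometryError("radius of curvature must be positive")
    re = reynolds(q_ul_min, geom, fluid)
    dh = hydraulic_diameter(geom)
    return re * math.sqrt(dh / (2.0 * geom.radius_um))


class WallShear(NamedTuple):
    tau_pa: float
    below_damage_threshold: bool


def wall_shear_stress(
    q_ul_min: float,
    geom: ChannelGeometry,
    fluid: Fluid = WATER,
    damage_threshold_pa: float = DAMAGE_THRESHOLD_PA,
) -> WallShear:
    """Wall shear stress ``tau = 6 mu Q / (w h^2)`` (Pa) and a damage flag.

    The parallel-plate approximation is appropriate for shallow ducts
    (h << w).  The flag reports whether the stress stays below the damage
    threshold for yeast (default 1292 Pa).
    """
    if q_ul_min < 0:
        raise ValueError("flow rate must be non-negative")
    q = q_ul_min * UL_PER_MIN_TO_M3_PER_S
    tau = 6.0 * fluid.dynamic_viscosity * q / (geom.width_m * geom.height_m**2)
    return WallShear(tau, tau < damage_threshold_pa)


@dataclass(frozen=True)
class FlowCondition:
    """A volumetric flow rate through a given duct and fluid.

    All derived quantities are recomputed from (Q, geometry, fluid) and
    never set independently.
    """

    q_ul_min: float
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    fluid: Fluid = WATER

    def __post_init__(self) -> None:
        if self.q_ul_min < 0:
            raise ValueError("flow rate must be non-negative")

    @property
    def mean_velocity(self) -> float:
        return mean_velocity(self.q_ul_min, self.geometry)

    @property
    def hydraulic_diameter_um(self) -> float:
        return hydraulic_diameter(self.geometry)

    @property
    def reynolds(self) -> float:
        return reynolds(self.q_ul_min, self.geometry, self.fluid)

    @property
    def dean(self) -> float:
        return dean_number(self.q_ul_min, self.geometry, self.fluid)

    @property
    def wall_shear(self) -> WallShear:
        return wall_shear_stress(self.q_ul_min, self.geometry, self.fluid)

    def summary(self) -> dict:
        """Bulk quantities as a plain dict (units in key names)."""
        ws = self.wall_shear
        return {
            "q_ul_min": self.q_ul_min,
            "hydraulic_diameter_um": self.hydraulic_diameter_um,
            "mean_velocity_m_s": self.mean_velocity,
            "reynolds": self.reynolds,
            "dean": self.dean,
            "wall_shear_pa": ws.tau_pa,
            "below_damage_threshold": ws.below_damage_threshold,
        }
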