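"""Axisymmetric vault / silo geometry and ray-to-boundary queries.

Coordinates: the cylinder axis is the z-axis, z measured in metres above the
outside ground plane (z = 0).  The isocenter, when one exists, sits on the
axis at ``z = isocenter_height``.  Regions are

* ``ground``       — the half-space z < 0 (concrete by default);
* ``wall``         — the annulus  d_w - wall_thickness < r <= d_w between the
                     floor and the roof underside;
* ``roof``         — the slab r <= d_w, roof_z0 < z <= roof_z1 (if any);
* ``interior-air`` — the cavity inside the wall below the roof;
* ``air``          — everywhere else, up to a world cylinder far beyond all
                     tallies where photons are terminated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

_EPS = 1e-9


@dataclass(frozen=True)
class CylinderShieldGeometry:
    """Cylindrically symmetric shield: wall annulus, roof slab, ground."""

    d_w: float                    # outer wall radius from the axis, m
    wall_thickness: float         # radial wall thickness, m
    h: float                      # isocenter (or source datum) to roof top, m
    t_r: float = 0.0              # roof slab thickness, m
    isocenter_height: float = 1.3  # isocenter above outside grade, m
    roof_on_top: bool = False     # slab added above z = isocenter_height + h
    world_radius: float = 2000.0
    world_height: float = 2000.0
    ground_depth: float = -1.0    # photons deeper than this are terminated
    wall_material: str = "concrete"
    roof_material: str = "concrete"
    ground_material: str = "concrete"

    def __post_init__(self):
        if not (0.0 < self.wall_thickness <= self.d_w):
            raise ValueError("need 0 < wall_thickness <= d_w")
        if self.t_r < 0:
            raise ValueError("roof thickness must be >= 0")

    # -- derived elevations (m above outside grade) -----------------------
    @property
    def roof_top(self) -> float:
        top = self.isocenter_height + self.h
        return top + self.t_r if self.roof_on_top else top

    @property
    def roof_bottom(self) -> float:
        return self.roof_top - self.t_r

    @property
    def wall_top(self) -> float:
        return self.roof_bottom

    wall_base: float = 0.0

    @classmethod
    def vault(cls, d_w: float, h: float, t_r: float = 0.0,
              wall_thickness: float = 1.5, isocenter_height: float = 1.3,
              **kw) -> "CylinderShieldGeometry":
        """Nominal linac vault: isocenter 1.3 m above grade, 1.5 m side walls."""
        return cls(d_w=d_w, wall_thickness=wall_thickness, h=h, t_r=t_r,
                   isocenter_height=isocenter_height, **kw)

    @classmethod
    def silo(cls, outer_radius: float = 2.16, wall_thickness: float = 0.91,
             height: float = 2.3, lid_thickness: float = 0.0,
             **kw) -> "CylinderShieldGeometry":
        """Benchmark silo: hollow concrete cylinder, optional lid on top."""
        return cls(d_w=outer_radius, wall_thickness=wall_thickness,
                   h=height, t_r=lid_thickness, isocenter_height=0.0,
                   roof_on_top=True, **kw)

    def with_(self, **kw) -> "CylinderShieldGeometry":
        return replace(self, **kw)

    # -- queries ----------------------------------------------------------
    def region_at(self, point) -> str:
        x, y, z = float(point[0]), float(point[1]), float(point[2])
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise ValueError("non-finite point")
        r = math.hypot(x, y)
        if z < 0.0:
            return "ground"
        if self.t_r > 0.0 and r <= self.d_w and self.roof_bottom < z <= self.roof_top:
            return "roof"
        if (self.d_w - self.wall_thickness < r <= self.d_w
                and self.wall_base <= z <= self.wall_top):
            return "wall"
        if r <= self.d_w - self.wall_thickness and z <= self.wall_top:
            return "interior-air"
        return "air"

    def material_at(self, point) -> str:
        return {"ground": self.ground_material, "wall": self.wall_material,
                "roof": self.roof_material, "air": "air",
                "interior-air": "air"}[self.region_at(point)]

    def _plane_heights(self):
        zs = [0.0, self.wall_base, self.wall_top, self.ground_depth,
              self.world_height]
        if self.t_r > 0.0:
            zs += [self.roof_bottom, self.roof_top]
        return zs

    def _cyl_radii(self):
        return [self.d_w - self.wall_thickness, self.d_w, self.world_radius]

    def distance_to_boundary(self, point, direction) -> tuple[float, str]:
        """Distance (m) to the nearest region surface along ``direction``.

        Returns ``(distance, next_region)`` where *next_region* is the region
        just past the crossing (the crossing point is nudged forward by 1 nm
        along the ray, which also resolves boundary-membership ties).
        """
        x, y, z = (float(v) for v in point)
        u, v, w = (float(c) for c in direction)
        norm = math.sqrt(u * u + v * v + w * w)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction cosines must be normalized")
        tmin = math.inf
        for zp in self._plane_heights():
            if w != 0.0:
                t = (zp - z) / w
                if _EPS < t < tmin:
                    tmin = t
        a = u * u + v * v
        if a > 0.0:
            b = x * u + y * v
            for radius in self._cyl_radii():
                c = x * x + y * y - radius * radius
                disc = b * b - a * c
                if disc > 0.0:
                    sq = math.sqrt(disc)
                    for t in ((-b - sq) / a, (-b + sq) / a):
                        if _EPS < t < tmin:
                            tmin = t
        if not math.isfinite(tmin):
            return math.inf, "air"
        q = (x + u * (tmin + _EPS), y + v * (tmin + _EPS), z + w * (tmin + _EPS))
        return tmin, self.region_at(q)

    def outside_world(self, point) -> bool:
        x, y, z = (float(v) for v in point)
        return (x * x + y * y > self.world_radius ** 2
                or z > self.world_height or z < self.ground_depth)

    # -- kernel export -----------------------------------------------------
    def to_params(self) -> np.ndarray:
        """Pack the geometry into the flat float array the kernel consumes."""
        roof_r = self.d_w if self.t_r > 0.0 else -1.0
        return np.array([
            self.d_w - self.wall_thickness,   # 0 wall inner radius
            self.d_w,                         # 1 wall outer radius
            self.wall_base,                   # 2
            self.wall_top,                    # 3
            roof_r,                           # 4 roof radius (<0: no roof)
            self.roof_bottom,                 # 5
            self.roof_top,                    # 6
            self.world_radius,                # 7
            self.world_height,                # 8
            self.ground_depth,                # 9
        ], dtype=np.float64)
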