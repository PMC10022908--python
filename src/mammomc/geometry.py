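"""Phantom geometry: layered breast, skin shell, plates, body block.

Coordinates are right-handed with z vertical (the beam travels in -z),
origin at the center of the breast top face, all lengths in cm.  The chest
wall is the plane y = 0; the breast protrudes into y > 0 and the body block
occupies y < 0.  The breast footprint is either a D-shaped half-disc
(radius R, flat face on the chest wall) matching the clinical compressed
breast, or a rectangular box for closed-form test geometries.

Regions are checked in priority order by :func:`locate`; the skin shell is
expressed as the outer breast shape minus the stacked interior, so regions
are pairwise disjoint by construction.  Ray tracing intersects the ray with
every primitive surface (axis-aligned planes and the vertical cylinder) and
finds the first crossing at which the containing region changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import Material, builtin_materials

__all__ = [
    "Box", "DPrism", "Region", "PhantomAssembly", "GeometryConfig",
    "build_assembly", "locate", "trace", "region_mass",
    "WORLD_ID", "BOUNDARY_PUSH",
]

WORLD_ID = 0
#: photons are advanced this far past a boundary before relocation
BOUNDARY_PUSH = 1e-9


# -- primitive surfaces ---------------------------------------------------

@dataclass(frozen=True)
class AxisPlane:
    axis: int   # 0=x, 1=y, 2=z
    c: float


@dataclass(frozen=True)
class CylinderZ:
    radius: float  # axis along z through x=y=0


# -- shapes ---------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("box must have positive extent on every axis")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=-1)

    def surfaces(self):
        return [AxisPlane(a, self.lo[a]) for a in range(3)] + \
               [AxisPlane(a, self.hi[a]) for a in range(3)]

    @property
    def volume(self) -> float:
        return math.prod(h - l for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class DPrism:
    """Half-disc prism: x^2 + y^2 <= R^2, y >= 0, z0 <= z <= z1."""

    radius: float
    z0: float
    z1: float

    def __post_init__(self):
        if self.radius <= 0 or self.z1 <= self.z0:
            raise ValueError("D-prism needs positive radius and z extent")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
        return (
            (y >= 0.0)
            & (x * x + y * y <= self.radius * self.radius)
            & (z >= self.z0) & (z <= self.z1)
        )

    def surfaces(self):
        return [
            AxisPlane(1, 0.0),
            AxisPlane(2, self.z0), AxisPlane(2, self.z1),
            CylinderZ(self.radius),
        ]

    @property
    def volume(self) -> float:
        return 0.5 * math.pi * self.radius**2 * (self.z1 - self.z0)


# -- regions and assembly -------------------------------------------------

@dataclass(frozen=True)
class Region:
    """One homogeneous cell of the phantom.

    ``holes`` lists shapes carved out of ``shape`` (the skin shell is the
    outer breast volume minus the layered interior).
    """

    id: int
    name: str
    role: str  # layer1|layer2|layer3|skin|plate_top|plate_bottom|body|world
    material: Material | None
    shape: Box | DPrism | None
    holes: tuple = ()

    def contains(self, pts: np.ndarray) -> np.ndarray:
        inside = self.shape.contains(pts)
        for h in self.holes:
            inside &= ~h.contains(pts)
        return inside

    @property
    def volume(self) -> float:
        return self.shape.volume - sum(h.volume for h in self.holes)


@dataclass
class PhantomAssembly:
    """Ordered disjoint regions plus the source definition.

    ``regions`` excludes the world; :func:`locate` checks them in order and
    falls through to ``WORLD_ID`` (vacuum).  The source is a point at
    ``source_position`` collimated onto the rectangular ``field``
    (xlo, xhi, ylo, yhi) in the plane z = ``field_z``.
    """

    regions: list[Region]
    source_position: tuple[float, float, float]
    field: tuple[float, float, float, float]
    field_z: float
    sid: float = 65.0
    layer_thicknesses: tuple[float, float, float] | None = None
    skin_thickness: float | None = None

    def __post_init__(self):
        ids = [r.id for r in self.regions]
        if WORLD_ID in ids or len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique and nonzero")
        self._surfaces = self._collect_surfaces()
        self._by_id = {r.id: r for r in self.regions}

    def _collect_surfaces(self):
        planes: dict[tuple[int, float], None] = {}
        cyls: dict[float, None] = {}
        for r in self.regions:
            for shape in (r.shape, *r.holes):
                for s in shape.surfaces():
                    if isinstance(s, AxisPlane):
                        planes[(s.axis, s.c)] = None
                    else:
                        cyls[s.radius] = None
        plane_ax = np.array([a for a, _ in planes], dtype=int)
        plane_c = np.array([c for _, c in planes], dtype=float)
        cyl_r = np.array(sorted(cyls), dtype=float)
        return plane_ax, plane_c, cyl_r

    def region(self, region_id: int) -> Region:
        return self._by_id[region_id]

    @property
    def region_ids(self) -> list[int]:
        return [r.id for r in self.regions]

    def roles(self) -> dict[int, str]:
        return {r.id: r.role for r in self.regions}

    # -- queries ----------------------------------------------------------

    def locate_many(self, pts: np.ndarray) -> np.ndarray:
        """Region id for each point (first matching region, else world)."""
        pts = np.atleast_2d(pts)
        out = np.full(pts.shape[0], WORLD_ID, dtype=np.int32)
        unresolved = np.ones(pts.shape[0], dtype=bool)
        for r in self.regions:
            if not unresolved.any():
                break
            hit = unresolved & r.contains(pts)
            out[hit] = r.id
            unresolved &= ~hit
        return out

    def surface_distances(self, pos: np.ndarray, direction: np.ndarray,
                          eps: float = 1e-12) -> np.ndarray:
        """Distance to the nearest primitive surface crossing per ray.

        Returns ``inf`` where no surface lies ahead (the ray escapes).
        Crossings closer than ``eps`` are ignored so that a ray sitting on
        a surface moves off it.
        """
        pos = np.atleast_2d(pos)
        direction = np.atleast_2d(direction)
        n = pos.shape[0]
        best = np.full(n, np.inf)
        plane_ax, plane_c, cyl_r = self._surfaces
        for ax in (0, 1, 2):
            cs = plane_c[plane_ax == ax]
            if cs.size == 0:
                continue
            d = direction[:, ax]
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (cs[None, :] - pos[:, ax, None]) / d[:, None]
            t = np.where((t > eps) & np.isfinite(t), t, np.inf)
            best = np.minimum(best, t.min(axis=1))
        if cyl_r.size:
            dx, dy = direction[:, 0], direction[:, 1]
            px, py = pos[:, 0], pos[:, 1]
            a = dx * dx + dy * dy
            b = px * dx + py * dy
            for R in cyl_r:
                c = px * px + py * py - R * R
                disc = b * b - a * c
                ok = (disc > 0) & (a > 0)
                sq = np.sqrt(np.where(ok, disc, 0.0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    t1 = (-b - sq) / a
                    t2 = (-b + sq) / a
                t1 = np.where(ok & (t1 > eps), t1, np.inf)
                t2 = np.where(ok & (t2 > eps), t2, np.inf)
                best = np.minimum(best, np.minimum(t1, t2))
        return best


def locate(assembly: PhantomAssembly, point) -> int:
    """Region id containing ``point`` (``WORLD_ID`` if none)."""
    pt = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(pt)):
        raise ValueError("point must be finite")
    return int(assembly.locate_many(pt[None, :])[0])


def trace(assembly: PhantomAssembly, point, direction):
    """Distance to the first region boundary along ``direction``.

    Returns ``(distance, next_region_id)``.  The ray is walked from surface
    crossing to surface crossing until the containing region changes
    (crossing a surface that does not bound the current region is not a
    boundary).  On exact boundary hits the next region is probed a
    ``BOUNDARY_PUSH`` beyond the crossing, the documented tie-break.  If no
    boundary lies ahead the distance is ``inf`` with the world id.
    """
    p = np.asarray(point, dtype=float).copy()
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    current = locate(assembly, p)
    travelled = 0.0
    for _ in range(10000):
        t = float(assembly.surface_distances(p[None, :], d[None, :])[0])
        if not np.isfinite(t):
            return math.inf, WORLD_ID
        probe = p + (t + BOUNDARY_PUSH) * d
        nxt = locate(assembly, probe)
        travelled += t
        if nxt != current:
            return travelled, nxt
        p = probe
        travelled += BOUNDARY_PUSH
    raise RuntimeError("trace did not terminate (degenerate geometry?)")


def region_mass(assembly: PhantomAssembly, region_id: int) -> float:
    """Mass in grams (volume x density) of a non-world region."""
    if region_id == WORLD_ID:
        raise ValueError("world region has no defined mass")
    r = assembly.region(region_id)
    return r.volume * r.material.density


# -- assembly construction ------------------------------------------------

@dataclass
class GeometryConfig:
    """Phantom construction parameters (cm) with the packaged defaults.

    The default is the heterogeneous compressed breast: 4.5 cm of tissue in
    three equal layers mapped GF25/GF50/GF75 top-to-bottom (the top layer is
    the least dense), a 1.5 mm skin shell on the five non-chest-wall faces,
    2 mm PMMA compression plates above and below, and a 30x15x30 cm
    soft-tissue body block behind the chest wall.
    """

    footprint: str = "dshape"              # dshape | box
    radius: float = 8.0                    # D-shape radius
    box_width: float = 16.0                # box mode: x extent
    box_depth: float = 8.0                 # box mode: y extent
    layer_thicknesses: tuple[float, float, float] = (1.5, 1.5, 1.5)
    layer_materials: tuple[str, str, str] = ("GF25", "GF50", "GF75")
    skin_thickness: float = 0.15
    include_skin: bool = True
    skin_material: str = "Skin"
    plate_thickness: float = 0.2
    include_plates: bool = True
    plate_material: str = "PMMA"
    include_body: bool = True
    body_material: str = "BodyTissue"
    body_size: tuple[float, float, float] = (30.0, 15.0, 30.0)  # x, y-depth, z
    sid: float = 65.0
    materials: dict[str, Material] = field(default_factory=dict)

    def resolve(self, name: str) -> Material:
        pool = {**builtin_materials(), **self.materials}
        if name not in pool:
            raise ValueError(f"unknown material {name!r}")
        return pool[name]


def build_assembly(config: GeometryConfig | None = None) -> PhantomAssembly:
    """Construct the phantom assembly from a :class:`GeometryConfig`.

    Region ids follow the cell bookkeeping convention: 3/4/5 for the three
    breast layers top to bottom, 7 for the skin shell, 10 for the body
    block, 1/2 for the top/bottom plates.
    """
    cfg = config or GeometryConfig()
    t1, t2, t3 = cfg.layer_thicknesses
    if min(t1, t2, t3) <= 0:
        raise ValueError("layer thicknesses must be positive")
    ts = cfg.skin_thickness
    if cfg.include_skin and ts <= 0:
        raise ValueError(
            "skin_thickness must be positive; set include_skin=False "
            "for a skinless phantom"
        )
    if not cfg.include_skin:
        ts = 0.0
    T = t1 + t2 + t3
    z_top = 0.0                     # top of the breast (outer surface)
    z_bot = -(T + 2.0 * ts)         # bottom of the breast (outer surface)

    def footprint(inset: float, z0: float, z1: float):
        if cfg.footprint == "dshape":
            return DPrism(cfg.radius - inset, z0, z1)
        if cfg.footprint == "box":
            return Box((-cfg.box_width / 2 + inset, 0.0, z0),
                       (cfg.box_width / 2 - inset, cfg.box_depth - inset, z1))
        raise ValueError(f"unknown footprint {cfg.footprint!r}")

    regions: list[Region] = []
    # interior layers, top to bottom
    z = z_top - ts
    for idx, (cell, thick, mat) in enumerate(
            zip((3, 4, 5), (t1, t2, t3), cfg.layer_materials)):
        regions.append(Region(
            id=cell, name=f"layer{idx + 1}", role=f"layer{idx + 1}",
            material=cfg.resolve(mat),
            shape=footprint(ts, z - thick, z),
        ))
        z -= thick

    if cfg.include_skin:
        outer = footprint(0.0, z_bot, z_top)
        inner = footprint(ts, z_bot + ts, z_top - ts)
        regions.append(Region(
            id=7, name="skin", role="skin",
            material=cfg.resolve(cfg.skin_material),
            shape=outer, holes=(inner,),
        ))

    # lateral extent of the plates / collimated field
    if cfg.footprint == "dshape":
        xlo, xhi, ylo, yhi = -cfg.radius, cfg.radius, 0.0, cfg.radius
    else:
        xlo, xhi = -cfg.box_width / 2, cfg.box_width / 2
        ylo, yhi = 0.0, cfg.box_depth

    tp = cfg.plate_thickness
    if cfg.include_plates:
        if tp <= 0:
            raise ValueError("plate_thickness must be positive")
        plate = cfg.resolve(cfg.plate_material)
        regions.append(Region(1, "plate_top", "plate_top", plate,
                              Box((xlo, ylo, z_top), (xhi, yhi, z_top + tp))))
        regions.append(Region(2, "plate_bottom", "plate_bottom", plate,
                              Box((xlo, ylo, z_bot - tp), (xhi, yhi, z_bot))))
        entrance_z = z_top + tp
        exit_z = z_bot - tp
    else:
        entrance_z = z_top
        exit_z = z_bot

    if cfg.include_body:
        bx, by, bz = cfg.body_size
        zc = (z_top + exit_z) / 2.0
        regions.append(Region(
            10, "body", "body", cfg.resolve(cfg.body_material),
            Box((-bx / 2, -by, zc - bz / 2), (bx / 2, 0.0, zc + bz / 2)),
        ))

    source = (0.0, (ylo + yhi) / 2.0, cfg.sid + exit_z)
    return PhantomAssembly(
        regions=regions,
        source_position=source,
        field=(xlo, xhi, ylo, yhi),
        field_z=entrance_z,
        sid=cfg.sid,
        layer_thicknesses=(t1, t2, t3),
        skin_thickness=ts if cfg.include_skin else None,
    )
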