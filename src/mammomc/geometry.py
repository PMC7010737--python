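"""Constructive geometry for the mammography arrangements.

Coordinates are right-handed with the origin on the receptor plane directly
under the x-ray focal spot, z up toward the source, y into the breast
(chest-wall face at y = 0, torso at y < 0); all lengths cm.

Three arrangements are built here:

* the three-layer semicylindrical breast phantom (interior radius ``radius``,
  skin shell on the curved surface and the top/bottom faces, three
  equal-thickness layers, layer 1 on the x-ray entrance side) with an
  ICRU-44 soft-tissue torso box behind the chest-wall face;
* the reference validation arrangement (homogeneous 20% glandular breast
  between two PMMA paddles, monoenergetic source 59.3 cm above the upper
  paddle);
* the free-in-air pancake-chamber arrangement used for entrance air kerma
  (breast and torso removed).

Solids are convex, so every region body is a single ray interval; the
transport kernel only ever needs the nearest surface crossing plus point
location, both vectorized over photon arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (CHAMBER_HEIGHT_CM, CHAMBER_OFFSET_Y_CM,
                        CHAMBER_RADIUS_CM, DEFAULT_FIELD_CM, PHANTOM_LIFT_CM,
                        SOURCE_TO_RECEPTOR_CM, SURFACE_EPS)
from .materials import (DRY_AIR, ICRU44_SOFT_TISSUE, Material, PMMA, SKIN,
                        breast_tissue)

__all__ = [
    "PhantomConfig", "SourceConfig", "GeometryModel",
    "build_thep", "build_tg195_case3", "build_kerma_setup",
    "classify_distribution", "mean_glandular_fraction", "DISTRIBUTION_GRID",
]

_INF = np.inf


# --------------------------------------------------------------------------
# solids
# --------------------------------------------------------------------------

class Box:
    """Axis-aligned box [lo, hi]."""

    def __init__(self, lo: Sequence[float], hi: Sequence[float]):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise ValueError("degenerate box")

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def contains(self, p: np.ndarray) -> np.ndarray:
        return np.all((p >= self.lo) & (p <= self.hi), axis=-1)

    def interval(self, p: np.ndarray, d: np.ndarray):
        t0 = np.full(p.shape[0], -_INF)
        t1 = np.full(p.shape[0], _INF)
        for ax in range(3):
            da, pa = d[:, ax], p[:, ax]
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (self.lo[ax] - pa) / da
                tb = (self.hi[ax] - pa) / da
            lohi = np.minimum(ta, tb), np.maximum(ta, tb)
            par = da == 0.0
            inside = (pa >= self.lo[ax]) & (pa <= self.hi[ax])
            t0 = np.where(par, np.where(inside, t0, _INF),
                          np.maximum(t0, lohi[0]))
            t1 = np.where(par, np.where(inside, t1, -_INF),
                          np.minimum(t1, lohi[1]))
        return t0, t1


class HalfCylinderZ:
    """Semicylinder: x^2+y^2 <= r^2, y >= 0, z0 <= z <= z1 (axis vertical)."""

    def __init__(self, r: float, z0: float, z1: float):
        if r <= 0 or z1 <= z0:
            raise ValueError("degenerate semicylinder")
        self.r, self.z0, self.z1 = float(r), float(z0), float(z1)

    @property
    def volume(self) -> float:
        return 0.5 * np.pi * self.r ** 2 * (self.z1 - self.z0)

    def contains(self, p: np.ndarray) -> np.ndarray:
        return ((p[:, 0] ** 2 + p[:, 1] ** 2 <= self.r ** 2)
                & (p[:, 1] >= 0.0)
                & (p[:, 2] >= self.z0) & (p[:, 2] <= self.z1))

    def interval(self, p: np.ndarray, d: np.ndarray):
        n = p.shape[0]
        # infinite cylinder
        a = d[:, 0] ** 2 + d[:, 1] ** 2
        b = p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]
        c = p[:, 0] ** 2 + p[:, 1] ** 2 - self.r ** 2
        disc = b * b - a * c
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            tc0 = (-b - sq) / a
            tc1 = (-b + sq) / a
        axial = a == 0.0
        inside_c = c <= 0.0
        miss = (~axial) & (disc <= 0.0)
        t0 = np.where(axial, np.where(inside_c, -_INF, _INF), tc0)
        t1 = np.where(axial, np.where(inside_c, _INF, -_INF), tc1)
        t0 = np.where(miss, _INF, t0)
        t1 = np.where(miss, -_INF, t1)
        # half-space y >= 0
        dy, py = d[:, 1], p[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ty = -py / dy
        t0 = np.where(dy > 0, np.maximum(t0, ty), t0)
        t1 = np.where(dy > 0, t1, np.where(
            dy < 0, np.minimum(t1, ty),
            np.where(py >= 0, t1, -_INF)))
        t1 = np.where(dy < 0, np.minimum(t1, ty), t1)
        # z slab
        dz, pz = d[:, 2], p[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (self.z0 - pz) / dz
            tb = (self.z1 - pz) / dz
        lo, hi = np.minimum(ta, tb), np.maximum(ta, tb)
        par = dz == 0.0
        in_z = (pz >= self.z0) & (pz <= self.z1)
        t0 = np.where(par, np.where(in_z, t0, _INF), np.maximum(t0, lo))
        t1 = np.where(par, np.where(in_z, t1, -_INF), np.minimum(t1, hi))
        return t0, t1


class CylinderZ:
    """Full cylinder of radius r about a vertical axis at (cx, cy)."""

    def __init__(self, cx: float, cy: float, r: float, z0: float, z1: float):
        self.cx, self.cy, self.r = float(cx), float(cy), float(r)
        self.z0, self.z1 = float(z0), float(z1)

    @property
    def volume(self) -> float:
        return np.pi * self.r ** 2 * (self.z1 - self.z0)

    def contains(self, p: np.ndarray) -> np.ndarray:
        return (((p[:, 0] - self.cx) ** 2 + (p[:, 1] - self.cy) ** 2
                 <= self.r ** 2)
                & (p[:, 2] >= self.z0) & (p[:, 2] <= self.z1))

    def interval(self, p: np.ndarray, d: np.ndarray):
        x, y = p[:, 0] - self.cx, p[:, 1] - self.cy
        a = d[:, 0] ** 2 + d[:, 1] ** 2
        b = x * d[:, 0] + y * d[:, 1]
        c = x * x + y * y - self.r ** 2
        disc = b * b - a * c
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            tc0 = (-b - sq) / a
            tc1 = (-b + sq) / a
        axial = a == 0.0
        inside_c = c <= 0.0
        miss = (~axial) & (disc <= 0.0)
        t0 = np.where(axial, np.where(inside_c, -_INF, _INF), tc0)
        t1 = np.where(axial, np.where(inside_c, _INF, -_INF), tc1)
        t0 = np.where(miss, _INF, t0)
        t1 = np.where(miss, -_INF, t1)
        dz, pz = d[:, 2], p[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (self.z0 - pz) / dz
            tb = (self.z1 - pz) / dz
        lo, hi = np.minimum(ta, tb), np.maximum(ta, tb)
        par = dz == 0.0
        in_z = (pz >= self.z0) & (pz <= self.z1)
        t0 = np.where(par, np.where(in_z, t0, _INF), np.maximum(t0, lo))
        t1 = np.where(par, np.where(in_z, t1, -_INF), np.minimum(t1, hi))
        return t0, t1


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Three-layer phantom: interior radius, overall thickness (including the
    top and bottom skin), skin thickness and the per-layer glandular
    fractions ordered from the x-ray-source side downward."""

    thickness: float
    gfs: tuple[float, float, float] = (0.5, 0.5, 0.5)
    radius: float = 8.5
    skin: float = 0.4

    def __post_init__(self):
        if self.radius <= 0 or self.skin < 0:
            raise ValueError("radius must be positive and skin >= 0")
        if self.skin * 2 >= self.thickness:
            raise ValueError("skin layers meet: skin >= thickness/2")
        for g in self.gfs:
            if not 0.0 <= g <= 1.0:
                raise ValueError("glandular fractions must be in [0, 1]")

    @property
    def layer_height(self) -> float:
        return (self.thickness - 2 * self.skin) / 3.0


@dataclass(frozen=True)
class SourceConfig:
    """Isotropic point source collimated to a rectangle.

    ``field`` is (lateral width, chest-wall depth) of the collimation
    rectangle, centred on x = 0 and extending from y = 0 toward the phantom,
    in the plane ``field_z``.
    """

    position: tuple[float, float, float] = (0.0, 0.0, SOURCE_TO_RECEPTOR_CM)
    field: tuple[float, float] = DEFAULT_FIELD_CM
    field_z: float = 0.0
    histories: int = 1_000_000
    seed: int = 0

    @property
    def field_rect(self) -> tuple[float, float, float, float]:
        w, dpt = self.field
        return (-w / 2.0, w / 2.0, 0.0, dpt)

    def field_solid_angle(self) -> float:
        """Exact solid angle of the collimation rectangle (source is above
        the midpoint of the rectangle's y=0 edge)."""
        w, dpt = self.field
        h = self.position[2] - self.field_z
        a, b = w / 2.0, dpt
        return 2.0 * np.arctan(a * b / (h * np.sqrt(a * a + b * b + h * h)))


@dataclass
class GeometryModel:
    """Ordered region list over a world box; first matching region wins."""

    regions: list  # (name, Material-or-None, solid)
    world: Box
    world_material: Material | None
    tally_regions: tuple[str, ...]
    source: SourceConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.regions = list(self.regions) + [("world", self.world_material,
                                              self.world)]
        self.names = tuple(name for name, _, _ in self.regions)
        self.materials = tuple(mat for _, mat, _ in self.regions)
        self.solids = tuple(solid for _, _, solid in self.regions)

    def region_index(self, name: str) -> int:
        return self.names.index(name)

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Region index for each point; -1 outside the world box."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(p.shape[0], -1, dtype=np.int64)
        undecided = self.world.contains(p)
        for i, solid in enumerate(self.solids):
            if not undecided.any():
                break
            hit = undecided & solid.contains(p)
            out[hit] = i
            undecided &= ~hit
        return out if np.asarray(points).ndim > 1 else int(out[0])

    def min_crossing(self, p: np.ndarray, d: np.ndarray,
                     eps: float = SURFACE_EPS) -> np.ndarray:
        """Distance to the nearest region surface along each ray."""
        tmin = np.full(p.shape[0], _INF)
        for solid in self.solids:
            t0, t1 = solid.interval(p, d)
            valid = t1 > t0
            cand0 = np.where(valid & (t0 > eps), t0, _INF)
            cand1 = np.where(valid & (t1 > eps), t1, _INF)
            tmin = np.minimum(tmin, np.minimum(cand0, cand1))
        return tmin

    def distance_to_boundary(self, point, direction,
                             eps: float = SURFACE_EPS):
        """Nearest boundary distance and the region entered beyond it."""
        p = np.atleast_2d(np.asarray(point, dtype=float))
        d = np.atleast_2d(np.asarray(direction, dtype=float))
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        t = self.min_crossing(p, d, eps)
        nxt = np.full(p.shape[0], -1, dtype=np.int64)
        fin = np.isfinite(t)
        if fin.any():
            nxt[fin] = np.atleast_1d(
                self.locate(p[fin] + (t[fin, None] + eps) * d[fin]))
        if np.asarray(point).ndim == 1:
            return float(t[0]), int(nxt[0])
        return t, nxt


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def build_thep(config: PhantomConfig,
               source: SourceConfig | None = None,
               world_material: Material | None = DRY_AIR,
               torso: bool = True) -> GeometryModel:
    """Three-layer phantom + torso mammography arrangement."""
    source = source or SourceConfig()
    z_bot = PHANTOM_LIFT_CM
    z_top = z_bot + config.thickness
    h = config.layer_height
    z_in0 = z_bot + config.skin
    regions = []
    for i, gf in enumerate(config.gfs):  # layer 1 = source side (top)
        z1 = z_top - config.skin - i * h
        regions.append((f"layer{i + 1}", breast_tissue(gf),
                        HalfCylinderZ(config.radius, z1 - h, z1)))
    regions.append(("skin", SKIN,
                    HalfCylinderZ(config.radius + config.skin, z_bot, z_top)))
    if torso:
        regions.append(("torso", ICRU44_SOFT_TISSUE,
                        Box([-15.0, -20.0, 0.0], [15.0, 0.0, 40.0])))
    world = Box([-20.0, -21.0, 0.0],
                [20.0, 15.0, source.position[2] + 1.0])
    return GeometryModel(regions, world, world_material,
                         ("layer1", "layer2", "layer3", "skin")
                         + (("torso",) if torso else ()),
                         source, meta={"phantom": config})


def build_tg195_case3(world_material: Material | None = DRY_AIR,
                      histories: int = 10_000_000,
                      seed: int = 0) -> GeometryModel:
    """Reference validation arrangement: homogeneous 20% glandular breast
    (r = 9.8 cm interior, 4.6 cm thick, 2 mm skin envelope) between
    14 x 26 x 0.2 cm PMMA paddles, monoenergetic source 59.3 cm above the
    compression paddle, beam collimated to the 14 x 26 cm image receptor at
    66 cm SID (air gap below the support paddle)."""
    z0 = 0.0
    support = Box([-13.0, 0.0, z0], [13.0, 14.0, z0 + 0.2])
    breast_lo = z0 + 0.2
    breast_hi = breast_lo + 5.0
    interior = HalfCylinderZ(9.8, breast_lo + 0.2, breast_hi - 0.2)
    skin = HalfCylinderZ(10.0, breast_lo, breast_hi)
    paddle = Box([-13.0, 0.0, breast_hi], [13.0, 14.0, breast_hi + 0.2])
    src_z = breast_hi + 0.2 + 59.3
    z_receptor = src_z - 66.0
    source = SourceConfig(position=(0.0, 0.0, src_z), field=(26.0, 14.0),
                          field_z=z_receptor, histories=histories,
                          seed=seed)
    regions = [
        ("interior", breast_tissue(0.20), interior),
        ("skin", SKIN, skin),
        ("paddle_top", PMMA, paddle),
        ("paddle_bottom", PMMA, support),
    ]
    world = Box([-20.0, -5.0, z_receptor], [20.0, 20.0, src_z + 1.0])
    return GeometryModel(regions, world, world_material,
                         ("interior", "skin"), source,
                         meta={"preset": "tg195_case3"})


def build_kerma_setup(source: SourceConfig | None = None,
                      phantom: PhantomConfig | None = None,
                      world_material: Material | None = DRY_AIR,
                      placement: str = "centre") -> GeometryModel:
    """Free-in-air pancake-chamber arrangement for the reference air kerma.

    Breast and torso are absent to avoid backscatter.  ``placement`` puts
    the chamber either at the removed phantom's mid-height (``"centre"``,
    the default: the chamber stands in for the phantom at its position) or
    with its upper face in the phantom entrance plane (``"entrance"``, the
    classic entrance-kerma convention); the two differ only by the
    inverse-square factor.  The chamber axis sits ``CHAMBER_OFFSET_Y_CM``
    in from the chest-wall field edge so the disc is fully irradiated; with
    the source directly above that edge the inverse-square difference of
    the offset is < 0.1%.
    """
    source = source or SourceConfig()
    phantom = phantom or PhantomConfig(thickness=4.0)
    if placement == "centre":
        z_top = (PHANTOM_LIFT_CM + phantom.thickness / 2.0
                 + CHAMBER_HEIGHT_CM / 2.0)
    elif placement == "entrance":
        z_top = PHANTOM_LIFT_CM + phantom.thickness
    else:
        raise ValueError("placement must be 'centre' or 'entrance'")
    chamber = CylinderZ(0.0, CHAMBER_OFFSET_Y_CM, CHAMBER_RADIUS_CM,
                        z_top - CHAMBER_HEIGHT_CM, z_top)
    world = Box([-20.0, -21.0, 0.0],
                [20.0, 15.0, source.position[2] + 1.0])
    return GeometryModel([("chamber", DRY_AIR, chamber)], world,
                         world_material, ("chamber",), source,
                         meta={"phantom": phantom, "chamber": chamber})


# --------------------------------------------------------------------------
# glandular distribution labels
# --------------------------------------------------------------------------

DISTRIBUTION_GRID = tuple(
    (a, b, c) for a in (0.25, 0.50, 0.75) for b in (0.25, 0.50, 0.75)
    for c in (0.25, 0.50, 0.75))


def classify_distribution(g1: float, g2: float, g3: float) -> str:
    """Label a GF triplet (layer 1 = x-ray entrance side)."""
    if g1 == g2 == g3:
        return "uniform"
    if g1 > g2 > g3:
        return "superior"
    if g1 < g2 < g3:
        return "inferior"
    if g2 > g1 and g2 > g3:
        if g1 > g3:
            return "concentrated-upper"
        if g1 < g3:
            return "concentrated-lower"
    return "other"


def mean_glandular_fraction(g1: float, g2: float, g3: float) -> float:
    """Volume-weighted mean GF over the three equal layers."""
    return (g1 + g2 + g3) / 3.0
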