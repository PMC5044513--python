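"""Parameterized 2D mid-plane geometries and structured meshes.

The three perfusion chambers are represented as planar 2D sections built from
shapely polygons, with named regions (free lumen, porous cell compartments,
filters, scaffold, bead bed) and named boundary segments (inlet, outlet,
wall, gas_membrane).  Each planar geometry carries an explicit extrusion
depth chosen so that the section area times the depth reproduces the device's
stated 3D volume exactly; a 3D volumetric flow rate Q then maps to the 2D
per-depth rate q = Q / depth.

Published dimensions (total volumes, port internal diameters, scaffold and
filter thicknesses, the three fluidized-bed widths) are defaults; the
remaining lengths are documented choices, all overridable.

Meshing is a masked Cartesian (marker-and-cell compatible) grid: cells whose
centers fall inside a region polygon are fluid and carry that region's tag;
boundary faces between fluid and solid are tagged by proximity to the named
boundary segments, defaulting to ``wall``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

from .physics import InvalidParameterError

__all__ = [
    "PorousRegion",
    "ChamberGeometry",
    "StructuredMesh",
    "build_realbio",
    "build_fluidizedbed",
    "build_quasivivo",
    "build_geometry",
    "generate_mesh",
    "kozeny_permeability",
]

FB_WIDTHS = {"original": 27.3e-3, "narrow": 22.2e-3, "oval": 16.7e-3}


class InvalidGeometryError(ValueError):
    pass


def kozeny_permeability(porosity: float, pore_size: float) -> float:
    """Kozeny–Carman permeability estimate κ = d² ε³ / (180 (1−ε)²)."""
    if not 0.0 < porosity < 1.0:
        raise InvalidParameterError("porosity must be in (0, 1)")
    if pore_size <= 0:
        raise InvalidParameterError("pore size must be positive")
    return pore_size**2 * porosity**3 / (180.0 * (1.0 - porosity) ** 2)


@dataclass(frozen=True)
class PorousRegion:
    porosity: float
    permeability: float  # m^2
    pore_size: float  # m

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise InvalidParameterError("porosity must be in (0, 1)")
        if self.permeability <= 0 or self.pore_size <= 0:
            raise InvalidParameterError("permeability and pore size must be positive")


Segment = tuple[tuple[float, float], tuple[float, float]]


@dataclass
class ChamberGeometry:
    """A named 2D chamber: regions tile the section, boundaries are tagged."""

    name: str
    mode: str  # 'planar' (axisymmetric bodies are handled by the pipe solver)
    dimensions: dict
    regions: dict  # name -> shapely Polygon
    porous: dict  # region name -> PorousRegion
    sink_regions: list  # region names hosting cells
    boundaries: dict  # tag -> list of axis-aligned Segment
    inlet_split: dict  # inlet tag -> fraction of total flow
    port_ids: dict  # tag -> 3D internal diameter (m), for Reynolds numbers
    extrusion_depth: float
    target_volume: float
    default_resolution: tuple = (5e-4, 2.5e-4)

    def area(self, region: str | None = None) -> float:
        if region is not None:
            return self.regions[region].area
        return unary_union(list(self.regions.values())).area

    def volume(self, region: str | None = None) -> float:
        return self.area(region) * self.extrusion_depth

    def boundary_length(self, tag: str) -> float:
        return sum(math.hypot(p1[0] - p0[0], p1[1] - p0[1]) for p0, p1 in self.boundaries[tag])

    def describe(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode,
            "extrusion_depth_m": self.extrusion_depth,
            "volume_mL": self.volume() * 1e6,
            "regions": {n: {"area_m2": p.area, "volume_mL": p.area * self.extrusion_depth * 1e6}
                        for n, p in self.regions.items()},
            "porous": {n: vars(p) for n, p in self.porous.items()},
            "boundaries": {t: self.boundary_length(t) for t in self.boundaries},
            "inlet_split": dict(self.inlet_split),
            "dimensions": dict(self.dimensions),
        }


def _merged(defaults: dict, overrides: dict | None) -> dict:
    dims = dict(defaults)
    if overrides:
        unknown = set(overrides) - set(defaults)
        if unknown:
            raise InvalidGeometryError(f"unknown dimension overrides: {sorted(unknown)}")
        dims.update(overrides)
    for key, val in dims.items():
        if isinstance(val, (int, float)) and not key.startswith("_") and val <= 0:
            raise InvalidGeometryError(f"dimension {key!r} must be positive, got {val}")
    return dims


def build_realbio(overrides: dict | None = None) -> ChamberGeometry:
    """Two stacked media channels separated by a porous scaffold.

    Outer channel walls are gas-permeable membranes.  Each channel has a
    1-mm inlet and outlet; ports are axially staggered (the top channel's
    outlet and the bottom channel's inlet sit part-way along the membrane
    walls), the 2D stand-in for the device's angled ports that drive a gentle
    cross-flow through the scaffold.
    """
    dims = _merged(
        {
            "length": 0.040,
            "channel_height": 0.003,
            "scaffold_thickness": 0.001,
            "port_id": 0.001,
            "top_outlet_frac": 0.6,
            "bottom_inlet_frac": 0.4,
            "scaffold_porosity": 0.9,
            "scaffold_pore_size": 1.0e-4,
            "volume": 7.0e-6,
        },
        overrides,
    )
    L, ch, sc, pid = dims["length"], dims["channel_height"], dims["scaffold_thickness"], dims["port_id"]
    H = 2 * ch + sc
    if pid >= ch:
        raise InvalidGeometryError("port diameter must be smaller than the channel height")
    regions = {
        "bottom_channel": Polygon([(0, 0), (L, 0), (L, ch), (0, ch)]),
        "scaffold": Polygon([(0, ch), (L, ch), (L, ch + sc), (0, ch + sc)]),
        "top_channel": Polygon([(0, ch + sc), (L, ch + sc), (L, H), (0, H)]),
    }
    y_top_mid = ch + sc + ch / 2
    y_bot_mid = ch / 2
    x_out = dims["top_outlet_frac"] * L
    x_in = dims["bottom_inlet_frac"] * L
    boundaries = {
        "inlet_top": [((0.0, y_top_mid - pid / 2), (0.0, y_top_mid + pid / 2))],
        "outlet_top": [((x_out - pid / 2, H), (x_out + pid / 2, H))],
        "inlet_bottom": [((x_in - pid / 2, 0.0), (x_in + pid / 2, 0.0))],
        "outlet_bottom": [((L, y_bot_mid - pid / 2), (L, y_bot_mid + pid / 2))],
        "gas_membrane": [
            ((0.0, H), (x_out - pid / 2, H)),
            ((x_out + pid / 2, H), (L, H)),
            ((0.0, 0.0), (x_in - pid / 2, 0.0)),
            ((x_in + pid / 2, 0.0), (L, 0.0)),
        ],
    }
    eps = dims["scaffold_porosity"]
    porous = {
        "scaffold": PorousRegion(eps, kozeny_permeability(eps, dims["scaffold_pore_size"]),
                                 dims["scaffold_pore_size"])
    }
    area = sum(p.area for p in regions.values())
    return ChamberGeometry(
        name="realbio",
        mode="planar",
        dimensions=dims,
        regions=regions,
        porous=porous,
        sink_regions=["scaffold"],
        boundaries=boundaries,
        inlet_split={"inlet_top": 0.5, "inlet_bottom": 0.5},
        port_ids={t: pid for t in ("inlet_top", "outlet_top", "inlet_bottom", "outlet_bottom")},
        extrusion_depth=dims["volume"] / area,
        target_volume=dims["volume"],
        default_resolution=(5e-4, 2.5e-4),
    )


def build_fluidizedbed(width_variant: str = "original", overrides: dict | None = None) -> ChamberGeometry:
    """Vertical flow-through column: funnel inlet, porous bead bed between
    two filter layers, funnel outlet.  The plan-view parabola's maximum width
    (27.3/22.2/16.7 mm by variant) sets the section width.

    The physically 100-μm filters are represented as one 250-μm mesh layer
    whose permeability is scaled so the Darcy resistance (thickness over
    permeability) of the physical layer is preserved.
    """
    if width_variant not in FB_WIDTHS:
        raise InvalidParameterError(
            f"unknown FB width variant {width_variant!r}; choose from {sorted(FB_WIDTHS)}"
        )
    dims = _merged(
        {
            "width": FB_WIDTHS[width_variant],
            "inlet_id": 1.5e-3,
            "outlet_id": 3.0e-3,
            "funnel_height": 4.0e-3,
            "filter_thickness": 2.5e-4,
            "filter_physical_thickness": 1.0e-4,
            "filter_porosity": 0.35,
            "filter_pore_size": 1.0e-4,
            "bed_height": 2.5e-3,
            "bed_porosity": 0.3,
            "bed_pore_size": 1.0e-4,
            "volume": 4.8e-6,
        },
        overrides,
    )
    W = dims["width"]
    fh, ft, bh = dims["funnel_height"], dims["filter_thickness"], dims["bed_height"]
    xc = W / 2
    y0, y1 = 0.0, fh                      # inlet funnel (smoothly expanding)
    y2 = y1 + ft                          # lower filter
    y3 = y2 + bh                          # bead bed
    y4 = y3 + ft                          # upper filter
    y5 = y4 + fh                          # outlet funnel (smoothly contracting)
    hi, ho = dims["inlet_id"] / 2, dims["outlet_id"] / 2

    def slab(ya, yb):
        return Polygon([(0, ya), (W, ya), (W, yb), (0, yb)])

    regions = {
        "inlet_funnel": Polygon([(xc - hi, y0), (xc + hi, y0), (W, y1), (0, y1)]),
        "filter_lower": slab(y1, y2),
        "bed": slab(y2, y3),
        "filter_upper": slab(y3, y4),
        "outlet_funnel": Polygon([(0, y4), (W, y4), (xc + ho, y5), (xc - ho, y5)]),
    }
    # gas exchange happens through the funnel lids: tag their slanted walls
    boundaries = {
        "inlet": [((xc - hi, y0), (xc + hi, y0))],
        "outlet": [((xc - ho, y5), (xc + ho, y5))],
        "gas_membrane": [
            ((0.0, y1), (xc - hi, y0)), ((xc + hi, y0), (W, y1)),
            ((0.0, y4), (xc - ho, y5)), ((xc + ho, y5), (W, y4)),
        ],
    }
    kappa_filter = kozeny_permeability(dims["filter_porosity"], dims["filter_pore_size"]) * (
        ft / dims["filter_physical_thickness"]
    )
    porous = {
        "filter_lower": PorousRegion(dims["filter_porosity"], kappa_filter, dims["filter_pore_size"]),
        "filter_upper": PorousRegion(dims["filter_porosity"], kappa_filter, dims["filter_pore_size"]),
        "bed": PorousRegion(dims["bed_porosity"],
                            kozeny_permeability(dims["bed_porosity"], dims["bed_pore_size"]),
                            dims["bed_pore_size"]),
    }
    area = sum(p.area for p in regions.values())
    return ChamberGeometry(
        name="fluidizedbed",
        mode="planar",
        dimensions={**dims, "_variant": width_variant},
        regions=regions,
        porous=porous,
        sink_regions=["bed"],
        boundaries=boundaries,
        inlet_split={"inlet": 1.0},
        port_ids={"inlet": dims["inlet_id"], "outlet": dims["outlet_id"]},
        extrusion_depth=dims["volume"] / area,
        target_volume=dims["volume"],
        default_resolution=(3e-4, 2.5e-4),
    )


def build_quasivivo(overrides: dict | None = None) -> ChamberGeometry:
    """Single chamber with slanted roof, offset outlet and a floor bead bed.

    Medium enters near the top of the left wall (1-mm ID) and leaves through
    the lower, wider outlet on the right wall (2-mm ID).  Alginate beads rest
    as a sparse single layer on the chamber floor, modeled as a thin
    homogenized porous sink region.
    """
    dims = _merged(
        {
            "width": 0.020,
            "height_left": 0.011,
            "height_right": 0.009,
            "inlet_id": 1.0e-3,
            "outlet_id": 2.0e-3,
            "inlet_center_y": 0.009,
            "outlet_center_y": 0.007,
            "bed_x0": 0.004,
            "bed_x1": 0.016,
            "bed_height": 5.0e-4,
            "bed_porosity": 0.7,
            "bed_pore_size": 2.5e-4,
            "volume": 4.0e-6,
        },
        overrides,
    )
    W, hl, hr = dims["width"], dims["height_left"], dims["height_right"]
    chamber = Polygon([(0, 0), (W, 0), (W, hr), (0, hl)])
    bed = Polygon(
        [(dims["bed_x0"], 0), (dims["bed_x1"], 0),
         (dims["bed_x1"], dims["bed_height"]), (dims["bed_x0"], dims["bed_height"])]
    )
    lumen = chamber.difference(bed)
    yi, yo = dims["inlet_center_y"], dims["outlet_center_y"]
    hi, ho = dims["inlet_id"] / 2, dims["outlet_id"] / 2
    if yi + hi >= hl or yo + ho >= hr:
        raise InvalidGeometryError("ports must lie below the roof")
    boundaries = {
        "inlet": [((0.0, yi - hi), (0.0, yi + hi))],
        "outlet": [((W, yo - ho), (W, yo + ho))],
    }
    porous = {
        "bed": PorousRegion(dims["bed_porosity"],
                            kozeny_permeability(dims["bed_porosity"], dims["bed_pore_size"]),
                            dims["bed_pore_size"]),
    }
    area = chamber.area
    return ChamberGeometry(
        name="quasivivo",
        mode="planar",
        dimensions=dims,
        regions={"lumen": lumen, "bed": bed},
        porous=porous,
        sink_regions=["bed"],
        boundaries=boundaries,
        inlet_split={"inlet": 1.0},
        port_ids={"inlet": dims["inlet_id"], "outlet": dims["outlet_id"]},
        extrusion_depth=dims["volume"] / area,
        target_volume=dims["volume"],
        default_resolution=(4e-4, 2.5e-4),
    )


def build_geometry(name: str, overrides: dict | None = None, width_variant: str = "original") -> ChamberGeometry:
    builders = {
        "realbio": lambda: build_realbio(overrides),
        "fluidizedbed": lambda: build_fluidizedbed(width_variant, overrides),
        "quasivivo": lambda: build_quasivivo(overrides),
    }
    if name not in builders:
        raise InvalidParameterError(f"unknown bioreactor {name!r}; choose from {sorted(builders)}")
    return builders[name]()


@dataclass
class StructuredMesh:
    """Masked Cartesian grid with region-tagged cells and tagged boundary faces.

    ``region`` holds an integer region id per cell (-1 = solid/outside).
    Boundary faces are stored per tag as arrays of (axis, j, i, sign):
    axis 0 = x-normal face between cells (j,i-1)|(j,i); axis 1 = y-normal
    face between (j-1,i)|(j,i); sign is the inward (into-fluid) normal
    direction along the face axis.
    """

    geometry: ChamberGeometry
    dx: float
    dy: float
    nx: int
    ny: int
    region: np.ndarray  # (ny, nx) int
    region_names: list
    coverage: np.ndarray  # (ny, nx) float polygon-overlap fraction
    boundary_faces: dict = field(default_factory=dict)  # tag -> (m,4) int array

    @property
    def fluid(self) -> np.ndarray:
        return self.region >= 0

    @property
    def n_cells(self) -> int:
        return int(self.fluid.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dy
        return np.meshgrid(x, y)

    def region_mask(self, name: str) -> np.ndarray:
        return self.region == self.region_names.index(name)

    def area(self, region: str | None = None) -> float:
        """Quadrature area from per-cell polygon coverage fractions."""
        if region is None:
            return float(self.coverage.sum()) * self.dx * self.dy
        return float(np.where(self.region_mask(region), self.coverage, 0.0).sum()) * self.dx * self.dy

    def quality_report(self) -> dict:
        return {
            "cell_count": self.n_cells,
            "min_angle_deg": 90.0,  # axis-aligned rectangles
            "dx": self.dx,
            "dy": self.dy,
            "aspect_ratio": max(self.dx, self.dy) / min(self.dx, self.dy),
        }


def _coverage_fractions(polys, x0, y0, dx, dy, nx, ny, sub: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Region id per cell center plus sub-sampled coverage fraction."""
    xc = x0 + (np.arange(nx) + 0.5) * dx
    yc = y0 + (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xc, yc)
    region = np.full((ny, nx), -1, dtype=int)
    for idx, poly in enumerate(polys):
        inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(ny, nx)
        region[inside & (region < 0)] = idx
    # coverage by sub-cell sampling of the union
    union = unary_union(list(polys))
    offs = (np.arange(sub) + 0.5) / sub
    cover = np.zeros((ny, nx))
    for ox in offs:
        for oy in offs:
            xs = x0 + (np.arange(nx) + ox) * dx
            ys = y0 + (np.arange(ny) + oy) * dy
            XX, YY = np.meshgrid(xs, ys)
            cover += shapely.contains_xy(union, XX.ravel(), YY.ravel()).reshape(ny, nx)
    return region, cover / sub**2


def generate_mesh(geom: ChamberGeometry, resolution=None) -> StructuredMesh:
    """Rasterize a chamber geometry onto a masked Cartesian grid.

    ``resolution`` is (dx, dy) in meters, or a scalar for an isotropic grid;
    defaults to the geometry's recommended resolution.  Refuses resolutions
    too coarse to resolve the inlet ports or any region.
    """
    if resolution is None:
        resolution = geom.default_resolution
    if np.isscalar(resolution):
        dx = dy = float(resolution)
    else:
        dx, dy = map(float, resolution)
    if dx <= 0 or dy <= 0:
        raise InvalidParameterError("resolution must be positive")

    minx, miny, maxx, maxy = unary_union(list(geom.regions.values())).bounds
    if minx < -1e-12 or miny < -1e-12:
        raise InvalidGeometryError("geometries are expected in the first quadrant")
    nx = max(int(round(maxx / dx)), 1)
    ny = max(int(round(maxy / dy)), 1)
    if abs(nx * dx - maxx) > 1e-9 or abs(ny * dy - maxy) > 1e-9:
        nx = int(math.ceil(maxx / dx - 1e-9))
        ny = int(math.ceil(maxy / dy - 1e-9))

    # resolution checks: inlets must span >= 2 faces along their axis
    for tag, segs in geom.boundaries.items():
        if not tag.startswith("inlet"):
            continue
        (p0, p1) = segs[0]
        width = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
        along = dx if abs(p1[0] - p0[0]) > abs(p1[1] - p0[1]) else dy
        if along > width / 2 + 1e-12:
            raise InvalidGeometryError(
                f"resolution {along} too coarse for the {width}-wide {tag} port"
            )

    names = list(geom.regions)
    region, cover = _coverage_fractions([geom.regions[n] for n in names], 0.0, 0.0, dx, dy, nx, ny)

    for idx, name in enumerate(names):
        if not (region == idx).any():
            raise InvalidGeometryError(f"resolution too coarse: region {name!r} has no cells")

    mesh = StructuredMesh(
        geometry=geom, dx=dx, dy=dy, nx=nx, ny=ny,
        region=region, region_names=names, coverage=cover,
    )
    mesh.boundary_faces = _tag_boundary_faces(mesh, geom.boundaries)
    return mesh


def _tag_boundary_faces(mesh: StructuredMesh, boundaries: dict) -> dict:
    F = np.zeros((mesh.ny + 2, mesh.nx + 2), dtype=bool)
    F[1:-1, 1:-1] = mesh.fluid
    faces = []  # (axis, j, i, sign, xm, ym)
    for j in range(mesh.ny):
        for i in range(mesh.nx + 1):
            left, right = F[j + 1, i], F[j + 1, i + 1]
            if left != right:
                sign = 1 if right else -1
                faces.append((0, j, i, sign, i * mesh.dx, (j + 0.5) * mesh.dy))
    for j in range(mesh.ny + 1):
        for i in range(mesh.nx):
            below, above = F[j, i + 1], F[j + 1, i + 1]
            if below != above:
                sign = 1 if above else -1
                faces.append((1, j, i, sign, (i + 0.5) * mesh.dx, j * mesh.dy))

    tol = 0.51 * max(mesh.dx, mesh.dy)
    tags = {t: [] for t in boundaries}
    tags["wall"] = []
    for axis, j, i, sign, xm, ym in faces:
        assigned = None
        for tag, segs in boundaries.items():
            for (x0, y0), (x1, y1) in segs:
                axis_aligned = abs(y1 - y0) < 1e-12 or abs(x1 - x0) < 1e-12
                if axis_aligned:
                    horizontal = abs(y1 - y0) <= abs(x1 - x0)
                    if horizontal and axis == 1:
                        if abs(ym - y0) <= tol and min(x0, x1) - 1e-12 <= xm <= max(x0, x1) + 1e-12:
                            assigned = tag
                    elif (not horizontal) and axis == 0:
                        if abs(xm - x0) <= tol and min(y0, y1) - 1e-12 <= ym <= max(y0, y1) + 1e-12:
                            assigned = tag
                else:
                    # slanted wall (staircase boundary): match by distance
                    if LineString([(x0, y0), (x1, y1)]).distance(Point(xm, ym)) <= tol:
                        assigned = tag
                if assigned:
                    break
            if assigned:
                break
        tags[assigned or "wall"].append((axis, j, i, sign))
    return {t: np.array(v, dtype=int).reshape(-1, 4) for t, v in tags.items()}
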