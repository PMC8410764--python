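"""Lake bathymetry rasters and shoreline geometry.

The spatial frame for the whole pipeline: a regular raster of bottom
depths plus a shoreline polygon.  Synthetic basins are radially
symmetric bowls with seeded small-scale relief, which is enough to
exercise everything downstream (distance-to-bottom, boundary filtering,
kernel home ranges truncated at the shore).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

__all__ = [
    "LakeScenario",
    "LakeGrid",
    "make_lake",
    "read_ascii_grid",
    "write_ascii_grid",
    "HSC_SCENARIO",
    "LSC_SCENARIO",
]


@dataclass(frozen=True)
class LakeScenario:
    """Parameters describing one study lake.

    ``macrophyte_profile`` maps a sampling period label to a list of
    ``(depth_interval_m, coverage_range_pct, height_range_cm)`` tuples,
    each giving the colonized depth band and the uniform ranges from
    which quadrat coverage and plant height are drawn.
    """

    name: str
    max_depth: float            # m
    surface_area: float         # m^2
    raster_cell: float = 10.0   # m
    macrophyte_profile: dict = field(default_factory=dict)
    thermocline_depth_by_date: dict = field(default_factory=dict)
    twilight_by_date: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_depth <= 0:
            raise ValueError(f"max_depth must be > 0, got {self.max_depth}")
        if self.surface_area <= 0:
            raise ValueError(f"surface_area must be > 0, got {self.surface_area}")
        if self.raster_cell <= 0:
            raise ValueError("raster_cell must be > 0")
        for period, entries in self.macrophyte_profile.items():
            for (d0, d1), (c0, c1), (h0, h1) in entries:
                if not (0 <= c0 <= c1 <= 100):
                    raise ValueError(
                        f"coverage range ({c0}, {c1}) outside [0, 100] in period {period!r}"
                    )
                if h0 < 0 or h1 < h0:
                    raise ValueError(f"invalid height range ({h0}, {h1})")

    @property
    def radius(self) -> float:
        """Radius (m) of the equivalent-area circular basin."""
        return float(np.sqrt(self.surface_area / np.pi))


# Presets for the two contrasting study basins: a shallower lake densely
# colonized by macrophytes down to 12 m (high structural complexity) and a
# deep lake with only trace vegetation at 0-3 m (low structural complexity).
# Surface areas 252 and 311 ha, maximum depths 25 and 75 m.
HSC_SCENARIO = LakeScenario(
    name="HSC",
    max_depth=25.0,
    surface_area=252e4,
    macrophyte_profile={
        "June": [((0.0, 12.0), (60.0, 91.0), (40.0, 200.0))],
        "September": [((0.0, 12.0), (60.0, 91.0), (40.0, 200.0))],
    },
)

LSC_SCENARIO = LakeScenario(
    name="LSC",
    max_depth=75.0,
    surface_area=311e4,
    macrophyte_profile={
        "June": [((0.0, 3.0), (0.1, 1.6), (5.0, 60.0))],
        # vegetation expands markedly late in the season in the sparse lake
        "September": [((0.0, 5.0), (5.0, 20.0), (10.0, 120.0))],
    },
)


@dataclass
class LakeGrid:
    """Bathymetry raster plus derived shoreline polygon.

    ``depths`` holds bottom depth (m, positive down) at cell centres,
    row index along y, column index along x; land cells are 0.
    """

    depths: np.ndarray
    cell: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    shoreline: Polygon
    name: str = "lake"
    seed: int | None = None

    @property
    def max_depth(self) -> float:
        return float(np.max(self.depths))

    @property
    def radius(self) -> float:
        return float(np.sqrt(self.shoreline.area / np.pi))

    def bottom_depth(self, x, y):
        """Bottom depth (m) at planar coordinates via nearest-cell lookup.

        Returns NaN for coordinates off the raster; land cells return 0.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.rint((x - self.x_centers[0]) / self.cell).astype(int)
        iy = np.rint((y - self.y_centers[0]) / self.cell).astype(int)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        ok = (
            (ix >= 0)
            & (ix < self.x_centers.size)
            & (iy >= 0)
            & (iy < self.y_centers.size)
            & ~np.isnan(x)
            & ~np.isnan(y)
        )
        out[ok] = self.depths[iy[ok], ix[ok]]
        if out.ndim == 0:
            return float(out)
        return out

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) lies on a wet cell of the raster."""
        d = self.bottom_depth(x, y)
        return np.nan_to_num(d, nan=0.0) > 0


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, scale: int = 8) -> np.ndarray:
    """Coarse random field upsampled to `shape`; zero mean, unit-ish range."""
    coarse = rng.standard_normal((max(shape[0] // scale, 2), max(shape[1] // scale, 2)))
    iy = np.linspace(0, coarse.shape[0] - 1, shape[0])
    ix = np.linspace(0, coarse.shape[1] - 1, shape[1])
    # separable linear interpolation
    fy = np.floor(iy).astype(int)
    fx = np.floor(ix).astype(int)
    cy = np.minimum(fy + 1, coarse.shape[0] - 1)
    cx = np.minimum(fx + 1, coarse.shape[1] - 1)
    wy = (iy - fy)[:, None]
    wx = (ix - fx)[None, :]
    a = coarse[np.ix_(fy, fx)]
    b = coarse[np.ix_(fy, cx)]
    c = coarse[np.ix_(cy, fx)]
    d = coarse[np.ix_(cy, cx)]
    return (1 - wy) * ((1 - wx) * a + wx * b) + wy * ((1 - wx) * c + wx * d)


def make_lake(scenario: LakeScenario, seed: int = 0) -> LakeGrid:
    """Build a radially symmetric basin raster for ``scenario``.

    The bowl profile is ``max_depth * (1 - (r/R)^1.7)`` with a small
    seeded multiplicative relief; the deepest cell is pinned to
    ``max_depth`` and the shoreline is the circle of radius R.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    R = scenario.radius
    cell = scenario.raster_cell
    half = int(np.ceil((R + cell) / cell))
    centers = np.arange(-half, half + 1) * cell  # odd count, a centre at 0
    xg, yg = np.meshgrid(centers, centers)
    r = np.hypot(xg, yg)
    bowl = scenario.max_depth * np.clip(1.0 - (r / R) ** 1.7, 0.0, None)
    relief = 1.0 + 0.05 * _smooth_noise(bowl.shape, rng)
    depths = np.clip(bowl * relief, 0.0, scenario.max_depth)
    depths[r >= R] = 0.0
    iy, ix = np.unravel_index(np.argmin(r), r.shape)
    depths[iy, ix] = scenario.max_depth  # deepest point at the centre
    shoreline = Point(0.0, 0.0).buffer(R, quad_segs=90)
    return LakeGrid(
        depths=depths,
        cell=cell,
        x_centers=centers.copy(),
        y_centers=centers.copy(),
        shoreline=shoreline,
        name=scenario.name,
        seed=seed,
    )


def write_ascii_grid(lake: LakeGrid, path) -> None:
    """Write the bathymetry as an ESRI ASCII grid (text, metres)."""
    nrows, ncols = lake.depths.shape
    xll = lake.x_centers[0] - lake.cell / 2
    yll = lake.y_centers[0] - lake.cell / 2
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {lake.cell}\n")
        fh.write("NODATA_value -9999\n")
        # ESRI convention: first data row is the northernmost
        for row in lake.depths[::-1]:
            fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")


def read_ascii_grid(path, name: str = "lake") -> LakeGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`.

    The shoreline polygon is reconstructed as the equivalent-area circle
    of the wet cells, centred on their centroid.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    vals = np.loadtxt(lines[data_start:data_start + nrows], dtype=float, ndmin=2)
    if "nodata_value" in header:
        vals[vals == header["nodata_value"]] = 0.0
    depths = vals[::-1]  # back to south-up row order
    x_centers = header["xllcorner"] + cell / 2 + np.arange(ncols) * cell
    y_centers = header["yllcorner"] + cell / 2 + np.arange(nrows) * cell
    wet = depths > 0
    area = wet.sum() * cell * cell
    if area == 0:
        raise ValueError(f"grid {path} has no wet cells")
    cx = float(np.mean(np.meshgrid(x_centers, y_centers)[0][wet]))
    cy = float(np.mean(np.meshgrid(x_centers, y_centers)[1][wet]))
    shoreline = Point(cx, cy).buffer(float(np.sqrt(area / np.pi)), quad_segs=90)
    return LakeGrid(
        depths=depths,
        cell=cell,
        x_centers=x_centers,
        y_centers=y_centers,
        shoreline=shoreline,
        name=name,
    )
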