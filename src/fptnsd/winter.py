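"""Winter utilization distributions, isopleths, and wintering-area assignment.

The population-level winter space use is summarized by a kernel density
estimate (bivariate normal kernel, shared isotropic bandwidth) on a regular
grid. The bandwidth starts at the normal reference value h_ref and is
reduced stepwise (the "ad hoc" approach) until just before the chosen
isopleth fragments into more pieces than at h_ref or develops interior
holes. Wintering areas are the labeled isopleth polygons — the 50% contour
in the high-density coastal plain, the 85% contour in the sparser Brooks
Range — and each caribou-year is assigned to the area holding the greatest
share of its individual UD mass, falling back to the nearest area by
edge-to-edge distance from its 95% contour when there is no overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

log = logging.getLogger(__name__)

__all__ = [
    "UtilizationDistribution",
    "WinteringArea",
    "WinteringAreaSet",
    "WinterAssignment",
    "RegionRule",
    "fit_ud",
    "href",
    "select_bandwidth_adhoc",
    "delineate_areas",
    "assign_winter_area",
    "write_ud_tiff",
]

FINE_LABELS = ("W Coastal", "E Coastal", "W Brooks", "E Brooks")
REGION_MAP = {
    "W Coastal": "Coastal",
    "E Coastal": "Coastal",
    "W Brooks": "Brooks",
    "E Brooks": "Brooks",
}


@dataclass
class UtilizationDistribution:
    """Gridded probability density of space use (unit mass over the grid).

    ``density[iy, ix]`` is the density at the cell center
    ``(x0 + (ix+0.5)·cell, y0 + (iy+0.5)·cell)``; mass per cell is
    density · cell².
    """

    density: np.ndarray
    x0: float
    y0: float
    cell_m: float
    bandwidth_m: float
    href_m: float | None = None

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_m**2)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.cell_m
        cy = self.y0 + (np.arange(ny) + 0.5) * self.cell_m
        return cx, cy

    def isopleth_threshold(self, level: float) -> float:
        """Smallest density whose super-level set holds mass ≥ level."""
        if not 0 < level < 1:
            raise ValueError("isopleth level must be in (0, 1)")
        d = np.sort(self.density.ravel())[::-1]
        mass = np.cumsum(d) * self.cell_m**2
        idx = int(np.searchsorted(mass, level * self.total_mass))
        idx = min(idx, len(d) - 1)
        return float(d[idx])

    def isopleth_polygons(self, level: float) -> list[Polygon]:
        """Closed polygons (with holes) bounding the super-level set."""
        thr = self.isopleth_threshold(level)
        padded = np.pad(self.density, 1, constant_values=0.0)
        contours = measure.find_contours(padded, thr)
        rings = []
        for c in contours:
            # (row, col) index coords on the padded grid -> map meters
            x = self.x0 + (c[:, 1] - 1 + 0.5) * self.cell_m
            y = self.y0 + (c[:, 0] - 1 + 0.5) * self.cell_m
            if len(x) >= 4:
                p = Polygon(np.column_stack([x, y]))
                if p.is_valid and p.area > 0:
                    rings.append(p)
        if not rings:
            # degenerate super-level set (a handful of cells): fall back to
            # the union of the cell rectangles themselves
            iy, ix = np.nonzero(self.density >= thr)
            if len(ix) == 0:
                raise ValueError(f"isopleth at level {level} is empty")
            from shapely.geometry import box
            from shapely.ops import unary_union
            cells = [box(self.x0 + i * self.cell_m, self.y0 + j * self.cell_m,
                         self.x0 + (i + 1) * self.cell_m,
                         self.y0 + (j + 1) * self.cell_m)
                     for j, i in zip(iy, ix)]
            merged = unary_union(cells)
            geoms = getattr(merged, "geoms", [merged])
            return [g for g in geoms if isinstance(g, Polygon)]
        rings.sort(key=lambda p: p.area, reverse=True)
        # nesting depth by containment: even depth = shell, odd = hole
        depth = []
        for i, p in enumerate(rings):
            pt = p.representative_point()
            depth.append(sum(1 for q in rings[:i] if q.contains(pt)))
        polys: list[Polygon] = []
        for i, p in enumerate(rings):
            if depth[i] % 2 == 0:
                holes = [
                    list(rings[j].exterior.coords)
                    for j in range(len(rings))
                    if depth[j] == depth[i] + 1
                    and p.contains(rings[j].representative_point())
                ]
                polys.append(Polygon(p.exterior.coords, holes))
        return polys

    def mass_in_polygon(self, poly) -> float:
        """UD mass over cells whose centers fall inside a polygon."""
        cx, cy = self.cell_centers()
        minx, miny, maxx, maxy = poly.bounds
        ix = np.flatnonzero((cx >= minx - self.cell_m) & (cx <= maxx + self.cell_m))
        iy = np.flatnonzero((cy >= miny - self.cell_m) & (cy <= maxy + self.cell_m))
        if len(ix) == 0 or len(iy) == 0:
            return 0.0
        gx, gy = np.meshgrid(cx[ix], cy[iy])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        return float((self.density[np.ix_(iy, ix)] * inside).sum() * self.cell_m**2)


def href(points: np.ndarray) -> float:
    """Normal-reference bandwidth h_ref = σ · n^(−1/6).

    σ is the root mean of the coordinate variances — the isotropic version
    of the bivariate normal reference rule.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points")
    sig = np.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)))
    if sig <= 0:
        raise ValueError("zero spatial variance")
    return float(sig * len(pts) ** (-1.0 / 6.0))


def fit_ud(
    points: np.ndarray,
    bandwidth_m: float,
    cell_m: float = 1_000.0,
    pad_factor: float = 3.0,
) -> UtilizationDistribution:
    """Kernel density estimate on a regular grid (exact Gaussian sums).

    The kernel is an isotropic bivariate normal with SD ``bandwidth_m``;
    the grid covers the point bounding box padded by ``pad_factor``
    bandwidths and the density is renormalized to unit mass over the grid.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points")
    if bandwidth_m <= 0:
        raise ValueError("bandwidth must be positive")
    h = float(bandwidth_m)
    pad = pad_factor * h
    x0 = pts[:, 0].min() - pad
    y0 = pts[:, 1].min() - pad
    nx = int(np.ceil((pts[:, 0].max() + pad - x0) / cell_m)) + 1
    ny = int(np.ceil((pts[:, 1].max() + pad - y0) / cell_m)) + 1
    cx = x0 + (np.arange(nx) + 0.5) * cell_m
    cy = y0 + (np.arange(ny) + 0.5) * cell_m
    dens = np.zeros((ny, nx))
    norm = 1.0 / (2.0 * np.pi * h * h * len(pts))
    # separable per-point product, chunked to bound memory
    for a in range(0, len(pts), 2048):
        chunk = pts[a : a + 2048]
        gx = np.exp(-0.5 * ((cx[None, :] - chunk[:, 0:1]) / h) ** 2)
        gy = np.exp(-0.5 * ((cy[None, :] - chunk[:, 1:2]) / h) ** 2)
        dens += gy.T @ gx
    dens *= norm
    ud = UtilizationDistribution(dens, float(x0), float(y0), float(cell_m), h)
    mass = ud.total_mass
    if mass <= 0:
        raise ValueError("degenerate density")
    ud.density = ud.density / mass
    return ud


def _fragmentation(ud: UtilizationDistribution, level: float) -> tuple[int, int]:
    polys = ud.isopleth_polygons(level)
    n_holes = sum(len(p.interiors) for p in polys)
    return len(polys), n_holes


def select_bandwidth_adhoc(
    points: np.ndarray,
    isopleth: float = 0.95,
    step: float = 0.05,
    cell_m: float = 1_000.0,
    floor_frac: float = 0.5,
) -> float:
    """Stepwise bandwidth reduction from h_ref (the ad hoc approach).

    h is reduced in multiples of ``step``·h_ref and the smallest h is
    returned for which the chosen isopleth neither fragments into more
    disjoint polygons than at h_ref nor develops interior holes; the search
    floors at ``floor_frac``·h_ref (returned with a warning if reached).
    """
    h0 = href(points)
    if step <= 0:
        return h0
    base_polys, _ = _fragmentation(fit_ud(points, h0, cell_m), isopleth)
    best = h0
    i = 1
    while True:
        h = h0 * (1.0 - step * i)
        if h < floor_frac * h0:
            log.warning("ad hoc bandwidth search reached the %.0f%% floor",
                        100 * floor_frac)
            return best
        n_polys, n_holes = _fragmentation(fit_ud(points, h, cell_m), isopleth)
        if n_polys > base_polys or n_holes > 0:
            return best
        best = h
        i += 1


@dataclass(frozen=True)
class RegionRule:
    """Geographic split of the study area.

    Polygons with centroid ``y ≥ divide_y`` belong to the (northern)
    coastal plain, the rest to the Brooks Range; within each region,
    centroid ``x < meridian_x`` means West.
    """

    divide_y: float
    meridian_x: float


@dataclass
class WinteringArea:
    label: str
    polygon: Polygon
    isopleth_level: float


@dataclass
class WinteringAreaSet:
    areas: list[WinteringArea]
    region_map: dict[str, str] = field(default_factory=lambda: dict(REGION_MAP))

    def __getitem__(self, label: str) -> WinteringArea:
        for a in self.areas:
            if a.label == label:
                return a
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.areas]


def delineate_areas(
    pop_ud: UtilizationDistribution,
    region_rule: RegionRule,
    coastal_level: float = 0.50,
    brooks_level: float = 0.85,
) -> WinteringAreaSet:
    """Label wintering-area polygons from the population UD.

    Coastal (northern) areas are cut at the 50% isopleth where density is
    high; Brooks (southern) areas at the 85% isopleth. If several polygons
    fall in one quadrant the largest is kept (logged).
    """
    candidates: dict[str, list[tuple[Polygon, float]]] = {l: [] for l in FINE_LABELS}
    for level, want_region in ((coastal_level, "Coastal"), (brooks_level, "Brooks")):
        for poly in pop_ud.isopleth_polygons(level):
            c = poly.centroid
            region = "Coastal" if c.y >= region_rule.divide_y else "Brooks"
            if region != want_region:
                continue
            side = "W" if c.x < region_rule.meridian_x else "E"
            candidates[f"{side} {region}"].append((poly, level))
    areas = []
    for label in FINE_LABELS:
        if not candidates[label]:
            log.info("no polygon found for wintering area %s", label)
            continue
        if len(candidates[label]) > 1:
            log.info("%d polygons in quadrant %s; keeping largest",
                     len(candidates[label]), label)
        poly, level = max(candidates[label], key=lambda pl: pl[0].area)
        areas.append(WinteringArea(label=label, polygon=poly, isopleth_level=level))
    if not areas:
        raise ValueError("no wintering areas could be delineated")
    return WinteringAreaSet(areas=areas)


@dataclass
class WinterAssignment:
    """Fine- and coarse-scale wintering-area membership for one year."""

    animal_id: str
    year: int
    fine_label: str
    coarse_label: str
    method: str  # overlap | edge_distance
    overlap_fraction: float = np.nan
    edge_km: float = np.nan


def assign_winter_area(
    animal_id: str,
    year: int,
    individual_ud: UtilizationDistribution,
    area_set: WinteringAreaSet,
) -> WinterAssignment:
    """Assign a caribou-year to the wintering area of greatest UD overlap.

    With zero overlap everywhere, the year goes to the area nearest its 95%
    contour by edge-to-edge distance (ties break to the smaller distance,
    then to the lexicographically smaller label).
    """
    overlaps = {a.label: individual_ud.mass_in_polygon(a.polygon)
                for a in area_set.areas}
    best_label = max(sorted(overlaps), key=lambda l: overlaps[l])
    if overlaps[best_label] > 0:
        return WinterAssignment(
            animal_id=animal_id, year=year, fine_label=best_label,
            coarse_label=area_set.region_map[best_label], method="overlap",
            overlap_fraction=float(overlaps[best_label]),
        )
    ind_polys = individual_ud.isopleth_polygons(0.95)
    dists = {
        a.label: min(p.distance(a.polygon) for p in ind_polys)
        for a in area_set.areas
    }
    best_label = min(sorted(dists), key=lambda l: dists[l])
    return WinterAssignment(
        animal_id=animal_id, year=year, fine_label=best_label,
        coarse_label=area_set.region_map[best_label], method="edge_distance",
        edge_km=float(dists[best_label]) / 1000.0,
    )


def write_ud_tiff(ud: UtilizationDistribution, path: str, crs: str = "") -> None:
    """Write the UD raster as a single-band TIFF with world-file sidecars.

    Rows are flipped so row 0 is the northern edge (raster convention); the
    ``.tfw`` world file and a JSON sidecar carry the georeferencing.
    """
    import tifffile

    tifffile.imwrite(path, ud.density[::-1].astype(np.float32))
    ny = ud.density.shape[0]
    top_center_y = ud.y0 + (ny - 0.5) * ud.cell_m
    tfw = [ud.cell_m, 0.0, 0.0, -ud.cell_m, ud.x0 + 0.5 * ud.cell_m, top_center_y]
    base = str(path).rsplit(".", 1)[0]
    with open(base + ".tfw", "w") as fh:
        fh.write("\n".join(f"{v:.6f}" for v in tfw) + "\n")
    with open(base + ".meta.json", "w") as fh:
        json.dump({"crs": crs, "cell_m": ud.cell_m, "bandwidth_m": ud.bandwidth_m,
                   "x0": ud.x0, "y0": ud.y0}, fh, indent=2)
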