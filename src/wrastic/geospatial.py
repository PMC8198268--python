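"""Raster/vector engine: derive indicator and hazard grades from layers and
run the per-lake evaluation workflow.

All layers of one run share a projected coordinate system in metres; the
engine fails fast on CRS mismatch rather than reprojecting.  Cell inclusion
in zonal operations is by cell centre strictly inside the polygon.  Any
arithmetic touching nodata yields nodata; zonal statistics ignore nodata
cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .core import (
    DEFAULT_THRESHOLDS,
    DEFAULT_TYPE_RULE,
    DEFAULT_WEIGHTS,
    ClassThresholds,
    DegradationResult,
    HazardScores,
    HazardType,
    IndicatorScores,
    State,
    TypeRule,
    WeightScheme,
    evaluate_lake,
)
from .grid import RasterGrid
from .rubrics import (
    SLOPE_QUARTILE_GRADES,
    RubricBins,
    score_agricultural_land,
    score_cover,
    score_industry,
    score_irrigation,
    score_recreation,
    score_transport,
    score_wastewater,
    score_watershed_size,
)
from .vector import Feature, VectorLayer

__all__ = [
    "ZeroValidCellsError",
    "GeoConfig",
    "SceneLayers",
    "WatershedContext",
    "GeoDegradationResult",
    "compute_slope",
    "compute_aspect",
    "reclassify",
    "zonal_stats",
    "class_fraction",
    "features_within",
    "nearest_point_surface",
    "rasterize",
    "bearing_to_point",
    "grade_slope_cells",
    "grade_aspect_cells",
    "per_pixel_index",
    "classify_surface",
    "build_context",
    "evaluate_lake_geospatial",
]


class ZeroValidCellsError(ValueError):
    """A zonal operation found no valid cell inside the zone."""


def _require_projected(grid: RasterGrid) -> None:
    crs = grid.crs.lower()
    if "4326" in crs or "wgs84" in crs or "degree" in crs:
        raise ValueError(
            f"raster crs {grid.crs!r} is geographic (degree units); "
            "reproject to a metre-based projected crs first"
        )


# -- terrain derivatives ------------------------------------------------------

def _horn_gradients(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dz/d_east, dz/d_north, window-valid mask), defined on interior cells
    whose full 3x3 window is valid; everything else is masked."""
    _require_projected(dem)
    z = dem.values.astype(float)
    valid = dem.valid_mask()
    nrows, ncols = z.shape
    if nrows < 3 or ncols < 3:
        raise ValueError("DEM must be at least 3x3 for Horn derivatives")

    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    win_ok = np.ones(z.shape, dtype=bool)
    win_ok[1:-1, 1:-1] = (
        valid[:-2, :-2] & valid[:-2, 1:-1] & valid[:-2, 2:]
        & valid[1:-1, :-2] & valid[1:-1, 1:-1] & valid[1:-1, 2:]
        & valid[2:, :-2] & valid[2:, 1:-1] & valid[2:, 2:]
    )
    win_ok[0, :] = win_ok[-1, :] = False
    win_ok[:, 0] = win_ok[:, -1] = False

    dzdx = np.full(z.shape, np.nan)
    dznorth = np.full(z.shape, np.nan)
    dzdx[1:-1, 1:-1] = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cell)
    # row index grows southward, so the southward derivative is negated
    dznorth[1:-1, 1:-1] = -((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dem.cell)
    return dzdx, dznorth, win_ok


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees per cell (Horn's 3x3 method); cells whose window
    touches nodata or the raster edge are nodata."""
    dzdx, dznorth, ok = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dznorth)))
    out = np.full(dem.shape, dem.nodata, dtype=float)
    out[ok] = slope[ok]
    return dem.with_values(out)


def compute_aspect(dem: RasterGrid) -> RasterGrid:
    """Downslope compass direction per cell (degrees, 0 = north, clockwise);
    flat cells are nodata."""
    dzdx, dznorth, ok = _horn_gradients(dem)
    east, north = -dzdx, -dznorth
    flat = np.hypot(east, north) == 0
    aspect = np.degrees(np.arctan2(east, north)) % 360.0
    out = np.full(dem.shape, dem.nodata, dtype=float)
    keep = ok & ~flat
    out[keep] = aspect[keep]
    return dem.with_values(out)


# -- reclassification ---------------------------------------------------------

def reclassify(
    r: RasterGrid,
    bins_or_map: RubricBins | Mapping,
    default: int | None = None,
) -> RasterGrid:
    """Replace every valid cell by its grade, via interval bins or a
    category map; nodata is preserved.  Unmapped categories raise unless a
    default grade is supplied."""
    valid = r.valid_mask()
    out = np.full(r.shape, r.nodata, dtype=float)
    vals = r.values
    if isinstance(bins_or_map, RubricBins):
        out[valid] = bins_or_map.grade_array(vals[valid]).astype(float)
    else:
        cat = dict(bins_or_map)
        uniq = np.unique(vals[valid])
        unmapped = [u for u in uniq if u not in cat and u.item() not in cat]
        if unmapped and default is None:
            raise ValueError(f"unmapped categories without default: {unmapped}")
        graded = np.full(r.shape, float(default) if default is not None else np.nan)
        for code, grade in cat.items():
            graded[vals == code] = float(grade)
        out[valid] = graded[valid]
    return r.with_values(out)


# -- zonal statistics ---------------------------------------------------------

def _zone_values(r: RasterGrid, zone: BaseGeometry) -> np.ndarray:
    """Valid cell values whose centres fall strictly inside the zone."""
    x, y = r.cell_centers()
    inside = shapely.contains_xy(zone, x.ravel(), y.ravel()).reshape(r.shape)
    return r.values[inside & r.valid_mask()]


def zone_mask(r: RasterGrid, zone: BaseGeometry) -> np.ndarray:
    x, y = r.cell_centers()
    return shapely.contains_xy(zone, x.ravel(), y.ravel()).reshape(r.shape)


def _mode_lowest(vals: np.ndarray) -> float:
    uniq, counts = np.unique(vals, return_counts=True)
    return float(uniq[np.argmax(counts)])  # np.unique sorts, argmax keeps first -> lowest


def zonal_stats(
    r: RasterGrid,
    zone: BaseGeometry,
    stat: str,
    percentiles: Sequence[float] = (25, 50, 75),
):
    """Zonal statistic over valid in-zone cells.

    stat: "max" | "mean" | "mode" (ties -> lowest value) | "percentiles"
    | "class_percentages" (percent of valid cells per distinct value,
    summing to 100).
    """
    vals = _zone_values(r, zone)
    if vals.size == 0:
        raise ZeroValidCellsError("no valid raster cells inside the zone")
    if stat == "max":
        return float(vals.max())
    if stat == "mean":
        return float(vals.mean())
    if stat == "mode":
        return _mode_lowest(vals)
    if stat == "percentiles":
        return {float(p): float(np.percentile(vals, p)) for p in percentiles}
    if stat == "class_percentages":
        uniq, counts = np.unique(vals, return_counts=True)
        return {float(u): 100.0 * c / vals.size for u, c in zip(uniq, counts)}
    raise ValueError(f"unknown statistic: {stat!r}")


def class_fraction(
    landcover: RasterGrid, zone: BaseGeometry, class_codes: Sequence
) -> float:
    """Percent of valid in-zone cells whose code is in ``class_codes``."""
    vals = _zone_values(landcover, zone)
    if vals.size == 0:
        raise ZeroValidCellsError("no valid land-cover cells inside the zone")
    return 100.0 * float(np.isin(vals, list(class_codes)).sum()) / vals.size


# -- vector operations --------------------------------------------------------

def features_within(
    features: VectorLayer, zone_or_geometry, distance_m: float = 0.0
) -> VectorLayer:
    """Features intersecting the geometry buffered by ``distance_m``
    (distance 0 is a plain intersection test)."""
    geom = zone_or_geometry.geometry if isinstance(zone_or_geometry, Feature) else zone_or_geometry
    target = geom.buffer(distance_m) if distance_m > 0 else geom
    return VectorLayer(
        [f for f in features if f.geometry.intersects(target)], crs=features.crs
    )


def nearest_point_surface(
    points: VectorLayer, attribute: str, template: RasterGrid
) -> RasterGrid:
    """Allocate each cell the attribute of its nearest point (Euclidean);
    exact distance ties go to the feature with the lower index."""
    if len(points) == 0:
        raise ValueError("empty point set")
    points.require_crs(template.crs)
    points.require_attributes(attribute)
    px = np.array([f.geometry.x for f in points])
    py = np.array([f.geometry.y for f in points])
    pv = np.array([float(f.properties[attribute]) for f in points])
    x, y = template.cell_centers()
    d2 = (x[..., None] - px) ** 2 + (y[..., None] - py) ** 2
    nearest = np.argmin(d2, axis=-1)  # first occurrence wins ties -> lower id
    return template.with_values(pv[nearest])


def rasterize(
    layer: VectorLayer,
    attribute: str,
    template: RasterGrid,
    value_map: Mapping | None = None,
) -> RasterGrid:
    """Burn polygon attributes onto the template grid by cell-centre
    containment; later features overwrite earlier ones; uncovered cells are
    nodata.  ``value_map`` translates categorical attributes to numbers."""
    layer.require_crs(template.crs)
    layer.require_attributes(attribute)
    out = np.full(template.shape, template.nodata, dtype=float)
    x, y = template.cell_centers()
    for f in layer:
        v = f.properties[attribute]
        if value_map is not None:
            if v not in value_map:
                raise ValueError(f"attribute value {v!r} missing from value map")
            v = value_map[v]
        inside = shapely.contains_xy(f.geometry, x.ravel(), y.ravel()).reshape(template.shape)
        out[inside] = float(v)
    return template.with_values(out)


def bearing_to_point(template: RasterGrid, point) -> RasterGrid:
    """Compass bearing (degrees, 0 = north) from every cell centre to a point."""
    x, y = template.cell_centers()
    east = point.x - x
    north = point.y - y
    return template.with_values(np.degrees(np.arctan2(east, north)) % 360.0)


# -- per-cell hazard grading --------------------------------------------------

def grade_slope_cells(slope: RasterGrid, reference_values: np.ndarray) -> RasterGrid:
    """Per-cell slope grade by quartile of the reference slope distribution
    (left-closed; published scale 1/3/4/5)."""
    if reference_values.size == 0:
        raise ValueError("empty slope reference distribution")
    q = np.percentile(reference_values, [25, 50, 75])
    valid = slope.valid_mask()
    idx = np.searchsorted(q, slope.values, side="right")
    grades = np.asarray(SLOPE_QUARTILE_GRADES, dtype=float)[idx]
    out = np.full(slope.shape, slope.nodata, dtype=float)
    out[valid] = grades[valid]
    return slope.with_values(out)


def grade_aspect_cells(
    aspect: RasterGrid, bearing: RasterGrid, flat_grade: int = 3
) -> RasterGrid:
    """Per-cell aspect grade from angular proximity between downslope aspect
    and the bearing to the lake (<=45 deg -> 5, <=135 -> 3, else 1); flat
    (nodata-aspect) cells take the neutral ``flat_grade``."""
    aspect.require_aligned(bearing, "aspect/bearing")
    d = np.abs(aspect.values - bearing.values)
    d = np.minimum(d, 360.0 - d)
    out = np.where(d <= 45, 5.0, np.where(d <= 135, 3.0, 1.0))
    out[~aspect.valid_mask()] = float(flat_grade)
    out[~bearing.valid_mask()] = aspect.nodata
    return aspect.with_values(out)


# -- per-pixel index surfaces -------------------------------------------------

@dataclass(frozen=True)
class IndexSurfaces:
    wrastic: RasterGrid
    hi: RasterGrid
    index: RasterGrid  # the full product, per the published formula


def per_pixel_index(
    grade_rasters: Mapping[str, RasterGrid],
    weights: WeightScheme,
    hazard_rasters: Mapping[str, RasterGrid],
) -> IndexSurfaces:
    """Cell-wise weighted WRASTIC sum, HI sum and their product; a cell is
    nodata if any input is nodata.  Keys: W R A a S T I C / slope aspect
    permeability."""
    names = ("W", "R", "A", "a", "S", "T", "I", "C")
    missing = [n for n in names if n not in grade_rasters] + [
        n for n in ("slope", "aspect", "permeability") if n not in hazard_rasters
    ]
    if missing:
        raise ValueError(f"missing grade rasters: {', '.join(missing)}")
    ref = grade_rasters[names[0]]
    rasters = list(grade_rasters.values()) + list(hazard_rasters.values())
    for r in rasters:
        ref.require_aligned(r)
    ok = np.ones(ref.shape, dtype=bool)
    for r in rasters:
        ok &= r.valid_mask()

    wr = np.zeros(ref.shape)
    for n in names:
        wr += grade_rasters[n].values * getattr(weights, "w" + n)
    hi = (
        hazard_rasters["slope"].values
        + hazard_rasters["aspect"].values
        + hazard_rasters["permeability"].values
    )
    def masked(v):
        out = np.full(ref.shape, ref.nodata, dtype=float)
        out[ok] = v[ok]
        return ref.with_values(out)

    return IndexSurfaces(masked(wr), masked(hi), masked(wr * hi))


_STATE_CODES = {State.NATURAL: 0, State.SEMI_DEGRADED: 1, State.DEGRADED: 2}


def classify_surface(
    wrastic: RasterGrid,
    hi: RasterGrid,
    rule: TypeRule = DEFAULT_TYPE_RULE,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> RasterGrid:
    """Per-cell degradation state surface (0 natural, 1 semi-degraded,
    2 degraded)."""
    wrastic.require_aligned(hi, "index/hi")
    ok = wrastic.valid_mask() & hi.valid_mask()
    out = np.full(wrastic.shape, wrastic.nodata, dtype=float)
    w = wrastic.values
    t1s = np.where(hi.values <= rule.t1, 1, np.where(hi.values <= rule.t2, 2, 3))
    for t in (1, 2, 3):
        natural_hi, semi_hi = thresholds.bounds[HazardType(t)]
        sel = ok & (t1s == t)
        out[sel] = np.where(w[sel] <= natural_hi, 0, np.where(w[sel] <= semi_hi, 1, 2))
    return wrastic.with_values(out)


# -- the per-lake workflow ----------------------------------------------------

@dataclass
class GeoConfig:
    """Knobs of the geospatial workflow."""

    #: zonal aggregation of per-cell hazard grades to the lake's single grade
    hazard_aggregation: str = "mode"  # "mode" | "max" | "mean"
    #: reference distribution for slope quartiles: the whole scene raster
    #: (mirrors country-scale pre-processing) or the watershed's own cells
    slope_reference: str = "scene"  # "scene" | "watershed"
    agriculture_scale: str = "extended_5bin"
    tourist_buffer_m: float = 50.0
    flat_aspect_grade: int = 3


_LAYER_ROLES = (
    "dem", "landcover", "soil", "roads", "railways", "treatment_plants",
    "settlements", "industrial", "exploitation", "tourist", "lake", "watershed",
)


@dataclass
class SceneLayers:
    """The full layer set for one lake evaluation.

    ``legend`` maps semantic land-cover groups to code lists:
    {"agricultural": [...], "irrigated": [...], "vegetation": [...]}.
    The lake feature carries the regulatory attributes "sports"
    (motorized/non_motorized/none) and "access" (by_car/pedestrian/prohibited).
    """

    dem: RasterGrid
    landcover: RasterGrid
    legend: dict
    soil: VectorLayer
    roads: VectorLayer
    railways: VectorLayer
    treatment_plants: VectorLayer
    settlements: VectorLayer
    industrial: VectorLayer
    exploitation: VectorLayer
    tourist: VectorLayer
    lake: Feature
    watershed: BaseGeometry
    protected_areas: VectorLayer | None = None

    def validate(self) -> None:
        for role in _LAYER_ROLES:
            if getattr(self, role, None) is None:
                raise ValueError(f"missing layer: {role}")
        self.dem.require_aligned(self.landcover, "dem/landcover")
        for name in ("soil", "roads", "railways", "treatment_plants",
                     "settlements", "industrial", "exploitation", "tourist"):
            getattr(self, name).require_crs(self.dem.crs)


@dataclass
class WatershedContext:
    lake: Feature
    watershed: BaseGeometry
    lake_centroid: object
    slope: RasterGrid
    aspect: RasterGrid
    permeability: RasterGrid
    watershed_mask: np.ndarray

    @property
    def area_km2(self) -> float:
        return self.watershed.area / 1e6


@dataclass(frozen=True)
class GeoDegradationResult:
    scores: IndicatorScores
    hazards: HazardScores
    result: DegradationResult
    diagnostics: dict = field(default_factory=dict)


def build_context(layers: SceneLayers) -> WatershedContext:
    """Derive terrain and permeability layers for one lake's watershed."""
    layers.validate()
    if not layers.lake.geometry.intersects(layers.watershed):
        raise ValueError("lake polygon must lie within or touch its watershed")
    slope = compute_slope(layers.dem)
    aspect = compute_aspect(layers.dem)
    from .rubrics import SOIL_PERMEABILITY_GRADES

    perm = rasterize(layers.soil, "texture", layers.dem, SOIL_PERMEABILITY_GRADES)
    return WatershedContext(
        lake=layers.lake,
        watershed=layers.watershed,
        lake_centroid=layers.lake.geometry.centroid,
        slope=slope,
        aspect=aspect,
        permeability=perm,
        watershed_mask=zone_mask(layers.dem, layers.watershed),
    )


def _aggregate_hazard(
    grade_raster: RasterGrid, zone: BaseGeometry, how: str, valid_set: tuple[int, ...]
) -> int:
    vals = _zone_values(grade_raster, zone)
    if vals.size == 0:
        raise ZeroValidCellsError("no hazard grade cells inside the watershed")
    if how == "mode":
        g = _mode_lowest(vals)
    elif how == "max":
        g = float(vals.max())
    elif how == "mean":
        g = math.floor(vals.mean() + 0.5)  # round half-up
    else:
        raise ValueError(f"unknown hazard aggregation: {how!r}")
    g = int(g)
    if g not in valid_set:  # snap to the nearest valid grade, ties downward
        g = min(valid_set, key=lambda v: (abs(v - g), v))
    return g


def evaluate_lake_geospatial(
    layers: SceneLayers,
    weights: WeightScheme = DEFAULT_WEIGHTS,
    rule: TypeRule = DEFAULT_TYPE_RULE,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
    config: GeoConfig | None = None,
) -> GeoDegradationResult:
    """Derive all grades from the layers, evaluate the index, and record the
    per-pixel state-class percentages over the watershed."""
    config = config or GeoConfig()
    ctx = build_context(layers)
    ws = ctx.watershed

    # indicator grades
    plants = features_within(layers.treatment_plants, ws)
    stages = [f.properties["stage"] for f in plants]
    settlements = features_within(layers.settlements, ws)
    W = score_wastewater(stages, settlements_present=len(settlements) > 0)

    infra = features_within(layers.tourist, layers.lake.geometry, config.tourist_buffer_m)
    R = score_recreation(
        layers.lake.properties.get("sports", "none"),
        layers.lake.properties.get("access", "by_car"),
        infrastructure_within_50m=len(infra) > 0,
    )

    legend = layers.legend
    A = score_agricultural_land(
        class_fraction(layers.landcover, ws, legend["agricultural"]),
        scale=config.agriculture_scale,
    )
    a = score_irrigation(class_fraction(layers.landcover, ws, legend["irrigated"]))
    S = score_watershed_size(ctx.area_km2)

    crossing = features_within(layers.roads, ws).features + features_within(
        layers.railways, ws
    ).features
    T = score_transport([f.properties["category"] for f in crossing])

    industrial = features_within(layers.industrial, ws)
    exploit = features_within(layers.exploitation, ws)
    kinds = [f.properties["kind"] for f in exploit]
    order = {"mine_quarry_landfill": 2, "exploitation_perimeter": 1, "none": 0}
    worst_kind = max(kinds, key=lambda k: order[k]) if kinds else "none"
    I = score_industry(len(industrial) > 0, worst_kind)

    C = score_cover(class_fraction(layers.landcover, ws, legend["vegetation"]))
    scores = IndicatorScores(W=W, R=R, A=A, a=a, S=S, T=T, I=I, C=C)

    # per-cell hazard grades
    if config.slope_reference == "scene":
        ref = ctx.slope.values[ctx.slope.valid_mask()]
    elif config.slope_reference == "watershed":
        ref = _zone_values(ctx.slope, ws)
    else:
        raise ValueError(f"unknown slope reference: {config.slope_reference!r}")
    slope_g = grade_slope_cells(ctx.slope, ref)
    bearing = bearing_to_point(layers.dem, ctx.lake_centroid)
    aspect_g = grade_aspect_cells(ctx.aspect, bearing, config.flat_aspect_grade)
    # aspect grading is defined wherever slope is (flat cells neutral);
    # restrict to the slope-valid window so HI cells align
    av = aspect_g.values.copy()
    av[~ctx.slope.valid_mask()] = aspect_g.nodata
    aspect_g = aspect_g.with_values(av)
    perm_g = ctx.permeability

    hazards = HazardScores(
        slope=_aggregate_hazard(slope_g, ws, config.hazard_aggregation, (1, 2, 3, 4, 5)),
        aspect=_aggregate_hazard(aspect_g, ws, config.hazard_aggregation, (1, 3, 5)),
        permeability=_aggregate_hazard(perm_g, ws, config.hazard_aggregation, (1, 3, 5)),
    )

    result = evaluate_lake(scores, hazards, weights, rule, thresholds)

    # per-pixel class surface over the watershed (indicator grades are
    # watershed constants; hazards vary per cell)
    const = lambda v: layers.dem.with_values(np.full(layers.dem.shape, float(v)))
    surfaces = per_pixel_index(
        {k: const(getattr(scores, k)) for k in ("W", "R", "A", "a", "S", "T", "I", "C")},
        weights,
        {"slope": slope_g, "aspect": aspect_g, "permeability": perm_g},
    )
    state_surface = classify_surface(surfaces.wrastic, surfaces.hi, rule, thresholds)
    pct = zonal_stats(state_surface, ws, "class_percentages")
    code_to_state = {0.0: State.NATURAL, 1.0: State.SEMI_DEGRADED, 2.0: State.DEGRADED}
    class_pct = {s: 0.0 for s in State}
    class_pct.update({code_to_state[c]: p for c, p in pct.items()})

    result = DegradationResult(
        result.wrastic_value, result.hi_sum, result.hi_type, result.state,
        class_percentages=class_pct,
    )
    diagnostics = {
        "area_km2": ctx.area_km2,
        "n_watershed_cells": int(ctx.watershed_mask.sum()),
        "n_plants": len(plants),
        "n_settlements": len(settlements),
        "dominant_state_surface": code_to_state[
            zonal_stats(state_surface, ws, "max")
        ].value,
    }
    return GeoDegradationResult(scores, hazards, result, diagnostics)
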