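"""Scoring rubrics: raw watershed measurements -> integer indicator grades.

Each WRASTIC indicator (wastewater W, recreation R, agricultural land A,
irrigation a, watershed size S, transport T, industry I, vegetative cover C)
and each hazard factor (slope, aspect, soil permeability) is graded on a
small integer scale.  Interval rubrics are left-closed, right-open
([a, b)), with the final bin closed, so contiguous printed intervals such
as 10-25% / 25-50% form a partition.  Categorical multi-source indicators
(W, R, T, I) combine their sub-indicators by maximum, so adding a pollution
source never lowers the grade.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RubricBins",
    "TRANSPORT_GRADES",
    "SOIL_PERMEABILITY_GRADES",
    "TREATMENT_STAGE_GRADES",
    "jenks_breaks",
    "jenks_class_index",
    "score_aggregation_nuclei",
    "score_treatment_stage",
    "score_wastewater",
    "score_recreation",
    "score_irrigation",
    "score_agricultural_land",
    "score_watershed_size",
    "score_transport",
    "score_industry",
    "score_cover",
    "score_slope",
    "score_aspect",
    "score_permeability",
    "default_rubric_config",
    "dump_rubric_config",
]


@dataclass(frozen=True)
class RubricBins:
    """An interval rubric: ordered edges and one grade per bin.

    ``edges`` are the k interior thresholds; values fall into k+1 bins.
    Bins are left-closed ([a, b)); a value equal to an edge belongs to the
    bin on its right.
    """

    edges: tuple[float, ...]
    grades: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.grades) != len(self.edges) + 1:
            raise ValueError("need exactly one grade per bin (len(edges)+1)")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if any(not (0 <= g <= 5) for g in self.grades):
            raise ValueError("grades must lie in 0..5")

    def grade(self, value: float) -> int:
        """Grade a single value (left-closed bins)."""
        return self.grades[bisect.bisect_right(self.edges, value)]

    def grade_array(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, values, side="right")
        return np.asarray(self.grades)[idx]

    def to_dict(self) -> dict:
        return {"edges": list(self.edges), "grades": list(self.grades)}

    @classmethod
    def from_dict(cls, d: dict) -> "RubricBins":
        return cls(tuple(d["edges"]), tuple(d["grades"]))


# -- printed interval rubrics -------------------------------------------------

IRRIGATION_BINS = RubricBins(edges=(10, 25, 50, 75), grades=(1, 2, 3, 4, 5))

#: "printed_3bin" keeps the published 3-point scale (reading its overlapping
#: upper bound as >40%); "extended_5bin" (default) continues the 20%-wide
#: bins up to grade 5, the only scale consistent with the reference data.
AGRICULTURE_BINS = {
    "printed_3bin": RubricBins(edges=(20, 40), grades=(1, 2, 3)),
    "extended_5bin": RubricBins(edges=(20, 40, 60, 80), grades=(1, 2, 3, 4, 5)),
}

WATERSHED_SIZE_BINS = RubricBins(
    edges=(38.85, 155.39, 388.47, 1942.35), grades=(1, 2, 3, 4, 5)
)

COVER_BINS = RubricBins(edges=(5, 20, 35, 50), grades=(5, 4, 3, 2, 1))

# -- categorical grade maps ---------------------------------------------------

TRANSPORT_GRADES = {
    "highway_or_ring": 5,
    "national_road": 4,
    "main_railway": 4,
    "county_or_local_road": 3,
    "unpaved_road": 1,
    "narrow_tourist_railway": 1,
    "none": 0,
}

TREATMENT_STAGE_GRADES = {"primary": 3, "secondary": 2, "tertiary": 1}

SOIL_PERMEABILITY_GRADES = {"clay": 5, "sand": 3, "gravel": 1}

AQUATIC_SPORTS_GRADES = {"motorized": 5, "non_motorized": 4, "none": 0}
ACCESS_GRADES = {"by_car": 3, "pedestrian": 2, "prohibited": 1}
EXPLOITATION_GRADES = {"mine_quarry_landfill": 5, "exploitation_perimeter": 1, "none": 0}

#: Slope is graded by quartile of the reference slope distribution; the
#: published scale skips grade 2 (scores 1, 3, 4, 5) and is kept as printed.
SLOPE_QUARTILE_GRADES = (1, 3, 4, 5)


# -- Jenks natural breaks -----------------------------------------------------

def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Optimal 1-D natural-breaks classification into ``k`` classes.

    Dynamic program (Fisher's optimal partition) minimising the total
    within-class sum of squared deviations.  Returns the k-1 interior break
    thresholds, each the maximum value of its class.  Deterministic: among
    cost-ties the partition with the smallest class maxima (lexicographically,
    as produced by scanning split points left to right) is kept.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least k={k} distinct values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if k == 1:
        return []

    # prefix sums for O(1) within-class SSD of vals[i:j]
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    csq = np.concatenate(([0.0], np.cumsum(vals**2)))

    def ssd(i: int, j: int) -> float:  # vals[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    INF = float("inf")
    # cost[c][j]: optimal SSD of first j values in c classes
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):  # last class is vals[i:j]
                t = cost[c - 1][i] + ssd(i, j)
                if t < best - 1e-12:
                    best, arg = t, i
            cost[c][j] = best
            split[c][j] = arg

    # backtrack class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = split[c][j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop leading 0; k-1 split indices
    return [float(vals[i - 1]) for i in bounds]


def jenks_class_index(value: float, breaks: Sequence[float]) -> int:
    """0-based class index of ``value`` given class-maximum breaks."""
    return int(sum(value > b for b in breaks))


def score_aggregation_nuclei(
    population_density_values: Sequence[float], query_value: float
) -> int:
    """Grade 1-4 of a population-aggregation value within its natural-breaks
    classification (k=4) of the reference distribution."""
    vals = np.asarray(population_density_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty population-density distribution")
    query = float(np.clip(query_value, vals.min(), vals.max()))
    breaks = jenks_breaks(vals, 4)
    return 1 + jenks_class_index(query, breaks)


# -- indicator rubrics --------------------------------------------------------

def score_treatment_stage(stage: str) -> int:
    """Treatment-plant processing stage: primary 3 (worst), secondary 2, tertiary 1."""
    try:
        return TREATMENT_STAGE_GRADES[stage]
    except KeyError:
        raise ValueError(f"unknown treatment stage: {stage!r}") from None


def score_wastewater(
    stages_in_watershed: Sequence[str], settlements_present: bool
) -> int:
    """Wastewater grade W: 0 with no settlements and no plants, else the
    worst (maximum) treatment-stage grade among plants in the watershed."""
    if not stages_in_watershed and not settlements_present:
        return 0
    if not stages_in_watershed:
        return 0
    return max(score_treatment_stage(s) for s in stages_in_watershed)


def score_recreation(
    sports: str, access: str, infrastructure_within_50m: bool
) -> int:
    """Recreation grade R: maximum of the aquatic-sports, lake-access and
    tourist-infrastructure (within 50 m) sub-grades."""
    if sports not in AQUATIC_SPORTS_GRADES:
        raise ValueError(f"unknown sports category: {sports!r}")
    if access not in ACCESS_GRADES:
        raise ValueError(f"unknown access category: {access!r}")
    infra = 4 if infrastructure_within_50m else 0
    return max(AQUATIC_SPORTS_GRADES[sports], ACCESS_GRADES[access], infra)


def _check_pct(pct: float, what: str) -> None:
    if not (0 <= pct <= 100):
        raise ValueError(f"{what} percentage out of range [0, 100]: {pct}")


def score_irrigation(pct_permanently_irrigated: float) -> int:
    """Permanently irrigated share of the reception basin -> grade 1-5."""
    _check_pct(pct_permanently_irrigated, "irrigation")
    return IRRIGATION_BINS.grade(pct_permanently_irrigated)


def score_agricultural_land(pct_agricultural: float, scale: str = "extended_5bin") -> int:
    """Agricultural share of the reception basin -> grade (default 5-point scale)."""
    _check_pct(pct_agricultural, "agricultural land")
    try:
        bins = AGRICULTURE_BINS[scale]
    except KeyError:
        raise ValueError(f"unknown agriculture scale: {scale!r}") from None
    return bins.grade(pct_agricultural)


def score_watershed_size(area_km2: float) -> int:
    """Watershed area in km2 -> grade 1-5."""
    if area_km2 <= 0:
        raise ValueError(f"watershed area must be positive, got {area_km2}")
    return WATERSHED_SIZE_BINS.grade(area_km2)


def score_transport(categories_present: Sequence[str]) -> int:
    """Transport grade T: maximum grade of the road/rail categories crossing
    the watershed; 0 when none."""
    grade = 0
    for cat in categories_present:
        if cat not in TRANSPORT_GRADES:
            raise ValueError(f"unknown transport category: {cat!r}")
        grade = max(grade, TRANSPORT_GRADES[cat])
    return grade


def score_industry(industrial_present: bool, exploitation: str = "none") -> int:
    """Industry grade I: max of the industrial-activity sub-grade (present=3)
    and the exploitation sub-grade (mine/quarry/landfill=5, perimeter=1)."""
    if exploitation not in EXPLOITATION_GRADES:
        raise ValueError(f"unknown exploitation category: {exploitation!r}")
    return max(3 if industrial_present else 0, EXPLOITATION_GRADES[exploitation])


def score_cover(pct_natural_vegetation: float) -> int:
    """Natural-vegetation share -> grade 5 (bare, <5%) down to 1 (>50%)."""
    _check_pct(pct_natural_vegetation, "vegetation cover")
    return COVER_BINS.grade(pct_natural_vegetation)


# -- hazard rubrics -----------------------------------------------------------

def score_slope(slope_value: float, watershed_slope_distribution: Sequence[float]) -> int:
    """Slope grade by quartile of the reference slope distribution.

    Quartiles use linear interpolation between order statistics; bins are
    left-closed (value == quartile falls in the upper bin).  The published
    scale has no grade 2: below p25 -> 1, p25-p50 -> 3, p50-p75 -> 4,
    at or above p75 -> 5.
    """
    dist = np.asarray(watershed_slope_distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("empty slope distribution")
    q = np.percentile(dist, [25, 50, 75])
    return SLOPE_QUARTILE_GRADES[int(np.searchsorted(q, slope_value, side="right"))]


def score_aspect(aspect_deg: float, bearing_to_lake_deg: float) -> int:
    """Aspect grade from the angular distance between the downslope
    direction and the bearing from the cell to the lake centroid.

    d <= 45 deg: the slope drains toward the lake (grade 5); 45 < d <= 135:
    neutral (3); d > 135: drains away (1).
    """
    for name, ang in (("aspect", aspect_deg), ("bearing", bearing_to_lake_deg)):
        if not (0 <= ang < 360):
            raise ValueError(f"{name} must lie in [0, 360), got {ang}")
    d = abs(aspect_deg - bearing_to_lake_deg)
    d = min(d, 360 - d)
    if d <= 45:
        return 5
    if d <= 135:
        return 3
    return 1


def score_permeability(texture: str) -> int:
    """Soil permeability grade from texture: clay 5 (impermeable, hazardous),
    sand 3, gravel 1 (freely draining)."""
    try:
        return SOIL_PERMEABILITY_GRADES[texture]
    except KeyError:
        raise ValueError(f"unknown soil texture: {texture!r}") from None


# -- plain-text configuration -------------------------------------------------

def default_rubric_config() -> dict:
    """The shipped rubric definitions as a JSON-serialisable dict."""
    return {
        "bins": {
            "irrigation": IRRIGATION_BINS.to_dict(),
            "agriculture_extended_5bin": AGRICULTURE_BINS["extended_5bin"].to_dict(),
            "agriculture_printed_3bin": AGRICULTURE_BINS["printed_3bin"].to_dict(),
            "watershed_size_km2": WATERSHED_SIZE_BINS.to_dict(),
            "cover": COVER_BINS.to_dict(),
        },
        "categories": {
            "transport": TRANSPORT_GRADES,
            "treatment_stage": TREATMENT_STAGE_GRADES,
            "soil_permeability": SOIL_PERMEABILITY_GRADES,
            "aquatic_sports": AQUATIC_SPORTS_GRADES,
            "access": ACCESS_GRADES,
            "exploitation": EXPLOITATION_GRADES,
        },
        "combiners": {
            "wastewater": "max",
            "recreation": "max",
            "transport": "max",
            "industry": "max",
        },
        "slope_quartile_grades": list(SLOPE_QUARTILE_GRADES),
        "aspect_cutoffs_deg": [45, 135],
        "aggregation_nuclei_classes": 4,
        "agriculture_scale": "extended_5bin",
    }


def dump_rubric_config(path) -> None:
    with open(path, "w") as fh:
        json.dump(default_rubric_config(), fh, indent=2)
        fh.write("\n")
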