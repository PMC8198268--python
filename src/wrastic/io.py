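"""Tabular and configuration I/O, plus the bundled 30-lake reference fixture."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from shapely.geometry import mapping

from .core import (
    DEFAULT_THRESHOLDS,
    REQUIRED_COLUMNS,
    ClassThresholds,
    HazardType,
    TypeRule,
    WeightScheme,
)
from .rubrics import default_rubric_config

__all__ = [
    "RunConfig",
    "load_reference_table",
    "read_table",
    "write_results",
    "write_results_geojson",
    "percent",
]

_GRADE_COLUMNS = REQUIRED_COLUMNS  # W R A a S T I C slope aspect permeability


@dataclass
class RunConfig:
    """Validated run configuration; defaults reproduce the calibrated scheme."""

    weights: WeightScheme = field(default_factory=WeightScheme)
    type_rule: TypeRule = field(default_factory=TypeRule)
    thresholds: ClassThresholds = field(default_factory=lambda: DEFAULT_THRESHOLDS)
    hazard_aggregation: str = "mode"
    slope_reference: str = "scene"
    agriculture_scale: str = "extended_5bin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_aggregation not in ("mode", "max", "mean"):
            raise ValueError(f"unknown hazard aggregation {self.hazard_aggregation!r}")
        if self.slope_reference not in ("scene", "watershed"):
            raise ValueError(f"unknown slope reference {self.slope_reference!r}")
        if self.agriculture_scale not in ("extended_5bin", "printed_3bin"):
            raise ValueError(f"unknown agriculture scale {self.agriculture_scale!r}")

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.to_dict(),
            "type_rule": {"t1": self.type_rule.t1, "t2": self.type_rule.t2},
            "thresholds": {
                str(int(t)): list(b) for t, b in self.thresholds.bounds.items()
            },
            "hazard_aggregation": self.hazard_aggregation,
            "slope_reference": self.slope_reference,
            "agriculture_scale": self.agriculture_scale,
            "seed": self.seed,
            "rubrics": default_rubric_config(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "weights" in d:
            kw["weights"] = WeightScheme(**d["weights"])
        if "type_rule" in d:
            kw["type_rule"] = TypeRule(**d["type_rule"])
        if "thresholds" in d:
            kw["thresholds"] = ClassThresholds(
                bounds={HazardType(int(k)): tuple(v) for k, v in d["thresholds"].items()}
            )
        for key in ("hazard_aggregation", "slope_reference", "agriculture_scale", "seed"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_reference_table() -> pd.DataFrame:
    """The bundled 30-lake indicator/hazard score table with printed states."""
    with resources.files("wrastic.data").joinpath("lakes_ro30.csv").open() as fh:
        return pd.read_csv(fh)


def read_table(path) -> pd.DataFrame:
    """Read a per-lake score CSV, validating headers and grade integrality;
    malformed rows are reported by number."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    missing = [c for c in _GRADE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    bad_rows = []
    for col in _GRADE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        bad_rows.extend((int(i) + 2) for i in df.index[bad])  # 1-based incl. header
    if bad_rows:
        raise ValueError(
            f"non-integer grades in rows (file line numbers): {sorted(set(bad_rows))}"
        )
    df[_GRADE_COLUMNS] = df[_GRADE_COLUMNS].astype(int)
    return df


def write_results(table: pd.DataFrame, path) -> None:
    """Per-lake results as CSV (round-trippable with pandas)."""
    table.to_csv(path, index=False)


def write_results_geojson(results: list[dict], path) -> None:
    """Per-lake results as a GeoJSON FeatureCollection: each entry needs a
    shapely 'geometry' plus flat properties (state, percentages, ...)."""
    feats = []
    for rec in results:
        rec = dict(rec)
        geom = rec.pop("geometry")
        feats.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": rec,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
        fh.write("\n")


def percent(count: int, total: int) -> int:
    """Share as an integer percent, rounded half-up (17/30 -> 57)."""
    if total == 0:
        return 0
    return int((100 * count / total) + 0.5)
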