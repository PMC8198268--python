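"""Vector layers (shapely geometries + flat attributes) with GeoJSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["Feature", "VectorLayer", "read_geojson", "write_geojson"]


@dataclass
class Feature:
    geometry: BaseGeometry
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError("feature geometry must be non-empty")
        if not self.geometry.is_valid:
            raise ValueError("feature geometry must be valid")


@dataclass
class VectorLayer:
    features: list[Feature]
    crs: str = "local-metre"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def require_crs(self, crs: str) -> None:
        if self.crs != crs:
            raise ValueError(f"crs mismatch: layer is {self.crs!r}, expected {crs!r}")

    def require_attributes(self, *names: str) -> None:
        for i, f in enumerate(self.features):
            for n in names:
                if n not in f.properties:
                    raise ValueError(f"feature {i} lacks required attribute {n!r}")


def write_geojson(layer: VectorLayer, path) -> None:
    doc = {
        "type": "FeatureCollection",
        "crs_id": layer.crs,  # non-standard hint; layers use local projected coords
        "features": [
            {"type": "Feature", "geometry": mapping(f.geometry), "properties": f.properties}
            for f in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_geojson(path, crs: str | None = None) -> VectorLayer:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    feats = [
        Feature(shape(f["geometry"]), f.get("properties") or {})
        for f in doc["features"]
    ]
    return VectorLayer(feats, crs=crs or doc.get("crs_id", "local-metre"))
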