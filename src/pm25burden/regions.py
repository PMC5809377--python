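"""Region (state) masks from GeoJSON polygons.

Polygons are rasterised to the grid by cell-centre containment; a cell
whose centre falls inside several polygons is assigned to the first-
listed feature.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
from shapely import contains_xy
from shapely.geometry import shape

from .grids import GridSpec


def rasterize_regions(
    geojson: Mapping | str | Path, spec: GridSpec
) -> dict[str, np.ndarray]:
    """Boolean mask per named feature, shape (n_lat, n_lon).

    ``geojson`` is a FeatureCollection (or a path to one); each feature
    needs a ``name`` property.  Masks are disjoint: overlapping polygons
    resolve to the first-listed feature.
    """
    if isinstance(geojson, (str, Path)):
        geojson = json.loads(Path(geojson).read_text())
    features = geojson["features"]

    lon, lat = np.meshgrid(spec.lon_centers, spec.lat_centers)
    assigned = np.zeros(spec.shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    for feat in features:
        name = feat["properties"]["name"]
        geom = shape(feat["geometry"])
        inside = contains_xy(geom, lon, lat) & ~assigned
        assigned |= inside
        masks[name] = inside
    return masks


def regions_to_geojson(boxes: Mapping[str, tuple[float, float, float, float]]) -> dict:
    """FeatureCollection of rectangular regions (lon_min, lat_min, lon_max, lat_max)."""
    features = []
    for name, (lon0, lat0, lon1, lat1) in boxes.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [
                            [lon0, lat0],
                            [lon1, lat0],
                            [lon1, lat1],
                            [lon0, lat1],
                            [lon0, lat0],
                        ]
                    ],
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
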