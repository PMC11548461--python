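"""Land-use attribution: legend harmonisation and point-in-polygon joins.

Layers of different provenance and resolution (a fine local map and a
coarse country-wide one, in the field case) are kept as separate
:class:`LandUseMap` objects with an integer priority; a fix is attributed by
the highest-priority layer with a polygon covering it, falling back to
``"unclassified"``.  Containment uses shapely's closed-boundary ``covers``
rule and, among same-priority overlapping polygons, the lowest polygon ID
wins, so boundary points resolve identically across runs.

All geometry is WGS84 decimal degrees: the polygons involved are small
enough that geodesic effects sit far below GPS noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

UNIFIED_UNITS = (
    "homefields",
    "bushfields",
    "rangelands",
    "lowlands",
    "fallows",
    "other",
    "unclassified",
)


def harmonize_legend(labels, mapping_: dict) -> list[str]:
    """Map raw layer labels onto the unified legend; unmapped labels raise."""
    missing = sorted({str(l) for l in labels} - set(mapping_))
    if missing:
        raise ValueError(f"unmapped land-use labels: {missing}")
    return [mapping_[str(l)] for l in labels]


@dataclass
class LandUseMap:
    """One vector land-use layer with its legend and priority."""

    polygons: list  # shapely geometries
    labels: list[str]  # raw labels, one per polygon
    legend_map: dict[str, str]
    priority: int = 0
    resolution_tag: str = ""

    units: list[str] = field(init=False)

    def __post_init__(self):
        if len(self.polygons) != len(self.labels):
            raise ValueError("one label per polygon required")
        for i, g in enumerate(self.polygons):
            if g is None or not g.is_valid:
                raise ValueError(f"invalid geometry for polygon {i}")
        self.units = harmonize_legend(self.labels, self.legend_map)

    @classmethod
    def from_geojson(cls, path, legend_map: dict, priority: int = 0,
                     resolution_tag: str = "") -> "LandUseMap":
        with open(path) as fh:
            doc = json.load(fh)
        geoms, labels = [], []
        for feat in doc["features"]:
            geoms.append(shape(feat["geometry"]))
            labels.append(str(feat["properties"]["label"]))
        return cls(geoms, labels, legend_map, priority, resolution_tag)

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(g),
                "properties": {"label": lab},
            }
            for g, lab in zip(self.polygons, self.labels)
        ]
        doc = {"type": "FeatureCollection", "features": feats,
               "properties": {"priority": self.priority,
                              "resolution_tag": self.resolution_tag}}
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")


def join_fixes(fixes: pd.DataFrame, maps: list[LandUseMap]) -> pd.DataFrame:
    """Annotate fixes with ``unit`` and ``source_layer`` columns.

    Layers are tried in descending priority; each uses an STR-tree spatial
    index so the join stays near-linear in the number of fixes.
    """
    if not maps:
        raise ValueError("at least one land-use layer required")
    from shapely import points as make_points

    pts = make_points(np.column_stack([fixes["lon"].to_numpy(dtype=float),
                                       fixes["lat"].to_numpy(dtype=float)]))
    n = len(pts)
    unit = np.array(["unclassified"] * n, dtype=object)
    source = np.array([""] * n, dtype=object)
    unresolved = np.ones(n, dtype=bool)
    for layer in sorted(maps, key=lambda m: -m.priority):
        if not unresolved.any():
            break
        idx = np.flatnonzero(unresolved)
        tree = STRtree(layer.polygons)
        q_pt, q_poly = tree.query(pts[idx], predicate="covered_by")
        if q_pt.size == 0:
            continue
        # lowest polygon ID wins among same-priority hits
        order = np.lexsort((q_poly, q_pt))
        q_pt, q_poly = q_pt[order], q_poly[order]
        first = np.ones(q_pt.size, dtype=bool)
        first[1:] = q_pt[1:] != q_pt[:-1]
        rows = idx[q_pt[first]]
        unit[rows] = [layer.units[j] for j in q_poly[first]]
        source[rows] = layer.resolution_tag or f"priority{layer.priority}"
        unresolved[rows] = False
    out = fixes.copy()
    out["unit"] = unit
    out["source_layer"] = source
    return out
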