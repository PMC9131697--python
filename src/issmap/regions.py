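"""Region annotations: named tissue polygons with compartments and depth axes.

Regions play the role of atlas annotations: gray/white-matter compartments
(neocortex vs corpus callosum in the brain, GM/WM in the spinal cord), an
oriented pial-to-white-matter depth axis for cortical regions, fractional
layer boundaries, and optional cortical area subdivisions (S1/M1/M2/Cg1/Cg2).
All coordinates are Cartesian micrometres.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon, mapping, shape

GM = "GM"
WM = "WM"

#: Fractional depths delimiting cortical layers I, II/III, IV, V, VI.
DEFAULT_LAYER_BREAKS: tuple[float, ...] = (0.1, 0.35, 0.5, 0.75)
LAYER_NAMES: tuple[str, ...] = ("I", "II/III", "IV", "V", "VI")

#: Cortical areas, lateral to medial, and their fractional widths.
CORTICAL_AREAS: tuple[str, ...] = ("S1", "M1", "M2", "Cg1", "Cg2")
_AREA_WIDTHS: tuple[float, ...] = (0.30, 0.20, 0.20, 0.15, 0.15)


@dataclass
class RegionAnnotation:
    """Named simple polygons with compartment labels and cortical metadata.

    ``regions`` is ordered: a point on a shared boundary belongs to the
    region listed first (deterministic tie-break).  ``depth_axis`` maps a
    cortical region name to an oriented segment (pial point, white-matter
    point); ``layer_breaks`` to strictly increasing fractional depths in
    (0, 1).  ``areas`` optionally subdivides the cortex into named areas.
    """

    regions: dict[str, Polygon]
    compartment_of: dict[str, str]
    depth_axis: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(default_factory=dict)
    layer_breaks: dict[str, tuple[float, ...]] = field(default_factory=dict)
    areas: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, poly in list(self.regions.items()) + list(self.areas.items()):
            if not poly.is_valid:
                raise ValueError(f"region {name!r} polygon is not simple/valid")
            if poly.area <= 0:
                raise ValueError(f"region {name!r} polygon has non-positive area")
        for name in self.regions:
            if name not in self.compartment_of:
                raise ValueError(f"region {name!r} missing compartment label")
            if self.compartment_of[name] not in (GM, WM):
                raise ValueError(f"region {name!r} compartment must be GM or WM")
        for name, breaks in self.layer_breaks.items():
            arr = np.asarray(breaks, dtype=float)
            if arr.size and not (np.all(np.diff(arr) > 0)
                                 and arr[0] > 0 and arr[-1] < 1):
                raise ValueError(
                    f"layer_breaks for {name!r} must be strictly increasing in (0,1)")

    @property
    def region_names(self) -> list[str]:
        return list(self.regions)

    def area_mm2(self, name: str) -> float:
        """Polygon area of a region in mm^2."""
        return self.regions[name].area / 1e6

    def bounds(self) -> tuple[float, float, float, float]:
        geoms = list(self.regions.values())
        return shapely.unary_union(geoms).bounds

    # -- point membership ---------------------------------------------------
    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region name per point (first listed region wins on boundaries).

        Points outside all regions get ``"unassigned"``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "unassigned", dtype=object)
        pts = shapely.points(np.column_stack([x, y]))
        unresolved = np.ones(x.shape, dtype=bool)
        for name, poly in self.regions.items():
            if not unresolved.any():
                break
            hit = unresolved & shapely.covers(poly, pts)
            out[hit] = name
            unresolved &= ~hit
        return out.astype(str)

    # -- serialization ------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        features = []
        for name, poly in self.regions.items():
            props: dict = {"name": name, "compartment": self.compartment_of[name]}
            if name in self.layer_breaks:
                props["layer_breaks"] = list(self.layer_breaks[name])
            if name in self.depth_axis:
                a, b = self.depth_axis[name]
                props["depth_axis"] = [list(a), list(b)]
            features.append({"type": "Feature", "properties": props,
                             "geometry": mapping(poly)})
        for name, poly in self.areas.items():
            features.append({"type": "Feature",
                             "properties": {"name": name, "role": "area"},
                             "geometry": mapping(poly)})
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features}))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionAnnotation":
        data = json.loads(Path(path).read_text())
        regions: dict[str, Polygon] = {}
        compartment: dict[str, str] = {}
        depth_axis: dict = {}
        layer_breaks: dict = {}
        areas: dict[str, Polygon] = {}
        for feat in data["features"]:
            props = feat.get("properties", {})
            name = props["name"]
            poly = shape(feat["geometry"])
            if props.get("role") == "area":
                areas[name] = poly
                continue
            regions[name] = poly
            compartment[name] = props["compartment"]
            if "layer_breaks" in props:
                layer_breaks[name] = tuple(props["layer_breaks"])
            if "depth_axis" in props:
                a, b = props["depth_axis"]
                depth_axis[name] = (tuple(a), tuple(b))
        return cls(regions, compartment, depth_axis, layer_breaks, areas)


def _ellipse(cx: float, cy: float, rx: float, ry: float) -> Polygon:
    return affinity.scale(Point(cx, cy).buffer(1.0, quad_segs=64), rx, ry)


def make_layout(kind: str, scale: float = 1000.0) -> RegionAnnotation:
    """Construct a stylized tissue layout.

    ``brain_coronal``: a cortical band (CTX, gray matter) of depth ``scale``
    sitting on a corpus-callosum band (CC, white matter) of depth
    ``0.3 * scale``; the CTX carries a pial-to-white-matter depth axis, the
    five-layer boundaries, and a lateral-to-medial subdivision into the
    areas S1, M1, M2, Cg1 and Cg2.

    ``spinal_cord``: a gray-matter ellipse inside a white-matter ring.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if kind == "brain_coronal":
        width = 2.0 * scale
        cc = Polygon([(0, 0), (width, 0), (width, 0.3 * scale), (0, 0.3 * scale)])
        ctx = Polygon([(0, 0.3 * scale), (width, 0.3 * scale),
                       (width, 1.3 * scale), (0, 1.3 * scale)])
        areas: dict[str, Polygon] = {}
        x0 = 0.0
        for name, frac in zip(CORTICAL_AREAS, _AREA_WIDTHS):
            x1 = x0 + frac * width
            areas[name] = Polygon([(x0, 0.3 * scale), (x1, 0.3 * scale),
                                   (x1, 1.3 * scale), (x0, 1.3 * scale)])
            x0 = x1
        return RegionAnnotation(
            regions={"CTX": ctx, "CC": cc},
            compartment_of={"CTX": GM, "CC": WM},
            depth_axis={"CTX": ((width / 2, 1.3 * scale), (width / 2, 0.3 * scale))},
            layer_breaks={"CTX": DEFAULT_LAYER_BREAKS},
            areas=areas,
        )
    if kind == "spinal_cord":
        outer = _ellipse(0.0, 0.0, scale, 0.7 * scale)
        gm = _ellipse(0.0, 0.0, 0.55 * scale, 0.35 * scale)
        wm = outer.difference(gm)
        return RegionAnnotation(
            regions={"GM": gm, "WM": wm},
            compartment_of={"GM": GM, "WM": WM},
        )
    raise ValueError(f"unknown layout kind {kind!r}")
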