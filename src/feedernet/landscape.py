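"""Landscape covariates for feeder pairs: elliptical corridor buffers,
vegetation cover, road gaps and distances.

The habitat a bird is likely to use when moving between a pair of feeders
is described by an ellipse whose major axis lies along the inter-feeder
segment, with a buffer beyond each feeder of 0.25 times the inter-feeder
distance ``d``.  The ellipse therefore has total length ``1.5 d``, total
width ``0.5 d`` and a fixed length:width ratio of 3.  Within the buffer we
measure the percentage of pixels holding tall vegetation (canopy height
above a threshold AND a vegetation index above a threshold), and count the
distinct roads that dissect it ("road gaps", pooled at two or more).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.affinity import rotate, scale, translate
from shapely.geometry import LineString, Point, shape

from feedernet.errors import GeometryError, ValidationError
from feedernet.raster import Raster

#: Buffer margin beyond each feeder as a fraction of the pair distance.
BUFFER_FRACTION = 0.25
#: Fixed length:width ratio of the corridor ellipse.
AXIS_RATIO = 3.0

PAIR_FEATURE_COLUMNS = [
    "network_id",
    "feeder_a",
    "feeder_b",
    "distance_m",
    "veg_cover_pct",
    "road_gaps_raw",
    "road_gap_class",
    "ringing_dist_m",
]


@dataclass(frozen=True)
class EllipseBuffer:
    """Corridor ellipse between one unordered feeder pair."""

    pair: tuple  # (feeder_id, feeder_id), order as given
    center: tuple  # (x, y) midpoint, metres
    semi_major: float
    semi_minor: float
    orientation: float  # radians, major axis along the inter-feeder segment

    @property
    def distance(self) -> float:
        """Inter-feeder distance d (= 2 × semi_major / 1.5)."""
        return self.semi_major / (0.5 + BUFFER_FRACTION)

    @property
    def area(self) -> float:
        return np.pi * self.semi_major * self.semi_minor

    def contains(self, x, y):
        """Vectorised point-in-ellipse test (boundary inclusive)."""
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = (dx * c + dy * s) / self.semi_major
        v = (-dx * s + dy * c) / self.semi_minor
        return u * u + v * v <= 1.0

    def to_shapely(self, quad_segs: int = 64):
        """Polygonal approximation (for line-intersection tests)."""
        circ = Point(0.0, 0.0).buffer(1.0, quad_segs=quad_segs)
        ell = scale(circ, xfact=self.semi_major, yfact=self.semi_minor)
        ell = rotate(ell, np.degrees(self.orientation), origin=(0, 0))
        return translate(ell, xoff=self.center[0], yoff=self.center[1])


def _xy(station) -> tuple[float, float]:
    if isinstance(station, (tuple, list, np.ndarray)):
        return float(station[0]), float(station[1])
    return float(station["x"]), float(station["y"])


def _station_id(station, default: str) -> str:
    if isinstance(station, (tuple, list, np.ndarray)):
        return default
    try:
        return str(station["feeder_id"])
    except (KeyError, TypeError):
        return default


def pair_distance(a, b) -> float:
    """Euclidean distance in metres between two stations."""
    ax, ay = _xy(a)
    bx, by = _xy(b)
    return float(np.hypot(bx - ax, by - ay))


def ellipse_for_pair(a, b) -> EllipseBuffer:
    """Corridor ellipse for stations ``a`` and ``b``.

    The center is the pair midpoint; the major semi-axis is
    ``(0.5 + 0.25) d`` so the ellipse extends 0.25 d beyond each feeder,
    and the minor semi-axis is ``0.25 d``, giving the fixed 3:1 axis
    ratio.  Both feeders lie inside the ellipse.
    """
    ax, ay = _xy(a)
    bx, by = _xy(b)
    d = np.hypot(bx - ax, by - ay)
    if d == 0.0:
        raise GeometryError("coincident stations: ellipse undefined")
    return EllipseBuffer(
        pair=(_station_id(a, "a"), _station_id(b, "b")),
        center=((ax + bx) / 2.0, (ay + by) / 2.0),
        semi_major=(0.5 + BUFFER_FRACTION) * d,
        semi_minor=BUFFER_FRACTION * d,
        orientation=float(np.arctan2(by - ay, bx - ax)),
    )


def vegetation_cover(
    ellipse: EllipseBuffer,
    height: Raster,
    index: Raster | None = None,
    h_thresh: float = 0.7,
    idx_thresh: float = 0.2,
) -> float:
    """Percent of pixels inside the ellipse holding tall vegetation.

    A pixel belongs to the buffer when its *center* is inside the ellipse,
    and is vegetated when canopy height exceeds ``h_thresh`` metres and —
    if an index raster is supplied — the vegetation index exceeds
    ``idx_thresh``.
    """
    if index is not None and not height.same_grid(index):
        raise ValidationError("height and index rasters are not co-registered")
    xmin, ymin, xmax, ymax = height.bounds
    cx, cy = ellipse.center
    r = ellipse.semi_major
    if cx + r < xmin or cx - r > xmax or cy + r < ymin or cy - r > ymax:
        raise GeometryError("ellipse lies fully outside the raster extent")

    xs = height.x_centers()
    ys = height.y_centers()
    # restrict to the ellipse's bounding square before the exact test
    cols = np.where((xs >= cx - r) & (xs <= cx + r))[0]
    rows = np.where((ys >= cy - r) & (ys <= cy + r))[0]
    if cols.size == 0 or rows.size == 0:
        raise GeometryError("no pixel centers inside the ellipse")
    inside = ellipse.contains(
        xs[cols][None, :].repeat(rows.size, axis=0),
        ys[rows][:, None].repeat(cols.size, axis=1),
    )
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise GeometryError("no pixel centers inside the ellipse")
    h = height.data[np.ix_(rows, cols)][inside]
    veg = h > h_thresh
    if index is not None:
        veg &= index.data[np.ix_(rows, cols)][inside] > idx_thresh
    return 100.0 * float(veg.sum()) / n_inside


def count_road_gaps(ellipse: EllipseBuffer, roads) -> tuple[int, int]:
    """Number of distinct roads dissecting the buffer, and its class.

    A road gap is present when a road polyline crosses the ellipse
    interior (a tangency touching only the boundary does not count); each
    input feature counts at most once however many times it crosses.
    Classes pool rare multiple crossings: ``class = min(raw, 2)``.
    """
    poly = ellipse.to_shapely()
    raw = 0
    for road in roads:
        geom = road if isinstance(road, LineString) else LineString(road)
        inter = geom.intersection(poly)
        if not inter.is_empty and inter.length > 0.0:
            raw += 1
    return raw, min(raw, 2)


def ringing_distance(a, b, sites: pd.DataFrame, network_id: str | None = None) -> float:
    """Distance from the nearer feeder of the pair to the nearest ringing
    site of its network (minimum over both feeders × the network's sites).
    """
    if network_id is not None:
        sites = sites[sites["network_id"] == network_id]
    if len(sites) == 0:
        raise ValidationError(f"no ringing site in network {network_id!r}")
    sx = sites["x"].to_numpy(float)
    sy = sites["y"].to_numpy(float)
    best = np.inf
    for st in (a, b):
        x, y = _xy(st)
        best = min(best, float(np.min(np.hypot(sx - x, sy - y))))
    return best


def read_roads(path) -> list[LineString]:
    """Read road centrelines from a GeoJSON FeatureCollection of
    LineStrings; each feature is one distinct road."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    roads = []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type not in ("LineString", "MultiLineString"):
            raise ValidationError(f"road feature is {geom.geom_type}, not a line")
        roads.append(geom)
    return roads


def write_roads(roads, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"road_id": i},
            "geometry": json.loads(json.dumps(road.__geo_interface__)),
        }
        for i, road in enumerate(roads)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def build_pair_features(
    stations: pd.DataFrame,
    sites: pd.DataFrame,
    height: Raster | dict,
    index: Raster | dict | None,
    roads,
    network_id: str | None = None,
    h_thresh: float = 0.7,
    idx_thresh: float = 0.2,
) -> pd.DataFrame:
    """Per-pair landscape covariates, one row per unordered feeder pair.

    ``height``/``index`` and ``roads`` may be single objects (one network)
    or dicts keyed by network id.  With *n* stations per network the table
    has C(n, 2) rows per network.
    """
    if network_id is not None:
        stations = stations[stations["network_id"] == network_id]
    rows = []
    for net, group in stations.groupby("network_id"):
        h = height[net] if isinstance(height, dict) else height
        idx = index[net] if isinstance(index, dict) else index
        rds = roads[net] if isinstance(roads, dict) else roads
        recs = group.sort_values("feeder_id").to_dict("records")
        for a, b in itertools.combinations(recs, 2):
            ell = ellipse_for_pair(a, b)
            raw, cls = count_road_gaps(ell, rds)
            rows.append(
                {
                    "network_id": net,
                    "feeder_a": a["feeder_id"],
                    "feeder_b": b["feeder_id"],
                    "distance_m": pair_distance(a, b),
                    "veg_cover_pct": vegetation_cover(
                        ell, h, idx, h_thresh=h_thresh, idx_thresh=idx_thresh
                    ),
                    "road_gaps_raw": raw,
                    "road_gap_class": cls,
                    "ringing_dist_m": ringing_distance(a, b, sites, network_id=net),
                }
            )
    return pd.DataFrame(rows, columns=PAIR_FEATURE_COLUMNS)


def features_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Per-network summary: mean±SD pair distance, mean±SD vegetation
    cover, and total raw road-gap count."""
    return (
        features.groupby("network_id")
        .agg(
            n_pairs=("distance_m", "size"),
            mean_distance_m=("distance_m", "mean"),
            sd_distance_m=("distance_m", "std"),
            mean_veg_cover_pct=("veg_cover_pct", "mean"),
            sd_veg_cover_pct=("veg_cover_pct", "std"),
            total_road_gaps=("road_gaps_raw", "sum"),
        )
        .reset_index()
    )
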