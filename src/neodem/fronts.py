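"""Travelling-front tracking from time-stratified convex hulls.

The spatial expansion of an archaeological phenomenon is summarised by the
cumulative convex hull of all its dated points older than each 100-yr time
boundary. As the front advances, the hull area grows; episodes of rapid
growth (pulses) alternate with pauses in which already-occupied territory is
merely infilled. Successive hull differences at pulse boundaries partition
the study area into rings of first arrival, which in turn partition the date
database into dispersal-defined regions.

All geometry is done in the plane of a Lambert azimuthal equal-area
projection centred on the point cloud (areas in km²); polygons are exported
to GeoJSON in WGS84 coordinates via the inverse projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, Polygon, mapping, shape
from shapely.ops import split as shapely_split
from shapely.ops import unary_union

from .geo import LambertAzimuthalEqualArea

__all__ = [
    "HullSeries",
    "Pulse",
    "RegionPartition",
    "SplitLine",
    "GeometryError",
    "hull_series",
    "detect_pulses",
    "region_polygons",
    "apply_splits",
    "assign_dates",
    "SLIVER_KM2",
]

#: Geometric differences of near-tangent hulls create degenerate fragments;
#: pieces below this area (km²) are discarded as slivers.
SLIVER_KM2 = 1.0


class GeometryError(ValueError):
    pass


@dataclass
class HullSeries:
    """Cumulative convex hulls per 100-yr step.

    ``steps`` descend through time (cal BP); ``hulls[i]`` is the convex hull
    (projected plane, km) of every Neolithic point whose mode age is at least
    ``steps[i]``, so hulls are nested and ``areas`` (km²) non-decreasing.
    """

    steps: np.ndarray
    hulls: list
    areas: np.ndarray
    projection: LambertAzimuthalEqualArea

    def hull_at(self, step: float):
        """Hull whose younger bound equals ``step`` (cal BP)."""
        i = int(np.argmin(np.abs(self.steps - step)))
        if self.steps[i] != step:
            raise KeyError(f"no hull boundary at {step} cal BP")
        return self.hulls[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step_cal_bp": self.steps, "area_km2": self.areas})


@dataclass(frozen=True)
class Pulse:
    """One dispersal pulse: area growth resumes at ``start`` and stalls at ``end``.

    Ages are cal BP, so ``start > end``.
    """

    start: float
    end: float

    def __post_init__(self):
        if not self.start > self.end:
            raise ValueError("pulse start must be older (larger cal BP) than end")


@dataclass
class Region:
    label: str
    polygon: Polygon
    pulse_index: int
    bracket_old: float
    bracket_young: float


@dataclass
class RegionPartition:
    """Non-overlapping first-arrival rings (plus optional cultural splits)."""

    regions: list[Region]
    projection: LambertAzimuthalEqualArea
    warnings: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def to_geojson(self) -> dict:
        feats = []
        for r in self.regions:
            geo = shapely.transform(
                r.polygon,
                lambda xy: np.column_stack(self.projection.inverse(xy[:, 0], xy[:, 1])),
            )
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(geo),
                    "properties": {
                        "label": r.label,
                        "pulse_index": r.pulse_index,
                        "pulse_start": r.bracket_old,
                        "bracket_young": r.bracket_young,
                    },
                }
            )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {
                "projection": {"lon0": self.projection.lon0, "lat0": self.projection.lat0}
            },
        }

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


@dataclass(frozen=True)
class SplitLine:
    """A cultural split: a polyline that bisects one target region.

    The two sides get labels ``labels[0]`` (left of the line's direction of
    travel) and ``labels[1]`` (right).
    """

    target: str
    line: LineString
    labels: tuple[str, str]


def hull_series(
    points: pd.DataFrame,
    step: int = 100,
    time_range: tuple[float, float] = (12_000.0, 4_000.0),
    projection: LambertAzimuthalEqualArea | None = None,
) -> HullSeries:
    """Cumulative convex hull per time step.

    Parameters
    ----------
    points : DataFrame
        Columns ``lon``, ``lat``, ``mode_age`` (cal BP); pass the Neolithic
        subset only — no period filtering happens here.
    step : int
        Step width in years (default 100).
    time_range : (old, young)
        Boundaries run from old down to young inclusive.
    """
    old, young = time_range
    if old <= young:
        raise ValueError("time_range must be (older, younger) in cal BP")
    if projection is None:
        projection = LambertAzimuthalEqualArea.centered_on(points["lon"], points["lat"])
    x, y = projection.forward(points["lon"].to_numpy(), points["lat"].to_numpy())
    ages = points["mode_age"].to_numpy(dtype=float)
    steps = np.arange(old, young - step / 2.0, -step, dtype=float)
    hulls, areas = [], []
    for bound in steps:
        sel = ages >= bound
        if sel.sum() < 3:
            hulls.append(Polygon())
            areas.append(0.0)
            continue
        hull = MultiPoint(np.column_stack([x[sel], y[sel]])).convex_hull
        if hull.geom_type != "Polygon":  # collinear points
            hulls.append(Polygon())
            areas.append(0.0)
            continue
        hulls.append(hull)
        areas.append(hull.area)
    return HullSeries(steps=steps, hulls=hulls, areas=np.asarray(areas), projection=projection)


def detect_pulses(
    series: HullSeries,
    growth_frac: float = 0.05,
    pause_len: int = 2,
    min_growth: float = 0.25,
) -> list[Pulse]:
    """Detect dispersal pulses from the hull-area time series.

    A step's growth fraction is ΔA/A_prev across the preceding interval
    (infinite when the area first becomes positive). A pulse starts at the
    older boundary of the first super-threshold interval following at least
    ``pause_len`` consecutive sub-threshold steps (the series start counts as
    a pause), and ends at the younger boundary of its last super-threshold
    interval once growth has stayed below threshold for ``pause_len`` steps.

    Candidate pulses whose cumulative area gain is below ``min_growth``
    (fractional, relative to the area at pulse start) are discarded: isolated
    single-step blips from dating noise are not dispersal episodes. Set
    ``min_growth=0`` to keep every super-threshold run.
    """
    if series.steps.size < 3:
        raise ValueError("need at least 3 steps")
    areas = series.areas
    steps = series.steps
    growing = np.zeros(steps.size, dtype=bool)  # interval ending at step i
    for i in range(1, steps.size):
        prev, cur = areas[i - 1], areas[i]
        if cur > prev:
            growing[i] = True if prev == 0 else (cur - prev) / prev > growth_frac
    pulses: list[Pulse] = []
    quiet = pause_len  # steps since last growth; start counts as a long pause
    start = last_growth = None
    for i in range(1, steps.size):
        if growing[i]:
            if start is None and quiet >= pause_len:
                start = steps[i - 1]
            if start is not None:
                last_growth = steps[i]
            quiet = 0
        else:
            quiet += 1
            if start is not None and quiet >= pause_len:
                pulses.append(Pulse(start=float(start), end=float(last_growth)))
                start = last_growth = None
    if start is not None:
        pulses.append(Pulse(start=float(start), end=float(last_growth)))
    if min_growth > 0:
        kept = []
        for p in pulses:
            a0 = areas[np.argmin(np.abs(steps - p.start))]
            a1 = areas[np.argmin(np.abs(steps - p.end))]
            if a0 == 0 or (a1 - a0) / a0 >= min_growth:
                kept.append(p)
        pulses = kept
    return pulses


def _clean(poly, tol: float = SLIVER_KM2):
    """Drop sliver fragments and non-areal pieces below ``tol`` km²."""
    poly = poly.buffer(0)
    if poly.is_empty:
        return Polygon()
    parts = getattr(poly, "geoms", [poly])
    kept = [p for p in parts if p.geom_type == "Polygon" and p.area >= tol]
    if not kept:
        return Polygon()
    return unary_union(kept)


def region_polygons(
    series: HullSeries,
    pulses: list[Pulse],
    labels: list[str] | None = None,
) -> RegionPartition:
    """First-arrival ring per pulse: hull at pulse end minus previous hull.

    Region 0 is the origin (the hull already in place when the first pulse
    starts); region k (k >= 1) is the ring added by pulse k. Slivers below
    ``SLIVER_KM2`` are cleaned; a degenerate (empty) ring is dropped with a
    warning.
    """
    if not pulses:
        raise ValueError("need at least one pulse")
    warnings: list[str] = []
    boundary_hulls = [series.hull_at(pulses[0].start)]
    boundary_ages = [pulses[0].start]
    for p in pulses:
        boundary_hulls.append(series.hull_at(p.end))
        boundary_ages.append(p.end)
    regions: list[Region] = []
    for k, hull in enumerate(boundary_hulls):
        poly = hull if k == 0 else hull.difference(boundary_hulls[k - 1])
        poly = _clean(poly)
        if poly.is_empty:
            warnings.append(f"region {k} degenerate (empty difference); dropped")
            continue
        label = labels[k] if labels else (f"ring_{k}" if k else "origin")
        old = 12_000.0 if k == 0 else pulses[k - 1].start
        regions.append(
            Region(
                label=label,
                polygon=poly,
                pulse_index=k,
                bracket_old=float(old),
                bracket_young=float(boundary_ages[k]),
            )
        )
    return RegionPartition(regions=regions, projection=series.projection, warnings=warnings)


def apply_splits(partition: RegionPartition, splits: list[SplitLine]) -> RegionPartition:
    """Bisect target regions along cultural split polylines.

    Split lines are given in WGS84 lon/lat and projected with the partition's
    projection. Each line must cross its target polygon completely; pieces on
    the left of the line's direction get the first label, right the second.
    """
    regions = list(partition.regions)
    for sp in splits:
        idx = next((i for i, r in enumerate(regions) if r.label == sp.target), None)
        if idx is None:
            raise GeometryError(f"no region labelled {sp.target!r}")
        reg = regions[idx]
        coords = np.asarray(sp.line.coords)
        x, y = partition.projection.forward(coords[:, 0], coords[:, 1])
        line = LineString(np.column_stack([x, y]))
        pieces = shapely_split(reg.polygon, line)
        polys = [g for g in pieces.geoms if g.geom_type == "Polygon" and g.area >= SLIVER_KM2]
        if len(polys) < 2:
            raise GeometryError(
                f"split line does not cross region {sp.target!r} completely"
            )
        left_parts, right_parts = [], []
        for g in polys:
            (left_parts if _is_left(line, g) else right_parts).append(g)
        if not left_parts or not right_parts:
            raise GeometryError(f"split of region {sp.target!r} left one side empty")
        halves = [
            Region(
                label=sp.labels[j],
                polygon=_clean(unary_union(parts)),
                pulse_index=reg.pulse_index,
                bracket_old=reg.bracket_old,
                bracket_young=reg.bracket_young,
            )
            for j, parts in enumerate((left_parts, right_parts))
        ]
        regions[idx : idx + 1] = halves
    return RegionPartition(regions=regions, projection=partition.projection,
                           warnings=list(partition.warnings))


def _is_left(line: LineString, poly) -> bool:
    """Is the polygon's representative point left of the (projected) line?"""
    pt = poly.representative_point()
    p = np.asarray(line.coords)
    # nearest segment's cross product sign
    d = line.project(pt)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(p, axis=0).T))])
    seg = min(int(np.searchsorted(cum, d, side="right")) - 1, p.shape[0] - 2)
    a, b = p[seg], p[seg + 1]
    return (b[0] - a[0]) * (pt.y - a[1]) - (b[1] - a[1]) * (pt.x - a[0]) > 0


def assign_dates(dates: pd.DataFrame, partition: RegionPartition) -> pd.DataFrame:
    """Annotate a date table with the region containing each point.

    Points on shared boundaries go to the earlier-pulse region (the front
    defines first arrival); points outside every region get ``"unassigned"``.
    """
    x, y = partition.projection.forward(dates["lon"].to_numpy(), dates["lat"].to_numpy())
    pts = shapely.points(x, y)
    labels = np.full(len(dates), "unassigned", dtype=object)
    order = sorted(range(len(partition.regions)),
                   key=lambda i: partition.regions[i].pulse_index)
    unclaimed = np.ones(len(dates), dtype=bool)
    for i in order:
        reg = partition.regions[i]
        hit = shapely.covers(reg.polygon, pts) & unclaimed
        labels[hit] = reg.label
        unclaimed &= ~hit
    out = dates.copy()
    out["region"] = labels
    return out


def read_partition_geojson(path) -> RegionPartition:
    """Rebuild a region partition from a GeoJSON written by ``write_geojson``."""
    with open(path) as fh:
        gj = json.load(fh)
    proj_info = gj.get("properties", {}).get("projection")
    if proj_info is None:
        raise GeometryError("partition GeoJSON lacks projection metadata")
    projection = LambertAzimuthalEqualArea(proj_info["lon0"], proj_info["lat0"])
    regions = []
    for feat in gj["features"]:
        geo = shape(feat["geometry"])
        poly = shapely.transform(
            geo, lambda xy: np.column_stack(projection.forward(xy[:, 0], xy[:, 1]))
        )
        props = feat["properties"]
        regions.append(
            Region(
                label=props["label"],
                polygon=poly,
                pulse_index=props["pulse_index"],
                bracket_old=props["pulse_start"],
                bracket_young=props["bracket_young"],
            )
        )
    return RegionPartition(regions=regions, projection=projection)


def read_splits_geojson(path) -> list[SplitLine]:
    """Read cultural split polylines from a GeoJSON FeatureCollection.

    Each feature must be a LineString with properties ``target``, ``label_left``
    and ``label_right``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    splits = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type != "LineString":
            raise GeometryError("split features must be LineStrings")
        props = feat.get("properties", {})
        splits.append(
            SplitLine(
                target=props["target"],
                line=geom,
                labels=(props["label_left"], props["label_right"]),
            )
        )
    return splits
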