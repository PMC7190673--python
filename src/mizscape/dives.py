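"""Time-depth-recorder processing: dive segmentation, undulation counting,
bottom-phase and light summaries, dive classification and geolocation.

Depth is in metres, positive downward, sampled nominally at 1 Hz.  A dive is
a maximal excursion past ``dive_threshold`` (default 5 m) bounded by
crossings of ``surface_threshold`` (default 1 m).  Undulations — depth
reversals from ascent back to descent with the preceding ascent exceeding
1 m — proxy prey-capture attempts.  The bottom phase is the span between the
first and last sample at or below 80% of maximum depth (configurable
fraction).  Dives are classed as ``foraging`` (undulations in the bottom
phase, deeper than the shallow threshold), ``other`` (shallow travelling
dives) or ``exploratory`` (deep V-shaped dives with no bottom activity).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

__all__ = [
    "DiveRecord",
    "detect_dives",
    "count_undulations",
    "bottom_phase",
    "classify_dive",
    "dive_light_summary",
    "zero_offset_correct",
    "dives_to_frame",
    "assign_locations",
    "load_dated_edges",
    "distance_to_edge",
    "attach_edge_distance",
]

KM_PER_DEG = math.pi / 180.0 * 6371.0  # mean-Earth metres per degree, in km


@dataclass
class DiveRecord:
    """Summary of one dive extracted from a 1-Hz depth series."""

    tag_id: str
    start_s: float
    end_s: float
    max_depth: float
    duration: float
    bottom_start_s: float
    bottom_end_s: float
    bottom_time: float
    undulations: int            # whole-dive count
    bottom_undulations: int     # count within the bottom phase
    dive_class: str
    light_5m: float = np.nan
    light_bottom: float = np.nan
    start_time: pd.Timestamp | None = None
    lon: float = np.nan
    lat: float = np.nan
    minutes_from_tkp: float = np.nan
    distance_to_edge_km: float = np.nan

    def __post_init__(self):
        if not 0 <= self.bottom_time <= self.duration + 1e-9:
            raise ValueError("bottom_time must lie within the dive duration")
        if self.dive_class == "foraging" and self.undulations < 1:
            raise ValueError("foraging dives must contain at least one undulation")


def count_undulations(depths, min_amplitude: float = 1.0) -> int:
    """Count ascent-to-descent reversals with ascent amplitude > ``min_amplitude``.

    Walks the profile accumulating ascent (depth decrease); when descent
    resumes, a reversal is counted if the accumulated ascent exceeded the
    threshold (strictly), and the accumulator resets.  Profiles shorter than
    3 samples have no interior reversal and score 0.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 3:
        return 0
    count = 0
    ascent = 0.0
    for d in np.diff(depths):
        if d < 0:
            ascent += -d
        elif d > 0:
            if ascent > min_amplitude:
                count += 1
            ascent = 0.0
        # d == 0: plateau, keep any accumulated ascent
    return count


def bottom_phase(times, depths, fraction: float = 0.8):
    """Locate the bottom phase: first to last sample at >= ``fraction`` * max depth.

    Returns ``(start_time, end_time, bottom_time_s)``.  With ``fraction=1.0``
    this is the span spent at exact maximum depth.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    max_depth = depths.max()
    if max_depth <= 0:
        raise ValueError("bottom_phase requires a positive maximum depth")
    at_bottom = depths >= fraction * max_depth - 1e-12
    idx = np.nonzero(at_bottom)[0]
    start, end = times[idx[0]], times[idx[-1]]
    return float(start), float(end), float(end - start)


def classify_dive(
    max_depth: float,
    bottom_undulations: int,
    shallow_threshold: float = 10.0,
) -> str:
    """Three-way dive classification.

    ``other``: shallow travelling dives (max depth below the shallow
    threshold); ``foraging``: at least one undulation in the bottom phase;
    ``exploratory``: deep dives that go straight down and up with no bottom
    activity.
    """
    if max_depth < shallow_threshold:
        return "other"
    if bottom_undulations >= 1:
        return "foraging"
    return "exploratory"


def dive_light_summary(times, depths, light, bottom_start, bottom_end):
    """Mean logger light near 5 m (4-6 m band, descent and ascent) and over
    the bottom phase.  Returns NaN where no samples fall in the band."""
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    light = np.asarray(light, dtype=float)
    band = (depths >= 4.0) & (depths <= 6.0)
    light_5m = float(np.nanmean(light[band])) if band.any() else np.nan
    in_bottom = (times >= bottom_start) & (times <= bottom_end)
    light_bottom = float(np.nanmean(light[in_bottom])) if in_bottom.any() else np.nan
    return light_5m, light_bottom


def zero_offset_correct(times_s, depths, window_s: float = 3600.0, surface_band: float = 2.0):
    """Remove per-hour sensor drift: subtract the modal near-surface depth
    (0.1-m resolution) estimated in each window, then floor at 0."""
    times_s = np.asarray(times_s, dtype=float)
    depths = np.asarray(depths, dtype=float).copy()
    t0 = times_s[0]
    for w in range(int((times_s[-1] - t0) // window_s) + 1):
        sel = (times_s >= t0 + w * window_s) & (times_s < t0 + (w + 1) * window_s)
        surf = depths[sel & (depths < surface_band)]
        if surf.size:
            counts, edges = np.histogram(surf, bins=np.arange(-0.5, surface_band + 0.1, 0.1))
            offset = edges[np.argmax(counts)] + 0.05
            depths[sel] = depths[sel] - offset
    return np.maximum(depths, 0.0)


def detect_dives(
    series: pd.DataFrame,
    tag_id: str | None = None,
    dive_threshold: float = 5.0,
    surface_threshold: float = 1.0,
    bottom_fraction: float = 0.8,
    shallow_threshold: float = 10.0,
    max_gap_s: float = 10.0,
    zero_offset: bool = False,
) -> list[DiveRecord]:
    """Segment a 1-Hz depth series into dives and compute per-dive metrics.

    ``series`` needs ``time_s`` (strictly increasing) and ``depth_m``;
    ``light_raw`` and a ``timestamp`` column are used when present.  Gaps
    shorter than ``max_gap_s`` are linearly interpolated; larger gaps split
    the series and no dive spans them.
    """
    t = series["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    z = series["depth_m"].to_numpy(dtype=float)
    if tag_id is None:
        tag_id = str(series["tag_id"].iloc[0]) if "tag_id" in series else ""
    light = series["light_raw"].to_numpy(dtype=float) if "light_raw" in series else None
    ts0 = pd.to_datetime(series["timestamp"].iloc[0]) if "timestamp" in series else None
    if zero_offset:
        z = zero_offset_correct(t, z)

    # split at large gaps, interpolate small ones to the nominal 1-s grid
    split_at = np.nonzero(np.diff(t) > max_gap_s)[0] + 1
    dives: list[DiveRecord] = []
    for seg_t, seg_z, seg_l in zip(
        np.split(t, split_at), np.split(z, split_at),
        np.split(light, split_at) if light is not None else [None] * (len(split_at) + 1),
    ):
        if seg_t.size < 3:
            continue
        grid = np.arange(seg_t[0], seg_t[-1] + 0.5)
        gz = np.interp(grid, seg_t, seg_z)
        gl = np.interp(grid, seg_t, seg_l) if seg_l is not None else None

        submerged = gz > surface_threshold
        padded = np.concatenate([[False], submerged, [False]])
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
        for s, e in zip(starts, ends):
            lo = max(s - 1, 0)          # include bounding surface samples
            hi = min(e + 1, gz.size)
            dz = gz[lo:hi]
            if dz.max() < dive_threshold:
                continue
            dt = grid[lo:hi]
            b_start, b_end, b_time = bottom_phase(dt, dz, bottom_fraction)
            und = count_undulations(dz)
            in_bottom = (dt >= b_start) & (dt <= b_end)
            b_und = count_undulations(dz[in_bottom])
            cls = classify_dive(dz.max(), b_und, shallow_threshold)
            l5 = lb = np.nan
            if gl is not None:
                l5, lb = dive_light_summary(dt, dz, gl[lo:hi], b_start, b_end)
            dives.append(
                DiveRecord(
                    tag_id=tag_id,
                    start_s=float(dt[0]),
                    end_s=float(dt[-1]),
                    max_depth=float(dz.max()),
                    duration=float(dt[-1] - dt[0]),
                    bottom_start_s=b_start,
                    bottom_end_s=b_end,
                    bottom_time=b_time,
                    undulations=und,
                    bottom_undulations=b_und,
                    dive_class=cls,
                    light_5m=l5,
                    light_bottom=lb,
                    start_time=(ts0 + pd.Timedelta(seconds=float(dt[0] - t[0])))
                    if ts0 is not None
                    else None,
                )
            )
    dives.sort(key=lambda d: d.start_s)
    return dives


def dives_to_frame(dives) -> pd.DataFrame:
    """Per-dive summary table."""
    cols = [
        "tag_id", "start_s", "end_s", "start_time", "max_depth", "duration",
        "bottom_time", "undulations", "bottom_undulations", "dive_class",
        "light_5m", "light_bottom", "lon", "lat", "minutes_from_tkp",
        "distance_to_edge_km",
    ]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dives], columns=cols)


def assign_locations(
    dive_table: pd.DataFrame,
    fixes: pd.DataFrame,
    max_age_min: float = 30.0,
) -> pd.DataFrame:
    """Attach the temporally nearest satellite fix to each dive.

    ``fixes`` has ``timestamp, lon, lat, is_tkp`` on an interpolated 15-min
    grid.  Each fix's interpolation age is its time from the nearest
    temporally-known position (TKP); dives whose nearest fix is more than
    ``max_age_min`` from a TKP keep a missing location and are excluded from
    spatial models downstream.
    """
    out = dive_table.copy()
    out[["lon", "lat"]] = np.nan
    out["minutes_from_tkp"] = np.nan
    if len(fixes) == 0:
        return out
    fx = fixes.sort_values("timestamp").reset_index(drop=True)
    ft = pd.to_datetime(fx["timestamp"]).astype("int64").to_numpy() / 1e9
    tkp_t = ft[fx["is_tkp"].astype(bool).to_numpy()]
    if tkp_t.size:
        age_min = np.min(np.abs(ft[:, None] - tkp_t[None, :]), axis=1) / 60.0
    else:
        age_min = np.full(ft.shape, np.inf)

    dt = pd.to_datetime(out["start_time"]).astype("int64").to_numpy() / 1e9
    nearest = np.argmin(np.abs(ft[None, :] - dt[:, None]), axis=1)
    ok = age_min[nearest] <= max_age_min
    out.loc[ok, "lon"] = fx["lon"].to_numpy()[nearest[ok]]
    out.loc[ok, "lat"] = fx["lat"].to_numpy()[nearest[ok]]
    out.loc[ok, "minutes_from_tkp"] = age_min[nearest[ok]]
    return out


def load_dated_edges(path_or_obj):
    """Load dated ice-edge polylines from GeoJSON.

    Accepts a path or an already-parsed FeatureCollection.  Each LineString
    feature must carry a ``valid_from`` date property; the edge in force on a
    date is the one with the latest ``valid_from`` not after it.
    """
    if isinstance(path_or_obj, (str,)):
        with open(path_or_obj) as fh:
            obj = json.load(fh)
    else:
        obj = path_or_obj
    edges = []
    for feat in obj["features"]:
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            continue
        edges.append(
            {
                "valid_from": pd.Timestamp(feat["properties"]["valid_from"]),
                "coords": np.asarray(geom["coordinates"], dtype=float),
            }
        )
    edges.sort(key=lambda e: e["valid_from"])
    if not edges:
        raise ValueError("no LineString features with valid_from dates found")
    return edges


def distance_to_edge(lon: float, lat: float, edges, date) -> float:
    """Minimum great-circle distance (km) from a point to the dated ice edge.

    The segment geometry is projected onto a local tangent plane centred on
    the query point (equirectangular, metre-true at the point), which is
    accurate to well under 1% at the tens-of-km scales involved.
    """
    date = pd.Timestamp(date)
    valid = [e for e in edges if e["valid_from"] <= date]
    if not valid:
        raise ValueError(f"no ice-edge polyline valid on {date.date()}")
    coords = valid[-1]["coords"]
    coslat = math.cos(math.radians(lat))
    x = (coords[:, 0] - lon) * coslat * KM_PER_DEG
    y = (coords[:, 1] - lat) * KM_PER_DEG
    return float(Point(0.0, 0.0).distance(LineString(np.column_stack([x, y]))))


def attach_edge_distance(dive_table: pd.DataFrame, edges, date_col: str = "start_time"):
    """Fill ``distance_to_edge_km`` for located dives using the dated edges."""
    out = dive_table.copy()
    dists = []
    for _, row in out.iterrows():
        if np.isnan(row.get("lon", np.nan)):
            dists.append(np.nan)
        else:
            dists.append(distance_to_edge(row["lon"], row["lat"], edges, row[date_col]))
    out["distance_to_edge_km"] = dists
    return out
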