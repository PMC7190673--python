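"""Echogram processing: binning, aggregation delineation and backscatter summaries.

Volume backscattering strength (Sv, dB re 1 m**-1) is a logarithmic quantity;
every mean in this module is taken in the linear domain (s = 10**(Sv/10)) and
converted back to dB, the standard convention in fisheries acoustics.  Grids
are depth-by-time matrices of Sv with 1-m depth bins (top edge at 0 m,
positive downward) and 6-s time bins by default; missing cells are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "EchogramGrid",
    "Aggregation",
    "DEFAULT_CLASSIFICATION_RULES",
    "db_to_linear",
    "linear_to_db",
    "mean_sv_db",
    "bin_echogram",
    "delineate_aggregations",
    "classify_aggregation",
    "aggregation_mean_sv",
    "weighted_mean_depth",
    "bootstrap_ci",
    "aggregations_to_frame",
    "aggregation_cells_frame",
    "period_summary",
]


def db_to_linear(value_db):
    """Convert Sv in dB re 1 m**-1 to linear backscattering coefficient."""
    return np.power(10.0, np.asarray(value_db, dtype=float) / 10.0)


def linear_to_db(value_linear):
    """Convert linear backscattering coefficient to dB re 1 m**-1."""
    value_linear = np.asarray(value_linear, dtype=float)
    if np.any(value_linear <= 0):
        raise ValueError("linear backscatter must be strictly positive")
    return 10.0 * np.log10(value_linear)


def mean_sv_db(sv_db, axis=None):
    """Linear-domain mean of Sv values, reported in dB.

    NaN cells are ignored.  Raises on empty input.
    """
    sv_db = np.asarray(sv_db, dtype=float)
    if sv_db.size == 0 or np.all(np.isnan(sv_db)):
        raise ValueError("mean_sv_db requires at least one finite Sv value")
    return 10.0 * np.log10(np.nanmean(db_to_linear(sv_db), axis=axis))


@dataclass
class EchogramGrid:
    """Depth-binned echogram for one station deployment.

    ``sv`` is indexed ``[depth_bin, time_bin]``.  ``depth_edges`` has length
    ``n_depth + 1`` starting at 0 m; ``time_bin_s`` and ``ping_interval_s``
    relate grid columns to raw pings (6-s bins at 1 ping per second by
    default, so one column integrates six pings).
    """

    station_id: str
    location_class: str
    sv: np.ndarray
    depth_edges: np.ndarray
    deployment_date: pd.Timestamp | None = None
    time_bin_s: float = 6.0
    ping_interval_s: float = 1.0

    def __post_init__(self):
        self.sv = np.asarray(self.sv, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        if self.location_class not in ("edge", "interior"):
            raise ValueError(f"location_class must be edge/interior, got {self.location_class!r}")
        if np.any(np.diff(self.depth_edges) <= 0):
            raise ValueError("depth_edges must be strictly increasing")
        if len(self.depth_edges) != self.sv.shape[0] + 1:
            raise ValueError("depth_edges length must be n_depth_bins + 1")
        if self.time_bin_s <= 0 or self.ping_interval_s <= 0:
            raise ValueError("bin widths must be positive")

    @property
    def depth_mids(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def pings_per_bin(self) -> float:
        return self.time_bin_s / self.ping_interval_s


@dataclass
class Aggregation:
    """A delineated prey patch: a connected set of above-threshold cells."""

    station_id: str
    depth_idx: np.ndarray
    time_idx: np.ndarray
    depth_mids: np.ndarray
    sv_db: np.ndarray
    ping_width: int
    taxon: str = "unknown"

    def __post_init__(self):
        if self.sv_db.size == 0:
            raise ValueError("aggregation must contain at least one cell")

    @property
    def n_cells(self) -> int:
        return int(self.sv_db.size)

    @property
    def depth_extent_m(self) -> float:
        return float(self.depth_mids.max() - self.depth_mids.min() + 1.0)

    @property
    def mean_sv(self) -> float:
        return float(mean_sv_db(self.sv_db))

    @property
    def linear_sum(self) -> float:
        return float(db_to_linear(self.sv_db).sum())

    @property
    def weighted_depth(self) -> float:
        return float(weighted_mean_depth(self))


def bin_echogram(
    pings: pd.DataFrame,
    station_id: str = "",
    location_class: str = "interior",
    time_bin_s: float = 6.0,
    depth_bin_m: float = 1.0,
    max_depth_m: float = 200.0,
    ping_interval_s: float = 1.0,
    deployment_date=None,
) -> EchogramGrid:
    """Integrate raw ping samples onto a regular time-depth grid.

    ``pings`` is long-format with columns ``time_s`` (seconds from deployment
    start, ascending), ``depth_m`` and ``sv_db``.  Cell values are the
    linear-domain mean of all contributing samples; cells with no samples are
    NaN (absence of data, not zero backscatter).
    """
    required = {"time_s", "depth_m", "sv_db"}
    if not required.issubset(pings.columns):
        raise ValueError(f"ping table must have columns {sorted(required)}")
    t = pings["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(np.unique(pings["time_s"])) < 0) or np.any(np.diff(t) < -1e-9):
        raise ValueError("ping timestamps must be non-decreasing")

    n_t = int(np.ceil((t.max() + 1e-9) / time_bin_s)) if len(t) else 1
    n_z = int(round(max_depth_m / depth_bin_m))
    ti = np.clip((t / time_bin_s).astype(int), 0, n_t - 1)
    zi = (pings["depth_m"].to_numpy(dtype=float) / depth_bin_m).astype(int)
    keep = (zi >= 0) & (zi < n_z)
    ti, zi = ti[keep], zi[keep]
    lin = db_to_linear(pings["sv_db"].to_numpy(dtype=float)[keep])

    acc = np.zeros((n_z, n_t))
    cnt = np.zeros((n_z, n_t))
    np.add.at(acc, (zi, ti), lin)
    np.add.at(cnt, (zi, ti), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sv = 10.0 * np.log10(acc / cnt)
    sv[cnt == 0] = np.nan

    return EchogramGrid(
        station_id=station_id,
        location_class=location_class,
        sv=sv,
        depth_edges=np.arange(n_z + 1, dtype=float) * depth_bin_m,
        deployment_date=deployment_date,
        time_bin_s=time_bin_s,
        ping_interval_s=ping_interval_s,
    )


def delineate_aggregations(
    grid: EchogramGrid,
    sv_threshold: float = -95.0,
    min_ping_width: int = 5,
) -> list[Aggregation]:
    """Find prey aggregations as 4-connected components of cells >= threshold.

    Components narrower than ``min_ping_width`` pings are discarded (patches
    must be more than 4 pings wide to count as aggregations).  Width in pings
    is the time-bin span times the pings integrated per bin.  Output is
    deterministically ordered by first time bin, then shallowest depth bin.
    """
    mask = np.where(np.isnan(grid.sv), False, grid.sv >= sv_threshold)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    out = []
    mids = grid.depth_mids
    for lab in range(1, n + 1):
        zi, ti = np.nonzero(labels == lab)
        width_bins = int(ti.max() - ti.min() + 1)
        ping_width = int(round(width_bins * grid.pings_per_bin))
        if ping_width < min_ping_width:
            continue
        order = np.lexsort((zi, ti))
        zi, ti = zi[order], ti[order]
        out.append(
            Aggregation(
                station_id=grid.station_id,
                depth_idx=zi,
                time_idx=ti,
                depth_mids=mids[zi],
                sv_db=grid.sv[zi, ti],
                ping_width=ping_width,
            )
        )
    out.sort(key=lambda a: (int(a.time_idx.min()), int(a.depth_idx.min())))
    return out


# Rule table standing in for visual ground-truthing of acoustic aggregations.
# Crystal krill swarms concentrate in the upper water column; silverfish
# aggregations sit deeper.  An aggregation matching no rule stays "unknown".
DEFAULT_CLASSIFICATION_RULES = [
    {"taxon": "krill", "depth_range": (0.0, 60.0), "sv_range": (-95.0, -55.0)},
    {"taxon": "silverfish", "depth_range": (60.0, 200.0), "sv_range": (-100.0, -60.0)},
]


def classify_aggregation(agg: Aggregation, rules=None) -> str:
    """Assign a taxon from a rule table on weighted depth and mean Sv.

    Rules are checked in order; the first rule whose depth and Sv intervals
    both contain the aggregation's backscatter-weighted depth and mean Sv
    wins.  Deterministic: identical patches get identical labels.
    """
    if rules is None:
        rules = DEFAULT_CLASSIFICATION_RULES
    if not rules:
        raise ValueError("classification rule table is empty")
    depth = agg.weighted_depth
    sv = agg.mean_sv
    for rule in rules:
        zlo, zhi = rule["depth_range"]
        slo, shi = rule["sv_range"]
        if zlo <= depth < zhi and slo <= sv <= shi:
            return rule["taxon"]
    return "unknown"


def aggregation_mean_sv(aggs) -> float:
    """Linear-domain mean Sv (dB) over aggregations or a plain cell array."""
    if isinstance(aggs, Aggregation):
        return aggs.mean_sv
    if len(aggs) == 0:
        raise ValueError("no aggregations")
    if isinstance(aggs[0], Aggregation):
        cells = np.concatenate([a.sv_db for a in aggs])
    else:
        cells = np.asarray(aggs, dtype=float)
    return float(mean_sv_db(cells))


def weighted_mean_depth(agg: Aggregation) -> float:
    """Backscatter-weighted mean cell mid-depth (m) of an aggregation."""
    w = db_to_linear(agg.sv_db)
    return float(np.sum(w * agg.depth_mids) / np.sum(w))


def bootstrap_ci(values, stat=np.mean, n_boot: int = 10000, level: float = 0.95, seed=None):
    """Percentile bootstrap confidence interval for ``stat`` of a sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap_ci requires a non-empty sample")
    if values.size == 1 or np.ptp(values) == 0:
        v = float(stat(values))
        return (v, v)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    reps = stat(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def aggregations_to_frame(aggs, taxa=None) -> pd.DataFrame:
    """One row per aggregation: station, taxon, size, mean Sv, weighted depth."""
    rows = []
    for i, a in enumerate(aggs):
        rows.append(
            {
                "station_id": a.station_id,
                "taxon": taxa[i] if taxa is not None else a.taxon,
                "n_cells": a.n_cells,
                "ping_width": a.ping_width,
                "depth_extent_m": a.depth_extent_m,
                "mean_sv_db": a.mean_sv,
                "weighted_depth_m": a.weighted_depth,
                "linear_sum": a.linear_sum,
            }
        )
    cols = [
        "station_id", "taxon", "n_cells", "ping_width", "depth_extent_m",
        "mean_sv_db", "weighted_depth_m", "linear_sum",
    ]
    return pd.DataFrame(rows, columns=cols)


def aggregation_cells_frame(aggs, taxa=None) -> pd.DataFrame:
    """One row per member cell of each aggregation (for depth-binned pooling)."""
    rows = []
    for i, a in enumerate(aggs):
        taxon = taxa[i] if taxa is not None else a.taxon
        rows.append(
            pd.DataFrame(
                {
                    "station_id": a.station_id,
                    "taxon": taxon,
                    "depth_mid_m": a.depth_mids,
                    "sv_db": a.sv_db,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["station_id", "taxon", "depth_mid_m", "sv_db"])
    return pd.concat(rows, ignore_index=True)


def period_summary(
    agg_table: pd.DataFrame,
    station_table: pd.DataFrame,
    period_starts,
    taxa=("krill", "silverfish"),
    n_boot: int = 10000,
    seed=None,
    weighting: str = "cell",
) -> pd.DataFrame:
    """Summarize aggregation backscatter per (period, location class, taxon).

    ``agg_table`` comes from :func:`aggregations_to_frame`; ``station_table``
    must carry ``station_id``, ``location_class`` and ``deployment_date``.
    Periods are half-open date intervals between consecutive ``period_starts``
    (the last extends 6 days).  Mean Sv is linear-domain; with the default
    ``cell`` weighting every member cell counts equally, with ``aggregation``
    each patch counts once.  95% CIs are percentile bootstrap over
    aggregations.  Rows with no detected aggregations report NaN ("none").
    """
    if weighting not in ("cell", "aggregation"):
        raise ValueError("weighting must be 'cell' or 'aggregation'")
    starts = pd.to_datetime(pd.Series(list(period_starts))).sort_values().reset_index(drop=True)
    edges = list(starts) + [starts.iloc[-1] + pd.Timedelta(days=6)]

    st = station_table.set_index("station_id")
    df = agg_table.merge(
        st[["location_class", "deployment_date"]], left_on="station_id", right_index=True, how="left"
    )
    df["deployment_date"] = pd.to_datetime(df["deployment_date"])
    outside = df["deployment_date"] < edges[0]
    if outside.any():
        warnings.warn(f"{int(outside.sum())} aggregations dated before the first period; excluded")
        df = df[~outside]

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(len(starts)):
        in_period = (df["deployment_date"] >= edges[p]) & (df["deployment_date"] < edges[p + 1])
        for loc in ("interior", "edge"):
            for taxon in taxa:
                sub = df[in_period & (df["location_class"] == loc) & (df["taxon"] == taxon)]
                row = {
                    "period": p + 1,
                    "period_start": edges[p],
                    "location_class": loc,
                    "taxon": taxon,
                    "n_aggregations": len(sub),
                }
                if len(sub) == 0:
                    row.update(
                        mean_sv_db=np.nan, sv_lo=np.nan, sv_hi=np.nan,
                        mean_depth_m=np.nan, depth_lo=np.nan, depth_hi=np.nan,
                    )
                else:
                    if weighting == "cell":
                        lin = sub["linear_sum"].to_numpy()
                        mean_sv = 10.0 * np.log10(lin.sum() / sub["n_cells"].sum())
                        mean_depth = float(
                            np.sum(lin * sub["weighted_depth_m"].to_numpy()) / lin.sum()
                        )
                    else:
                        mean_sv = float(mean_sv_db(sub["mean_sv_db"].to_numpy()))
                        mean_depth = float(sub["weighted_depth_m"].mean())
                    sv_lo, sv_hi = bootstrap_ci(
                        sub["mean_sv_db"].to_numpy(),
                        stat=lambda v, axis=None: 10.0
                        * np.log10(np.mean(np.power(10.0, v / 10.0), axis=axis)),
                        n_boot=n_boot,
                        seed=rng.integers(2**31),
                    )
                    depth_lo, depth_hi = bootstrap_ci(
                        sub["weighted_depth_m"].to_numpy(), n_boot=n_boot, seed=rng.integers(2**31)
                    )
                    row.update(
                        mean_sv_db=mean_sv, sv_lo=sv_lo, sv_hi=sv_hi,
                        mean_depth_m=mean_depth, depth_lo=depth_lo, depth_hi=depth_hi,
                    )
                rows.append(row)
    return pd.DataFrame(rows)
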