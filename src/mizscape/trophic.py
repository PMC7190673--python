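"""Diet-preyscape rank correlations over 5-6 day periods.

Daily chick-feed diet observations and preyscape/foraging variables are
binned into the campaign's 5-6 day periods; each preyscape variable is then
correlated with the krill fraction of the diet by tie-corrected Kendall
tau-b, with Holm-Bonferroni adjustment across the family of tests.  Periods
where a variable was not measured (e.g. no aggregations detected) are
missing, not zero, so n varies by variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bin_periods",
    "period_diet_table",
    "kendall_tau_b",
    "holm_bonferroni",
    "correlate_preyscape_diet",
]


def bin_periods(observations: pd.DataFrame, period_starts, date_col: str = "date",
                last_period_days: int = 6) -> pd.DataFrame:
    """Assign each dated observation to a period.

    Period ``i`` spans ``[start_i, start_{i+1})``; the last period extends
    ``last_period_days``.  Observations before the first start (or at/after
    the end of the last period) are dropped with a warning.
    """
    starts = pd.to_datetime(pd.Series(list(period_starts))).sort_values().reset_index(drop=True)
    if starts.duplicated().any():
        raise ValueError("period starts must be strictly increasing")
    out = observations.copy()
    dates = pd.to_datetime(out[date_col])
    end = starts.iloc[-1] + pd.Timedelta(days=last_period_days)
    outside = (dates < starts.iloc[0]) | (dates >= end)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} observations outside the period range; excluded")
    out = out[~outside].copy()
    edges = np.array(list(starts) + [end], dtype="datetime64[ns]")
    out["period"] = np.digitize(
        pd.to_datetime(out[date_col]).to_numpy().astype("datetime64[ns]").astype("int64"),
        edges.astype("int64"),
    )
    return out


def period_diet_table(diet: pd.DataFrame, period_starts, date_col: str = "date") -> pd.DataFrame:
    """Per-period mean (and SD) diet fractions from per-feed observations.

    ``diet`` columns: ``date`` plus any of ``pct_krill, pct_fish, pct_other``
    (percent of the feed).  Periods with no feeds yield no row.
    """
    binned = bin_periods(diet, period_starts, date_col=date_col)
    starts = pd.to_datetime(pd.Series(list(period_starts))).sort_values().reset_index(drop=True)
    frac_cols = [c for c in ("pct_krill", "pct_fish", "pct_other") if c in binned.columns]
    rows = []
    for p, grp in binned.groupby("period"):
        row = {"period": int(p), "period_start": starts.iloc[int(p) - 1], "n_feeds": len(grp)}
        for c in frac_cols:
            row[c] = float(grp[c].mean())
            row[c + "_sd"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def kendall_tau_b(x, y, method: str = "auto"):
    """Tie-corrected Kendall rank correlation tau-b and its p-value.

    Pairs with a missing member are dropped; at least 3 complete pairs are
    required.  ``method`` is passed to the underlying test ("exact" is valid
    only for tie-free data; "auto" picks exact for small tie-free samples and
    the tie-adjusted normal approximation otherwise).  A margin with all
    values tied leaves tau undefined: returns (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("a margin is entirely tied; tau-b undefined")
        return (np.nan, np.nan)
    res = stats.kendalltau(x, y, variant="b", method=method)
    return (float(res.statistic), float(res.pvalue))


def holm_bonferroni(p_values):
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def correlate_preyscape_diet(
    period_table: pd.DataFrame,
    variables,
    response: str = "fraction_krill",
    min_periods: int = 3,
) -> pd.DataFrame:
    """Kendall tau-b of each preyscape/foraging variable against the krill
    diet fraction across periods, Holm-adjusted across the family.

    Uses pairwise-complete periods per variable, so ``n_periods`` varies.
    Variables with fewer than ``min_periods`` complete pairs, or an all-tied
    margin, are reported with NaN tau and excluded from the Holm family.
    """
    rows = []
    for var in variables:
        x = period_table[var].to_numpy(dtype=float)
        y = period_table[response].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        n = int(keep.sum())
        if n < min_periods:
            rows.append({"variable": var, "tau_b": np.nan, "p_raw": np.nan, "n_periods": n})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau, p = kendall_tau_b(x[keep], y[keep])
        rows.append({"variable": var, "tau_b": tau, "p_raw": p, "n_periods": n})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    testable = out["p_raw"].notna()
    if testable.any():
        out.loc[testable, "p_holm"] = holm_bonferroni(out.loc[testable, "p_raw"].to_numpy())
    return out
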