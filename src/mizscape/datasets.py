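"""Published summary tables from the 2014-15 McMurdo Sound field campaign.

The campaign observed Adelie penguin chick-feed diet, penguin biologging and
ROV acoustic preyscape surveys at the fast ice edge near Cape Royds from
14 December 2014 to 22 January 2015, in eight 5-6 day diet periods (five of
which overlap the acoustic sampling).  These tables are the package's
reference inputs for the cross-table rank correlations and the fixed-effect
predictions; missing entries ("no data" / "none detected") are NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PERIOD_STARTS",
    "ACOUSTIC_PERIOD_STARTS",
    "diet_periods",
    "preyscape_periods",
    "edge_distance_models",
    "diel_models",
]

#: Start dates of the eight 5-6 day diet periods.
PERIOD_STARTS = [
    "2014-12-14", "2014-12-20", "2014-12-25", "2014-12-30",
    "2015-01-04", "2015-01-09", "2015-01-14", "2015-01-19",
]

#: The first five periods, which overlap the acoustic preyscape sampling.
ACOUSTIC_PERIOD_STARTS = PERIOD_STARTS[:5]

_ND = np.nan


def diet_periods() -> pd.DataFrame:
    """Per-period diet composition, foraging summaries, whale presence and
    1% light depth.  Diet values are percent of chick feeds (SD in the
    companion column); foraging columns are period means across tagged birds.
    """
    cols = [
        "period", "start_date", "pct_fish", "pct_fish_sd", "pct_krill", "pct_krill_sd",
        "foraging_distance_km", "foraging_distance_sd", "foraging_depth_m",
        "foraging_depth_sd", "trip_duration_hr", "trip_duration_sd",
        "whale_presence", "depth_1pct_light_m", "depth_1pct_light_sd",
    ]
    rows = [
        (1, "2014-12-14", 7.4, 25.0, 83.9, 36.4, _ND, _ND, _ND, _ND, _ND, _ND, 0, 44.0, 41.0),
        (2, "2014-12-20", 19.0, 39.2, 81.0, 39.2, 10.3, 1.3, 47.4, 17.3, 13.3, 5.8, 0, 15.0, 27.0),
        (3, "2014-12-25", 33.8, 45.4, 62.3, 46.7, 12.2, 2.0, 52.9, 14.6, 19.1, 8.6, 1, 7.0, 3.0),
        (4, "2014-12-30", 45.2, 49.8, 54.8, 49.8, 11.9, 3.4, 49.5, 17.1, 16.2, 6.8, 1, 22.0, 28.0),
        (5, "2015-01-04", 50.0, 52.2, 50.0, 52.2, 11.9, 5.0, 46.7, 21.1, 16.9, 9.4, 1, 12.0, 5.0),
        (6, "2015-01-09", 55.9, 44.1, 44.1, 44.1, 10.9, 6.2, 54.0, 18.6, 26.7, 12.2, 1, _ND, _ND),
        (7, "2015-01-14", 47.9, 43.2, 52.1, 52.1, 10.8, 8.3, 50.6, 18.3, 12.0, 4.3, 1, _ND, _ND),
        (8, "2015-01-19", 44.5, 51.3, 55.5, 51.2, _ND, _ND, _ND, _ND, _ND, _ND, 1, _ND, _ND),
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["start_date"] = pd.to_datetime(df["start_date"])
    return df


def preyscape_periods() -> pd.DataFrame:
    """Acoustic preyscape summaries for periods 1-5, long format: one row per
    (period, location class, taxon) with linear-domain mean Sv (dB re m**-1),
    backscatter-weighted mean depth (m) and bootstrap 95% CIs.  Periods with
    no detected aggregations of a taxon are NaN.
    """
    cols = [
        "period", "location_class", "taxon",
        "mean_sv_db", "sv_lo", "sv_hi", "mean_depth_m", "depth_lo", "depth_hi",
    ]
    n = _ND
    rows = [
        (1, "interior", "silverfish", -80.2, -80.4, -80.0, 81.9, 80.1, 83.6),
        (1, "interior", "krill", -88.7, -89.8, -87.7, 37.4, 33.3, 41.9),
        (1, "edge", "silverfish", -80.6, -81.6, -79.5, 84.8, 74.4, 93.8),
        (1, "edge", "krill", -81.8, -81.9, -81.7, 91.4, 90.7, 92.0),
        (2, "interior", "silverfish", -98.4, -99.7, -97.1, 16.3, 13.4, 19.3),
        (2, "interior", "krill", -82.0, -82.3, -81.6, 32.6, 29.4, 37.5),
        (2, "edge", "silverfish", n, n, n, n, n, n),
        (2, "edge", "krill", -80.6, -80.8, -80.4, 89.8, 89.6, 90.1),
        (3, "interior", "silverfish", -92.6, -92.7, -92.4, 126.0, 124.0, 127.0),
        (3, "interior", "krill", -75.1, -75.2, -75.0, 29.0, 28.8, 29.2),
        (3, "edge", "silverfish", n, n, n, n, n, n),
        (3, "edge", "krill", -88.3, -88.6, -87.9, 24.9, 24.0, 26.2),
        (4, "interior", "silverfish", -94.3, -94.7, -93.9, 77.5, 73.7, 81.2),
        (4, "interior", "krill", -93.8, -94.2, -93.4, 58.6, 55.3, 61.6),
        (4, "edge", "silverfish", -95.0, -95.5, -94.5, 25.2, 24.8, 25.7),
        (4, "edge", "krill", -98.4, -99.5, -97.4, 23.0, 21.9, 24.2),
        (5, "interior", "silverfish", n, n, n, n, n, n),
        (5, "interior", "krill", -73.0, -73.3, -72.6, 24.6, 23.1, 26.0),
        (5, "edge", "silverfish", n, n, n, n, n, n),
        (5, "edge", "krill", -78.4, -78.6, -78.1, 50.1, 49.1, 51.1),
    ]
    return pd.DataFrame(rows, columns=cols)


def edge_distance_models() -> pd.DataFrame:
    """Campaign mixed-model estimates: dive criteria on distance to the fast
    ice edge (km), random intercept per penguin.  Log-transformed criteria
    are flagged; coefficients are per km on the (possibly log) criterion
    scale.
    """
    cols = [
        "criterion", "log_transformed", "mean", "sd", "coefficient", "se", "z", "p",
        "marginal_r2", "var_intercept", "sd_intercept", "var_residual", "sd_residual",
        "within_id_corr",
    ]
    rows = [
        ("light_bottom", True, 2.8, 1.4, 0.035, 0.003, 11.899, 0.001, 0.014,
         0.552, 0.743, 0.427, 0.653, -0.044),
        ("light_5m", True, 152.0, 150.0, 0.000, 0.002, -0.014, 1.0, _ND,
         0.061, 0.248, 0.197, 0.444, -0.089),
        ("max_depth", False, 51.0, 18.0, -0.682, 0.069, -9.930, 0.001, 0.014,
         150.7, 12.3, 236.7, 15.4, -0.062),
        ("undulations", False, 15.7, 7.4, -0.098, 0.028, -3.506, 0.001, 0.002,
         17.0, 4.12, 38.5, 6.21, -0.075),
    ]
    return pd.DataFrame(rows, columns=cols)


def diel_models() -> pd.DataFrame:
    """Campaign mixed-model estimates: dive criteria on the daily cosine
    (peak 14:00 local solar), random intercept per penguin."""
    cols = [
        "criterion", "log_transformed", "coefficient", "se", "t", "p",
        "marginal_r2", "var_intercept", "sd_intercept", "var_residual", "sd_residual",
        "within_id_corr",
    ]
    rows = [
        ("light_5m", True, 0.282, 0.007, 39.8, 0.001, 0.16, 0.043, 0.207, 0.161, 0.401, 0.010),
        ("light_bottom", True, 0.142, 0.012, 12.4, 0.001, 0.01, 0.537, 0.732, 0.426, 0.653, 0.005),
        ("max_depth", False, 1.377, 0.273, 5.0, 0.001, 0.001, 134.3, 11.59, 239.2, 15.46, 0.007),
        ("edge_distance", True, 0.166, 0.017, 9.7, 0.001, 0.01, 0.456, 0.676, 0.941, 0.970, 0.007),
        ("undulations", True, -0.052, 0.007, -6.9, 0.001, 0.01, 0.075, 0.274, 0.180, 0.424, 0.008),
        ("duration", False, -0.885, 0.374, -2.4, 0.02, 0.00, 212.0, 14.6, 448.0, 21.1, 0.007),
        ("n_dives", False, -0.068, 0.012, 5.3, 0.001, 0.00, 0.048, 0.204, _ND, _ND, 0.019),
    ]
    return pd.DataFrame(rows, columns=cols)
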