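"""End-to-end pipeline: synth -> echo -> permutation -> dives -> light ->
models -> correlations, reproducible from a config dict + seed.

All interchange is plain CSV/JSON; the run manifest records the package
version, every seed and threshold, and a SHA-256 digest per output table so
a rerun with the same config can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__, datasets
from .dives import (
    assign_locations, attach_edge_distance, detect_dives, dives_to_frame, load_dated_edges,
)
from .echo import (
    aggregation_cells_frame, aggregations_to_frame, classify_aggregation,
    delineate_aggregations, period_summary,
)
from .models import fit_random_intercept_model
from .optics import depth_1pct_light
from .permutation import permutation_depth_table
from .synthetic import (
    DietScenario, DiveScenario, SurveyScenario, gen_chl_profiles, gen_diet_predator_series,
    gen_dive_dataset, gen_echogram_survey,
)
from .trophic import correlate_preyscape_diet, period_diet_table

__all__ = ["default_config", "run_pipeline"]


def default_config(seed: int = 0) -> dict:
    """A compact default synthetic run (scaled for quick execution)."""
    return {
        "seed": seed,
        "out_dir": "mizscape_run",
        "survey": {"rng_seed": seed, "pings_per_station": 300},
        "dives": {"rng_seed": seed + 1, "n_penguins": 6, "trips_per_penguin": 1,
                  "dives_per_trip": 20},
        "diet": {"rng_seed": seed + 2},
        "chl": {"bloom_max": 15.0, "bloom_depth_extent": 60.0, "n_profiles": 5,
                "seed": seed + 3},
        "sv_threshold": -95.0,
        "permutation_B": 2000,
        "bootstrap_B": 2000,
        "period_starts": list(datasets.ACOUSTIC_PERIOD_STARTS),
    }


def _digest(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run every stage on synthetic inputs and write the result bundle.

    Emits preyscape period summaries, the permutation depth table, per-dive
    records, mixed-model summaries (edge distance and diel), 1% light
    depths, the period table and diet correlations, plus ``manifest.json``.
    Stage failures raise with the failing stage named.
    """
    out = pathlib.Path(config.get("out_dir", "mizscape_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    written: dict[str, pathlib.Path] = {}
    stage = "init"
    try:
        stage = "synth_survey"
        survey = SurveyScenario(**config.get("survey", {}))
        grids, stations, _truth = gen_echogram_survey(survey)

        stage = "echo"
        aggs, taxa = [], []
        for g in grids:
            for a in delineate_aggregations(g, sv_threshold=config.get("sv_threshold", -95.0)):
                a.taxon = classify_aggregation(a)
                aggs.append(a)
                taxa.append(a.taxon)
        agg_table = aggregations_to_frame(aggs)
        cells = aggregation_cells_frame(aggs)
        periods = period_summary(
            agg_table, stations, config["period_starts"],
            n_boot=int(config.get("bootstrap_B", 2000)), seed=seed,
        )
        written["preyscape_periods"] = out / "preyscape_periods.csv"
        periods.to_csv(written["preyscape_periods"], index=False)

        stage = "permutation"
        perm = permutation_depth_table(
            cells, stations, n_permutations=int(config.get("permutation_B", 2000)), seed=seed,
        )
        written["permutation_table"] = out / "permutation_table.csv"
        perm.to_csv(written["permutation_table"], index=False)

        stage = "dives"
        dive_scn = DiveScenario(**config.get("dives", {}))
        truth_table, tdr, fixes, edges_geojson = gen_dive_dataset(dive_scn)
        records = []
        for tag, sub in tdr.groupby("tag_id", sort=True):
            records.extend(detect_dives(sub.reset_index(drop=True), tag_id=str(tag)))
        dive_table = dives_to_frame(records)
        dive_table = assign_locations(dive_table, fixes)
        edges = load_dated_edges(edges_geojson)
        dive_table = attach_edge_distance(dive_table, edges)
        dive_table["penguin_id"] = dive_table["tag_id"]
        written["dive_records"] = out / "dive_records.csv"
        dive_table.to_csv(written["dive_records"], index=False)

        stage = "models"
        located = dive_table.dropna(subset=["distance_to_edge_km"])
        hours = pd.to_datetime(located["start_time"])
        located = located.assign(
            diel=np.cos(2 * np.pi * ((hours.dt.hour + hours.dt.minute / 60.0) - 14.0) / 24.0)
        )
        model_rows = []
        for fixed in ("distance_to_edge_km", "diel"):
            for crit, logc in (("max_depth", False), ("undulations", False),
                               ("light_bottom", True)):
                fit = fit_random_intercept_model(
                    located, crit, fixed, group="penguin_id", log_criterion=logc
                )
                model_rows.append(
                    {"fixed": fixed, "criterion": crit, "coefficient": fit.coefficient,
                     "se": fit.se, "z": fit.z, "p": fit.p, "marginal_r2": fit.marginal_r2,
                     "var_intercept": fit.var_intercept, "var_residual": fit.var_residual,
                     "within_id_corr": fit.within_id_corr, "n_obs": fit.n_obs,
                     "n_groups": fit.n_groups, "log_transformed": fit.log_transformed}
                )
        written["mixed_models"] = out / "mixed_models.csv"
        pd.DataFrame(model_rows).to_csv(written["mixed_models"], index=False)

        stage = "light"
        chl = gen_chl_profiles(**config.get("chl", {}))
        light_rows = []
        for p, prof in chl.groupby("profile_id"):
            res = depth_1pct_light(prof["depth_m"].to_numpy(), prof["chl_mg_m3"].to_numpy())
            light_rows.append({"profile_id": p, "depth_1pct_m": res.depth_m,
                               "reached": res.reached})
        written["light_depths"] = out / "light_depths.csv"
        pd.DataFrame(light_rows).to_csv(written["light_depths"], index=False)

        stage = "diet"
        diet_scn = DietScenario(**config.get("diet", {}))
        diet, whales = gen_diet_predator_series(diet_scn)
        period_starts = config["period_starts"]
        dtab = period_diet_table(diet, period_starts)
        krill_sv = (
            periods.query("location_class == 'interior' and taxon == 'krill'")
            .set_index("period")["mean_sv_db"]
        )
        dtab["krill_sv_interior"] = dtab["period"].map(krill_sv)
        starts = pd.to_datetime(pd.Series(period_starts))
        arrival = pd.Timestamp(diet_scn.whale_arrival_date)
        dtab["whale_presence"] = (starts.iloc[dtab["period"] - 1].reset_index(drop=True)
                                  >= arrival).astype(float)
        dtab["fraction_krill"] = dtab["pct_krill"]
        written["period_table"] = out / "period_table.csv"
        dtab.to_csv(written["period_table"], index=False)

        stage = "correlate"
        corr = correlate_preyscape_diet(
            dtab, variables=["whale_presence", "krill_sv_interior"]
        )
        written["correlations"] = out / "correlations.csv"
        corr.to_csv(written["correlations"], index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "outputs": {name: {"path": p.name, "sha256": _digest(p)} for name, p in written.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
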