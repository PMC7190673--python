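import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mizscape.echo import (
    Aggregation,
    DEFAULT_CLASSIFICATION_RULES,
    aggregation_cells_frame,
    aggregation_mean_sv,
    aggregations_to_frame,
    bin_echogram,
    bootstrap_ci,
    classify_aggregation,
    db_to_linear,
    delineate_aggregations,
    EchogramGrid,
    linear_to_db,
    mean_sv_db,
    period_summary,
    weighted_mean_depth,
)
from .conftest import SEED


def make_grid(sv, location="interior", station="S0", time_bin_s=1.0, ping_interval_s=1.0):
    sv = np.asarray(sv, dtype=float)
    return EchogramGrid(
        station_id=station, location_class=location, sv=sv,
        depth_edges=np.arange(sv.shape[0] + 1, dtype=float),
        time_bin_s=time_bin_s, ping_interval_s=ping_interval_s,
    )


class TestDbLinear:
    def test_identity_and_known_values(self):
        assert db_to_linear(0.0) == 1.0
        assert db_to_linear(-90.0) == pytest.approx(1e-9, rel=1e-12)
        # ratio of two krill backscatter levels 15.7 dB apart
        assert db_to_linear(-73.0) / db_to_linear(-88.7) == pytest.approx(10 ** 1.57, rel=1e-9)

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(ValueError):
            linear_to_db(0.0)

    @given(st.floats(min_value=-120.0, max_value=0.0))
    def test_round_trip_exact(self, sv):
        assert abs(linear_to_db(db_to_linear(sv)) - sv) < 1e-12

    def test_mean_of_minus90_minus80(self):
        assert mean_sv_db([-90.0, -80.0]) == pytest.approx(-82.596, abs=5e-3)

    @given(st.lists(st.floats(min_value=-110, max_value=-60), min_size=2, max_size=30))
    def test_linear_mean_dominates_db_mean(self, cells):
        # Jensen: the linear-domain mean is >= the dB arithmetic mean,
        # strictly when cells differ
        lin, arith = mean_sv_db(cells), np.mean(cells)
        assert lin >= arith - 1e-9
        if np.ptp(cells) > 1e-6:
            assert lin > arith


class TestBinEchogram:
    def make_pings(self, rows):
        return pd.DataFrame(rows, columns=["time_s", "depth_m", "sv_db"])

    def test_constant_bin(self):
        pings = self.make_pings([(t, 10.5, -80.0) for t in range(6)])
        grid = bin_echogram(pings, max_depth_m=20, time_bin_s=6.0)
        assert grid.sv[10, 0] == pytest.approx(-80.0, abs=1e-9)

    def test_linear_domain_average(self):
        pings = self.make_pings([(0.0, 5.2, -90.0), (1.0, 5.8, -80.0)])
        grid = bin_echogram(pings, max_depth_m=10, time_bin_s=6.0)
        assert grid.sv[5, 0] == pytest.approx(-82.596, abs=5e-3)

    def test_empty_cells_are_missing(self):
        pings = self.make_pings([(0.0, 5.0, -80.0)])
        grid = bin_echogram(pings, max_depth_m=10, time_bin_s=6.0)
        assert np.isnan(grid.sv[3, 0])  # no samples there, not 0 dB

    def test_unordered_timestamps_rejected(self):
        pings = self.make_pings([(5.0, 5.0, -80.0), (1.0, 5.0, -80.0)])
        with pytest.raises(ValueError):
            bin_echogram(pings)


class TestDelineation:
    def test_all_below_threshold(self):
        grid = make_grid(np.full((20, 30), -110.0))
        assert delineate_aggregations(grid, sv_threshold=-95.0) == []

    def test_single_rectangular_patch(self):
        sv = np.full((20, 30), -110.0)
        sv[5:10, 10:16] = -75.0  # 6 pings wide, 5 m tall (1-s time bins)
        aggs = delineate_aggregations(make_grid(sv), sv_threshold=-95.0)
        assert len(aggs) == 1
        a = aggs[0]
        assert a.ping_width == 6
        assert a.n_cells == 30
        assert set(a.depth_idx) == set(range(5, 10))
        assert set(a.time_idx) == set(range(10, 16))

    def test_four_ping_patch_rejected(self):
        sv = np.full((20, 30), -110.0)
        sv[5:10, 10:14] = -75.0  # exactly 4 pings wide: too narrow
        assert delineate_aggregations(make_grid(sv), sv_threshold=-95.0) == []

    def test_six_second_bins_count_pings(self):
        # one 6-s time bin integrates six 1-s pings: wide enough on its own
        sv = np.full((20, 5), -110.0)
        sv[5:8, 2] = -75.0
        aggs = delineate_aggregations(make_grid(sv, time_bin_s=6.0), sv_threshold=-95.0)
        assert len(aggs) == 1 and aggs[0].ping_width == 6

    def test_invariant_to_ping_order_within_station(self):
        rng = np.random.default_rng(SEED)
        times = np.arange(60.0)
        rows = []
        for t in times:
            rows.append((t, rng.uniform(0, 20), rng.uniform(-100, -70)))
        pings = pd.DataFrame(rows, columns=["time_s", "depth_m", "sv_db"])
        shuffled = pings.sample(frac=1.0, random_state=1).sort_values("time_s")
        g1 = bin_echogram(pings, max_depth_m=20)
        g2 = bin_echogram(shuffled, max_depth_m=20)
        a1 = delineate_aggregations(g1, sv_threshold=-90.0)
        a2 = delineate_aggregations(g2, sv_threshold=-90.0)
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.depth_idx, y.depth_idx)
            np.testing.assert_allclose(x.sv_db, y.sv_db)


def make_agg(depth_mids, sv_db, station="S0", ping_width=6):
    depth_mids = np.asarray(depth_mids, dtype=float)
    sv_db = np.asarray(sv_db, dtype=float)
    return Aggregation(
        station_id=station,
        depth_idx=depth_mids.astype(int),
        time_idx=np.arange(len(sv_db)),
        depth_mids=depth_mids,
        sv_db=sv_db,
        ping_width=ping_width,
    )


class TestClassification:
    def test_shallow_patch_is_krill_deep_is_silverfish(self):
        assert classify_aggregation(make_agg([25, 30], [-75, -75])) == "krill"
        assert classify_aggregation(make_agg([85, 90], [-80, -80])) == "silverfish"

    def test_patch_failing_all_rules_is_unknown(self):
        # far stronger than any rule's Sv range
        assert classify_aggregation(make_agg([30], [-20.0])) == "unknown"

    def test_deterministic(self):
        a = make_agg([40, 45], [-78, -76])
        assert classify_aggregation(a) == classify_aggregation(make_agg([40, 45], [-78, -76]))

    def test_accuracy_on_default_scenario(self, default_survey):
        """Generator taxon labels are ground truth; rule-table classification
        must match on >= 90% of recoverable patches."""
        scn, grids, stations, truth = default_survey
        by_station = {g.station_id: g for g in grids}
        hits = total = 0
        for _, patch in truth.iterrows():
            grid = by_station[patch["station_id"]]
            aggs = delineate_aggregations(grid)
            zc = patch["z0"] + patch["height_bins"] / 2
            tc = patch["t0"] + patch["width_bins"] / 2
            containing = [
                a for a in aggs
                if np.any((np.abs(a.depth_idx - zc) <= 1) & (np.abs(a.time_idx - tc) <= 1))
            ]
            if not containing:
                continue  # patch overwritten by a later overlapping patch
            total += 1
            hits += classify_aggregation(containing[0]) == patch["taxon"]
        assert total > 100
        assert hits / total >= 0.90


class TestSummaries:
    def test_mean_sv_constant_and_mixed(self):
        assert aggregation_mean_sv([-80.0, -80.0]) == pytest.approx(-80.0)
        assert aggregation_mean_sv([-90.0, -80.0]) == pytest.approx(-82.596, abs=5e-3)

    def test_adding_cell_at_mean_preserves_mean(self):
        cells = [-85.0, -79.0, -90.0]
        m = aggregation_mean_sv(cells)
        assert aggregation_mean_sv(cells + [m]) == pytest.approx(m, abs=1e-9)

    def test_weighted_depth_point_mass_and_balance(self):
        assert weighted_mean_depth(make_agg([50.0], [-80.0])) == 50.0
        assert weighted_mean_depth(make_agg([20.0, 40.0], [-80.0, -80.0])) == pytest.approx(30.0)

    def test_weighted_depth_scale_invariant(self):
        a = make_agg([10.0, 30.0, 55.0], [-90.0, -80.0, -85.0])
        b = make_agg([10.0, 30.0, 55.0], [-87.0, -77.0, -82.0])  # +3 dB everywhere
        assert weighted_mean_depth(a) == pytest.approx(weighted_mean_depth(b))

    def test_weighted_depth_within_range(self, small_survey):
        _, grids, _, _ = small_survey
        for g in grids[:8]:
            for a in delineate_aggregations(g):
                assert a.depth_mids.min() <= a.weighted_depth <= a.depth_mids.max()


class TestBootstrap:
    def test_degenerate_samples(self):
        assert bootstrap_ci(np.full(10, 3.2), seed=0) == (3.2, 3.2)
        assert bootstrap_ci([5.0], seed=0) == (5.0, 5.0)

    def test_interval_brackets_mean(self):
        rng = np.random.default_rng(SEED)
        x = rng.normal(size=200)
        lo, hi = bootstrap_ci(x, n_boot=2000, seed=1)
        assert lo <= x.mean() <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(SEED)
        widths = []
        for n in (50, 200, 800):
            x = rng.normal(size=n)
            lo, hi = bootstrap_ci(x, n_boot=2000, seed=2)
            widths.append(hi - lo)
        # ~1/sqrt(n): quadrupling n should roughly halve the width
        assert widths[1] < widths[0] * 0.65
        assert widths[2] < widths[1] * 0.65

    def test_seed_deterministic(self):
        x = np.random.default_rng(0).normal(size=50)
        assert bootstrap_ci(x, seed=7) == bootstrap_ci(x, seed=7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([])


class TestPeriodSummary:
    def periods(self):
        return ["2014-12-14", "2014-12-20", "2014-12-25"]

    def test_none_rows_for_absent_taxon(self):
        agg = aggregations_to_frame([make_agg([30], [-75], station="A")])
        agg.loc[0, "taxon"] = "krill"
        stations = pd.DataFrame(
            {"station_id": ["A"], "location_class": ["interior"],
             "deployment_date": ["2014-12-15"]}
        )
        out = period_summary(agg, stations, self.periods(), n_boot=200, seed=0)
        sf = out[(out["taxon"] == "silverfish") & (out["period"] == 1)
                 & (out["location_class"] == "interior")]
        assert sf["n_aggregations"].iloc[0] == 0
        assert np.isnan(sf["mean_sv_db"].iloc[0])

    def test_single_aggregation_degenerate_ci(self):
        a = make_agg([30, 31], [-75.0, -75.0], station="A")
        a.taxon = "krill"
        agg = aggregations_to_frame([a])
        stations = pd.DataFrame(
            {"station_id": ["A"], "location_class": ["edge"],
             "deployment_date": ["2014-12-16"]}
        )
        out = period_summary(agg, stations, self.periods(), n_boot=200, seed=0)
        row = out[(out["taxon"] == "krill") & (out["period"] == 1)
                  & (out["location_class"] == "edge")].iloc[0]
        assert row["mean_sv_db"] == pytest.approx(-75.0)
        assert row["sv_lo"] == pytest.approx(row["sv_hi"])
        assert row["depth_lo"] <= row["mean_depth_m"] <= row["depth_hi"]

    def test_out_of_range_dates_warn(self):
        a = make_agg([30], [-75], station="A")
        a.taxon = "krill"
        agg = aggregations_to_frame([a])
        stations = pd.DataFrame(
            {"station_id": ["A"], "location_class": ["edge"],
             "deployment_date": ["2014-11-01"]}
        )
        with pytest.warns(UserWarning, match="before the first period"):
            period_summary(agg, stations, self.periods(), n_boot=100, seed=0)

    def test_recovers_generator_patch_sv(self, small_survey):
        scn, grids, stations, _ = small_survey
        aggs = []
        for g in grids:
            for a in delineate_aggregations(g):
                a.taxon = classify_aggregation(a)
                aggs.append(a)
        from mizscape.datasets import ACOUSTIC_PERIOD_STARTS

        out = period_summary(
            aggregations_to_frame(aggs), stations,
            ACOUSTIC_PERIOD_STARTS, n_boot=500, seed=1,
        )
        rows = out[(out["location_class"] == "interior") & (out["taxon"] == "krill")
                   & (out["n_aggregations"] > 2)]
        assert len(rows) > 0
        # patch cells are drawn at patch_sv_mean; linear-domain means sit a
        # little above the dB mean but within a couple of dB
        for _, row in rows.iterrows():
            assert row["mean_sv_db"] == pytest.approx(scn.patch_sv_mean, abs=3.0)
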