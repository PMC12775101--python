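"""Connection counting, the analysis table, and the paired-strength table."""

import numpy as np
import pandas as pd
import pytest

from oncnet.errors import InvalidInputError
from oncnet.exposure_outcome import (
    build_analysis_table,
    count_connections,
    ever_connected,
    volume_category,
)
from oncnet.network_builder import AnnualNetwork


def mover_frame(rows):
    """rows: (physician, year, specialty, linchpin_flag[, excluded])"""
    return pd.DataFrame(
        [
            {
                "physician_id": p,
                "departure_year": y,
                "specialty": s,
                "linchpin_flag_at_departure": lf,
                "excluded": r[4] if len(r) > 4 else False,
            }
            for r in rows
            for p, y, s, lf in [r[:4]]
        ]
    )


class TestCountConnections:
    def nets(self, prev_edges, cur_edges):
        return {
            2017: AnnualNetwork.from_edges(2017, prev_edges),
            2018: AnnualNetwork.from_edges(2018, cur_edges),
        }

    def test_pooled_one_plus_one_counts_at_k2(self):
        nets = self.nets([("R", "M", 1)], [("R", "M", 1)])
        movers = mover_frame([("M", 2018, "surgery", False)])
        smap = {"R": "medical oncology", "M": "surgery"}
        assert count_connections("R", 2018, movers, nets, smap, k=2) == (1, 0, 0)

    def test_single_shared_patient_not_counted(self):
        nets = self.nets([], [("R", "M", 1)])
        movers = mover_frame([("M", 2018, "surgery", False)])
        smap = {"R": "medical oncology", "M": "surgery"}
        assert count_connections("R", 2018, movers, nets, smap, k=2) == (0, 0, 0)

    def test_secondary_exposure_bookkeeping(self):
        nets = self.nets(
            [("R", "M1", 1), ("R", "M2", 1), ("R", "M3", 1)],
            [("R", "M1", 1), ("R", "M2", 1), ("R", "M3", 1)],
        )
        movers = mover_frame(
            [
                ("M1", 2018, "medical oncology", False),
                ("M2", 2018, "surgery", True),
                ("M3", 2018, "radiation oncology", False),
            ]
        )
        smap = {"R": "medical oncology", "M1": "medical oncology",
                "M2": "surgery", "M3": "radiation oncology"}
        assert count_connections("R", 2018, movers, nets, smap, k=2) == (3, 1, 1)

    def test_per_year_variant_stricter(self):
        nets = self.nets([("R", "M", 2)], [("R", "M", 1)])
        movers = mover_frame([("M", 2018, "surgery", False)])
        smap = {"R": "medical oncology", "M": "surgery"}
        assert count_connections("R", 2018, movers, nets, smap, k=2,
                                 pooled=True)[0] == 1
        assert count_connections("R", 2018, movers, nets, smap, k=2,
                                 pooled=False)[0] == 0

    def test_self_mover_rejected(self):
        nets = self.nets([], [])
        movers = mover_frame([("R", 2018, "surgery", False)])
        with pytest.raises(InvalidInputError):
            count_connections("R", 2018, movers, nets, {"R": "surgery"}, k=2)

    def test_monotone_in_threshold(self, small_study, small_result):
        smap = dict(
            zip(small_result.profiles["physician_id"],
                small_result.profiles["specialty"])
        )
        movers = small_result.movers
        sample = sorted(small_result.retained)[:40]
        for r in sample:
            for year in (2017, 2018, 2019):
                if (movers["physician_id"] == r).any():
                    continue
                counts = [
                    count_connections(
                        r, year, movers, small_result.networks, smap, k=k
                    )[0]
                    for k in (2, 3, 4, 5)
                ]
                assert counts == sorted(counts, reverse=True)


class TestVolumeCategory:
    @pytest.mark.parametrize(
        "v,cat", [(0, "low"), (4, "low"), (5, "medium"), (9, "medium"),
                  (10, "high"), (60, "high")]
    )
    def test_bins(self, v, cat):
        assert volume_category(v) == cat


class TestAnalysisTable:
    def test_row_count_and_mover_truncation(self, small_study, small_result):
        a = small_result.analysis
        movers = small_result.movers
        dep = dict(
            zip(movers.loc[~movers["excluded"], "physician_id"],
                movers.loc[~movers["excluded"], "departure_year"])
        )
        expected = 0
        for r in small_result.retained:
            last = dep.get(r, 2020)
            expected += len([y for y in (2017, 2018, 2019) if y < last])
        assert len(a) == expected
        for rec in a.itertuples(index=False):
            assert rec.year < dep.get(rec.physician_id, 2020)

    def test_deltas_are_year_over_year(self, small_result):
        a = small_result.analysis
        m = {y: f.set_index("physician_id")
             for y, f in small_result.metrics_by_year.items()}
        sample = a.sample(25, random_state=0)
        for rec in sample.itertuples(index=False):
            expect = (
                m[rec.year].loc[rec.physician_id, "strength"]
                - m[rec.year - 1].loc[rec.physician_id, "strength"]
            )
            assert rec.delta_strength == pytest.approx(expect)

    def test_undefined_metric_propagates_to_missing_delta(self, small_result):
        a = small_result.analysis
        m = {y: f.set_index("physician_id")
             for y, f in small_result.metrics_by_year.items()}
        for rec in a.itertuples(index=False):
            prev_t = m[rec.year - 1].loc[rec.physician_id, "transitivity"]
            cur_t = m[rec.year].loc[rec.physician_id, "transitivity"]
            if np.isnan(prev_t) or np.isnan(cur_t):
                assert np.isnan(rec.delta_transitivity)

    def test_exposure_counts_match_generator_truth(self, small_study, small_result):
        truth = small_study.truth["exposure"].set_index(
            ["physician_id", "departure_year"]
        )
        a = small_result.analysis.set_index(["physician_id", "year"])
        for key, row in truth.iterrows():
            if key in a.index:
                assert a.loc[key, "exposure_any"] == row["exposure_any"]
                assert (
                    a.loc[key, "exposure_same_specialty"]
                    == row["exposure_same_specialty"]
                )
        measured_exposed = a[a["exposure_any"] > 0]
        for key, row in measured_exposed.iterrows():
            assert key in truth.index, f"unexplained exposure at {key}"

    def test_secondary_exposures_bounded_by_any(self, small_result):
        a = small_result.analysis
        assert (a["exposure_same_specialty"] <= a["exposure_any"]).all()
        assert (a["exposure_linchpin"] <= a["exposure_any"]).all()


class TestPairedTable:
    def test_rows_only_for_late_departure_exposures(self, small_study):
        from oncnet.pipeline import run_measurement

        res = run_measurement(
            small_study.claims,
            small_study.patients,
            small_study.physicians,
            small_study.crosswalk,
            small_study.config.years,
            fit_models=True,
        )
        assert res.paired is not None
        if len(res.paired):
            assert (res.paired["post_year"] >= 2018).all()
            assert (res.paired["pre_year"] == res.paired["post_year"] - 1).all()
            exposed = res.analysis[res.analysis["exposure_any"] > 0]
            keys = set(zip(exposed["physician_id"], exposed["year"]))
            for rec in res.paired.itertuples(index=False):
                assert (rec.physician_id, rec.post_year) in keys

    def test_ever_connected_indicator(self, small_result):
        conn = ever_connected(small_result.analysis)
        a = small_result.analysis
        manual = a.groupby("physician_id")["exposure_any"].max() > 0
        pd.testing.assert_series_equal(conn, manual)
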