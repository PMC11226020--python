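"""Survey pairing, richness tabulation, accumulation curves, top-N review."""

import numpy as np
import pandas as pd
import pytest

from pamval import richness as rich
from pamval.errors import ValidationError
from pamval.io import filter_by_confidence


class TestPairing:
    def _one(self, rec_offset_min, duration_s=3600.0):
        visits = pd.DataFrame(
            [{"site_id": "s1", "visit_start": pd.Timestamp("2022-06-01 07:00"),
              "duration_min": 10.0}]
        )
        recordings = pd.DataFrame(
            [{"recording_id": "r1", "site_id": "s1",
              "start": pd.Timestamp("2022-06-01 07:00")
              + pd.Timedelta(minutes=rec_offset_min),
              "duration_s": duration_s}]
        )
        return rich.pair_surveys_with_recordings(visits, recordings)

    def test_overlapping_recording_paired(self):
        pairs, excl = self._one(rec_offset_min=-30)
        assert len(pairs) == 1 and len(excl) == 0

    def test_recording_ending_two_hours_before_excluded(self):
        pairs, excl = self._one(rec_offset_min=-180)  # 07:00-180min..-120min
        assert len(pairs) == 0 and len(excl) == 1

    def test_window_boundary_inclusive(self):
        # recording ends exactly window ahead of the visit start
        pairs, _ = self._one(rec_offset_min=-120)  # ends 06:00 = start - 60 min
        assert len(pairs) == 1

    def test_constructed_30_visit_schedule(self, pairing_fixture):
        visits, recordings = pairing_fixture
        pairs, exclusions = rich.pair_surveys_with_recordings(visits, recordings)
        assert pairs.groupby(["site_id", "visit_start"]).ngroups == 24
        assert len(exclusions) == 6


class TestShortDurationRichness:
    def _pairs_and_detections(self, plain_detections, visits_sched):
        visits, schedule = visits_sched
        pairs, _ = rich.pair_surveys_with_recordings(visits, schedule)
        return pairs

    def test_no_detections_gives_zero(self, small_dataset, plain_detections):
        visits = small_dataset["visits"]
        pairs, _ = rich.pair_surveys_with_recordings(visits, small_dataset["schedule"])
        out = rich.short_duration_richness(pairs, plain_detections.head(0), 0.1)
        assert (out["richness"] == 0).all()
        assert len(out) == pairs.groupby(["site_id", "visit_start"]).ngroups

    def test_duplicate_species_counts_once(self):
        pairs = pd.DataFrame(
            [{"site_id": "s1", "visit_start": pd.Timestamp("2022-06-01 07:00"),
              "recording_id": "r1"}]
        )
        det = pd.DataFrame(
            {"recording_id": ["r1"] * 1000, "scientific_name": ["A a"] * 1000,
             "confidence": np.linspace(0.1, 1.0, 1000)}
        )
        out = rich.short_duration_richness(pairs, det, 0.1)
        assert out["richness"].tolist() == [1]

    def test_matches_brute_force_union(self, small_dataset, plain_detections):
        pairs, _ = rich.pair_surveys_with_recordings(
            small_dataset["visits"], small_dataset["schedule"]
        )
        out = rich.short_duration_richness(pairs, plain_detections, 0.5)
        filt = filter_by_confidence(plain_detections, 0.5)
        for row in out.itertuples(index=False):
            recs = pairs.loc[
                (pairs["site_id"] == row.site_id)
                & (pairs["visit_start"] == row.visit_start),
                "recording_id",
            ]
            expected = set(
                filt.loc[filt["recording_id"].isin(recs), "scientific_name"]
            )
            assert row.species_set == expected
            assert row.richness == len(expected)


class TestLongDurationRichness:
    def test_period_with_no_recordings_gives_zero(self, plain_detections):
        out = rich.long_duration_richness(
            plain_detections, ("1990-01-01", "1990-02-01"), 0.1,
            sites=["site01"],
        )
        assert out["richness"].tolist() == [0]

    def test_empty_period_raises(self, plain_detections):
        with pytest.raises(ValidationError):
            rich.long_duration_richness(
                plain_detections, ("2022-06-02", "2022-06-01"), 0.1
            )

    def test_monotone_in_threshold_per_site(self, plain_detections):
        period = ("2022-05-19", "2022-07-19")
        by_thr = {
            t: rich.long_duration_richness(plain_detections, period, t)
            .set_index("site_id")["richness"]
            for t in (0.1, 0.9)
        }
        common = by_thr[0.1].index
        assert (by_thr[0.9].reindex(common, fill_value=0) <= by_thr[0.1]).all()

    def test_matches_brute_force(self, plain_detections):
        period = ("2022-05-19", "2022-07-19")
        out = rich.long_duration_richness(plain_detections, period, 0.25)
        filt = filter_by_confidence(plain_detections, 0.25)
        for row in out.itertuples(index=False):
            expected = set(
                filt.loc[filt["site_id"] == row.site_id, "scientific_name"]
            )
            assert row.species_set == expected

    def test_long_bounds_short_from_above(self, small_dataset, plain_detections):
        pairs, _ = rich.pair_surveys_with_recordings(
            small_dataset["visits"], small_dataset["schedule"]
        )
        short = rich.short_duration_richness(pairs, plain_detections, 0.25)
        long = rich.long_duration_richness(
            plain_detections, ("2022-05-19", "2022-07-19"), 0.25
        ).set_index("site_id")["richness"]
        per_site_max = short.groupby("site_id")["richness"].max()
        assert (long.reindex(per_site_max.index, fill_value=0) >= per_site_max).all()


class TestPointCountRichness:
    def test_same_species_every_visit_is_one(self):
        obs = pd.DataFrame(
            {
                "site_id": ["s1"] * 3,
                "visit_start": pd.to_datetime(
                    ["2022-06-01 07:00", "2022-06-10 07:00", "2022-06-20 07:00"]
                ),
                "species": ["Sturnella neglecta"] * 3,
            }
        )
        out = rich.point_count_richness(obs, scope="all", per="site")
        assert out["richness"].tolist() == [1]

    def test_disjoint_visits_sum(self):
        obs = pd.DataFrame(
            {
                "site_id": ["s1"] * 3,
                "visit_start": pd.to_datetime(
                    ["2022-06-01 07:00", "2022-06-10 07:00", "2022-06-20 07:00"]
                ),
                "species": ["A a", "B b", "C c"],
            }
        )
        per_visit = rich.point_count_richness(obs, scope="all", per="visit")
        per_site = rich.point_count_richness(obs, scope="all", per="site")
        assert per_site["richness"].sum() == per_visit["richness"].sum() == 3

    def test_matches_brute_force_union(self, small_dataset):
        obs = small_dataset["observations"]
        out = rich.point_count_richness(obs, scope="all", per="site")
        for row in out.itertuples(index=False):
            assert row.species_set == set(
                obs.loc[obs["site_id"] == row.site_id, "species"]
            )


class TestAccumulationCurve:
    def test_single_species_day_one_flat(self):
        ev = pd.DataFrame(
            {"species": ["A a"], "time": [pd.Timestamp("2022-05-19 06:00")]}
        )
        curve = rich.accumulation_curve(ev, ("2022-05-19", "2022-05-28"))
        assert (curve["cumulative_richness"] == 1).all()
        assert len(curve) == 10

    def test_hand_computed_step_curve(self):
        # 4 species over 10 days: first observations on days 1, 1, 4, 9
        ev = pd.DataFrame(
            {
                "species": ["A", "B", "A", "C", "D", "C"],
                "time": pd.to_datetime(
                    [
                        "2022-05-19 05:00", "2022-05-19 21:00", "2022-05-21 05:00",
                        "2022-05-22 06:00", "2022-05-27 20:00", "2022-05-28 05:00",
                    ]
                ),
            }
        )
        curve = rich.accumulation_curve(ev, ("2022-05-19", "2022-05-28"))
        assert curve["cumulative_richness"].tolist() == [2, 2, 2, 3, 3, 3, 3, 3, 4, 4]

    def test_non_decreasing_and_terminal_equals_pool_richness(self, plain_detections):
        period = ("2022-05-19", "2022-07-19")
        filt = filter_by_confidence(plain_detections, 0.25)
        curve = rich.accumulation_curve(
            filt, period, species_col="scientific_name", time_col="start_time"
        )
        assert (np.diff(curve["cumulative_richness"]) >= 0).all()
        whole = rich.long_duration_richness(plain_detections, period, 0.25)
        union = set().union(*whole["species_set"]) if len(whole) else set()
        assert curve["cumulative_richness"].iloc[-1] == len(union)

    def test_events_outside_period_excluded(self):
        ev = pd.DataFrame(
            {"species": ["A", "B"],
             "time": pd.to_datetime(["2022-05-01 06:00", "2022-05-20 06:00"])}
        )
        curve = rich.accumulation_curve(ev, ("2022-05-19", "2022-05-21"))
        assert curve["cumulative_richness"].iloc[-1] == 1


class TestTopConfidenceReview:
    def test_small_pool_lists_all(self):
        det = pd.DataFrame(
            {
                "scientific_name": ["A a"] * 3,
                "confidence": [0.5, 0.9, 0.7],
                "start_time": pd.to_datetime(["2022-06-01"] * 3),
                "recording_id": ["r1", "r2", "r3"],
            }
        )
        out = rich.top_confidence_review(det, n=10)
        assert len(out) == 3
        assert out["confidence"].tolist() == [0.9, 0.7, 0.5]

    def test_tie_break_deterministic(self):
        det = pd.DataFrame(
            {
                "scientific_name": ["A a"] * 3,
                "confidence": [0.9, 0.9, 0.9],
                "start_time": pd.to_datetime(
                    ["2022-06-02", "2022-06-01", "2022-06-01"]
                ),
                "recording_id": ["r1", "r9", "r2"],
            }
        )
        out = rich.top_confidence_review(det, n=2)
        assert out["recording_id"].tolist() == ["r2", "r9"]

    def test_all_false_species_excluded(self):
        det = pd.DataFrame(
            {
                "scientific_name": ["A a"] * 2 + ["B b"],
                "confidence": [0.9, 0.8, 0.7],
                "start_time": pd.to_datetime(["2022-06-01"] * 3),
                "recording_id": ["r1", "r2", "r3"],
            }
        )
        reviews = rich.top_confidence_review(det, n=10)
        reviews["confirmed"] = [False, False, True]
        assert rich.confirmed_total_richness(reviews) == 1

    def test_confirmed_richness_matches_brute_force(self, small_dataset):
        det = small_dataset["detections"]
        reviews = rich.top_confidence_review(det, n=10)
        reviews["confirmed"] = reviews["truth"] == "true_positive"
        got = rich.confirmed_total_richness(reviews)
        expected = 0
        for sp, grp in det.groupby("scientific_name"):
            top = grp.sort_values(
                ["confidence", "start_time", "recording_id"],
                ascending=[False, True, True], kind="mergesort",
            ).head(10)
            expected += int((top["truth"] == "true_positive").any())
        assert got == expected
        assert got <= det["scientific_name"].nunique()
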