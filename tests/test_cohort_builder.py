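import numpy as np
import pandas as pd
import pytest

from markspat.capture_data import DEFAULT_SEASONS
from markspat.cohort_builder import (
    abundance_table,
    assign_seasons,
    classify_cohorts,
    maturity_class,
    seasonal_centroids,
    subset_min_captures,
)
from conftest import make_captures


def caps_with_seasons(rows):
    return assign_seasons(make_captures(rows), DEFAULT_SEASONS)


class TestSeasons:
    @pytest.mark.parametrize(
        "date,label",
        [
            ("1982-03-15", "dry-1982"),
            ("1982-10-02", "wet2-1982"),
            ("1983-01-31", "wet2-1982"),
            ("1983-08-15", "wet1-1983"),
        ],
    )
    def test_date_maps_to_pooling_window(self, date, label):
        out = caps_with_seasons([("a", "p1", date, 0, 0, 20.0, "F")])
        assert out.loc[0, "season"] == label

    def test_date_outside_coverage_rejected(self):
        with pytest.raises(ValueError, match="1984-01-01"):
            caps_with_seasons([("a", "p1", "1984-01-01", 0, 0, 20.0, "F")])


class TestMaturity:
    @pytest.mark.parametrize(
        "svl,expected", [(18.9, "juvenile"), (19.0, "adult"), (30.0, "adult")]
    )
    def test_nineteen_mm_threshold(self, svl, expected):
        assert maturity_class(svl) == expected

    def test_nonpositive_svl_rejected(self):
        with pytest.raises(ValueError):
            maturity_class(0.0)


class TestClassification:
    def test_first_season_adults_are_residents(self):
        caps = caps_with_seasons([("f1", "p1", "1982-03-01", 0, 0, 22.0, "F")])
        coh = classify_cohorts(caps)
        assert coh.iloc[0]["cohort"] == "RF"

    def test_new_adult_is_migrant_then_resident_on_recapture(self):
        # male first captured in season 3, absent season 2 -> MM; same plot
        # next season -> RM
        caps = caps_with_seasons(
            [
                ("m1", "p1", "1982-11-01", 0, 0, 21.0, "M"),
                ("m1", "p1", "1983-03-01", 0, 0, 22.0, "M"),
            ]
        )
        coh = classify_cohorts(caps).set_index("season")
        assert coh.loc["wet2-1982", "cohort"] == "MM"
        assert coh.loc["dry-1983", "cohort"] == "RM"

    def test_juvenile_maturing_in_same_plot_becomes_resident(self):
        caps = caps_with_seasons(
            [
                ("j1", "p1", "1982-07-01", 2, 2, 17.0, "U"),
                ("j1", "p1", "1982-11-01", 2, 3, 20.0, "F"),
            ]
        )
        coh = classify_cohorts(caps).set_index("season")
        assert coh.loc["wet1-1982", "cohort"] == "J"
        assert coh.loc["wet2-1982", "cohort"] == "RF"

    def test_adult_absent_a_full_season_reverts_to_migrant(self):
        caps = caps_with_seasons(
            [
                ("f1", "p1", "1982-03-01", 0, 0, 22.0, "F"),
                ("f1", "p1", "1983-03-01", 0, 0, 23.0, "F"),
            ]
        )
        coh = classify_cohorts(caps).set_index("season")
        assert coh.loc["dry-1982", "cohort"] == "RF"
        assert coh.loc["dry-1983", "cohort"] == "MF"

    def test_adult_with_unknown_sex_excluded(self):
        caps = caps_with_seasons([("u1", "p1", "1982-03-01", 0, 0, 22.0, "U")])
        coh = classify_cohorts(caps)
        assert len(coh) == 0

    def test_one_cohort_per_plot_season(self, tiny_captures):
        coh = classify_cohorts(assign_seasons(tiny_captures))
        assert not coh.duplicated(["individual_id", "plot_id", "season"]).any()


class TestSubset:
    def test_threshold_filters_study_wide_counts(self, tiny_captures):
        filtered, summary = subset_min_captures(tiny_captures, k=3)
        assert set(filtered["individual_id"]) == {"a1"}  # b1 has 2 captures
        assert summary["n_individuals_full"] == 2
        assert summary["n_captures_full"] == 5
        assert summary["n_individuals_subset"] == 1
        assert summary["n_captures_subset"] == 3

    def test_k_equal_one_is_identity(self, tiny_captures):
        filtered, _ = subset_min_captures(tiny_captures, k=1)
        assert len(filtered) == len(tiny_captures)

    def test_subsetting_monotone_in_k(self, tiny_captures):
        sizes = [len(subset_min_captures(tiny_captures, k)[0]) for k in (1, 2, 3, 4)]
        assert sizes == sorted(sizes, reverse=True)


class TestCentroids:
    def test_single_capture_centroid_is_cell_center(self):
        caps = caps_with_seasons([("a", "p1", "1982-03-01", 0, 0, 20.0, "F")])
        cent = seasonal_centroids(caps)
        assert (cent.iloc[0]["x"], cent.iloc[0]["y"]) == pytest.approx((0.75, 0.75))

    def test_centroid_is_mean_of_cell_centers(self):
        caps = caps_with_seasons(
            [
                ("a", "p1", "1982-03-01", 0, 0, 20.0, "F"),
                ("a", "p1", "1982-03-05", 0, 1, 20.0, "F"),
            ]
        )
        cent = seasonal_centroids(caps)
        assert (cent.iloc[0]["x"], cent.iloc[0]["y"]) == pytest.approx((1.5, 0.75))

    def test_capture_order_invariance(self, rng):
        rows = [
            ("a", "p1", f"1982-03-{d:02d}", int(r), int(c), 20.0, "F")
            for d, r, c in zip(
                range(1, 11), rng.integers(0, 6, 10), rng.integers(0, 8, 10)
            )
        ]
        base = seasonal_centroids(caps_with_seasons(rows))
        perm = seasonal_centroids(caps_with_seasons([rows[i] for i in rng.permutation(10)]))
        pd.testing.assert_frame_equal(base, perm)


class TestAbundance:
    def test_groups_partition_classified_individuals(self):
        caps = caps_with_seasons(
            [
                ("f1", "p1", "1982-03-01", 0, 0, 22.0, "F"),
                ("f2", "p1", "1982-03-01", 1, 1, 22.0, "F"),
                ("f3", "p1", "1982-07-01", 1, 2, 22.0, "F"),  # MF in wet1
                ("m1", "p1", "1982-03-01", 2, 2, 22.0, "M"),
                ("j1", "p1", "1982-03-01", 3, 3, 15.0, "U"),
            ]
        )
        coh = classify_cohorts(caps)
        tab = abundance_table(coh)
        per_unit = tab.groupby(["plot_id", "season"])["count"].sum()
        expected = coh.groupby(["plot_id", "season"])["individual_id"].nunique()
        for key, total in expected.items():
            assert per_unit[key] == total

    def test_females_pool_migrant_and_resident(self):
        caps = caps_with_seasons(
            [
                ("f1", "p1", "1982-03-01", 0, 0, 22.0, "F"),
                ("f1", "p1", "1982-07-01", 0, 0, 22.0, "F"),  # RF in wet1
                ("f2", "p1", "1982-07-01", 1, 1, 22.0, "F"),  # MF in wet1
            ]
        )
        tab = abundance_table(classify_cohorts(caps)).set_index(["season", "group"])
        assert tab.loc[("wet1-1982", "female"), "count"].item() == 2

    def test_empty_season_reports_zero_counts(self):
        caps = caps_with_seasons([("f1", "p1", "1982-03-01", 0, 0, 22.0, "F")])
        tab = abundance_table(
            classify_cohorts(caps), seasons=[w.label for w in DEFAULT_SEASONS]
        )
        wet = tab[tab["season"] == "wet1-1983"]
        assert (wet["count"] == 0).all()
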