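"""Buffer sums, imputation, window averaging, and median dichotomisation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambientgxe.config import ExposureConfig
from ambientgxe.errors import (
    DataError,
    InvalidWindowError,
    ThresholdUndefinedError,
    UndefinedExposureError,
)
from ambientgxe.exposure import (
    annual_buffer_sum,
    classify_class_exposure,
    compute_exposure,
    dichotomize_pesticide,
    exposure_window,
    impute_missing_years,
    window_average,
)
from conftest import make_applications

CFG = ExposureConfig()


def brute_force_buffer_sum(applications, point, year, pesticide_id, radius):
    """Independent oracle: plain double loop over the record table."""
    total = 0.0
    for row in applications.itertuples():
        if row.pesticide_id != pesticide_id or row.year != year:
            continue
        d = math.hypot(row.x_m - point[0], row.y_m - point[1])
        if d <= radius:
            total += row.pounds / row.acres
    return total


class TestAnnualBufferSum:
    def test_no_matching_applications(self):
        apps = make_applications(
            [("permethrin", "pyrethroid", 1990, 0.0, 0.0, 10.0, 5.0)]
        )
        assert annual_buffer_sum(apps, (0, 0), 1991, "permethrin", CFG) == 0.0
        assert annual_buffer_sum(apps, (0, 0), 1990, "maneb", CFG) == 0.0

    def test_beyond_radius_excluded_at_boundary_included(self):
        apps = make_applications(
            [
                ("permethrin", "pyrethroid", 1990, 600.0, 0.0, 10.0, 5.0),
                ("permethrin", "pyrethroid", 1990, 500.0, 0.0, 10.0, 5.0),
            ]
        )
        # 600 m out of a 500-m buffer; exactly 500 m is inside (closed disc)
        assert annual_buffer_sum(apps, (0, 0), 1990, "permethrin", CFG) == 2.0

    def test_three_record_example(self):
        apps = make_applications(
            [
                ("permethrin", "pyrethroid", 1990, 100.0, 0.0, 50.0, 25.0),
                ("permethrin", "pyrethroid", 1990, 600.0, 0.0, 50.0, 25.0),
                ("permethrin", "pyrethroid", 1991, 100.0, 0.0, 50.0, 25.0),
            ]
        )
        assert annual_buffer_sum(apps, (0, 0), 1990, "permethrin", CFG) == 2.0

    def test_equals_brute_force_on_large_random_instance(self, rng):
        n = 10_000
        apps = pd.DataFrame(
            {
                "pesticide_id": rng.choice(["permethrin", "maneb", "paraquat"], n),
                "chemical_class": "n/a",
                "year": rng.integers(1974, 1996, n),
                "x_m": rng.uniform(0, 5000, n),
                "y_m": rng.uniform(0, 5000, n),
                "pounds": rng.uniform(0.1, 200, n),
                "acres": rng.uniform(0.5, 80, n),
            }
        )
        for _ in range(25):
            point = tuple(rng.uniform(0, 5000, 2))
            year = int(rng.integers(1974, 1996))
            pest = str(rng.choice(["permethrin", "maneb", "paraquat"]))
            expected = brute_force_buffer_sum(apps, point, year, pest, CFG.radius_m)
            assert annual_buffer_sum(apps, point, year, pest, CFG) == pytest.approx(
                expected, rel=1e-12, abs=0.0
            )


class TestImputation:
    def test_complete_series_unchanged(self):
        vals = {1974: 1.0, 1975: 2.0}
        complete, imputed = impute_missing_years(vals, [1974, 1975])
        assert complete == vals and imputed == set()

    def test_missing_year_gets_recorded_mean(self):
        complete, imputed = impute_missing_years(
            {1974: 2.0, 1975: 4.0}, [1974, 1975, 1976]
        )
        assert complete[1976] == 3.0
        assert imputed == {1976}

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedExposureError):
            impute_missing_years({}, [1974, 1975])

    @given(
        st.dictionaries(
            st.integers(1974, 1990),
            st.floats(0, 1e4, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_imputation_preserves_recorded_mean(self, recorded):
        window = range(1974, 1991)
        complete, _ = impute_missing_years(recorded, window)
        in_window = [v for y, v in recorded.items() if y in window]
        assert np.mean(list(complete.values())) == pytest.approx(
            np.mean(in_window), rel=1e-9
        )


class TestWindowAverage:
    def test_constant_series(self):
        window = exposure_window(2000, CFG)
        vals = {y: 3.0 for y in window}
        assert window_average(vals, 2000, CFG) == pytest.approx(3.0)

    def test_single_spike_divided_by_window_length(self):
        # index 2001, lag 10 -> window 1974..1991, 18 years
        window = exposure_window(2001, CFG)
        assert list(window) == list(range(1974, 1992))
        vals = {y: 0.0 for y in window}
        vals[1980] = 18.0
        assert window_average(vals, 2001, CFG) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidWindowError):
            exposure_window(1983, CFG)
        with pytest.raises(InvalidWindowError):
            window_average({}, 1983, CFG)

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=15, max_size=15),
        st.floats(-5, 5, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_translation_equivariance(self, values, shift):
        vals = dict(zip(range(1974, 1989), values))
        base = window_average(vals, 1998, CFG)
        shifted = {y: v + shift for y, v in vals.items()}
        assert window_average(shifted, 1998, CFG) == pytest.approx(
            base + shift, abs=1e-9
        )


class TestDichotomisation:
    def test_even_sample_midpoint_median(self):
        vals = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 3.0, 2.0, 0.0],
            index=list("abcdefg"),
        )
        is_control = pd.Series(
            [True, True, True, True, False, False, False], index=vals.index
        )
        high, thr = dichotomize_pesticide(vals, is_control)
        assert thr == 2.5
        assert bool(high["e"]) is True   # value 3 >= 2.5
        assert bool(high["f"]) is False  # value 2 < 2.5
        assert bool(high["g"]) is False  # zero exposure is never high

    def test_single_exposed_control_inclusive_rule(self):
        vals = pd.Series([5.0, 5.0], index=["ctrl", "subj"])
        is_control = pd.Series([True, False], index=vals.index)
        high, thr = dichotomize_pesticide(vals, is_control)
        assert thr == 5.0
        assert bool(high["subj"]) is True  # "at or above"

    def test_no_exposed_control_is_undefined(self):
        vals = pd.Series([0.0, 3.0], index=["ctrl", "case"])
        is_control = pd.Series([True, False], index=vals.index)
        with pytest.raises(ThresholdUndefinedError):
            dichotomize_pesticide(vals, is_control)

    @given(
        st.lists(
            st.floats(0.01, 1e3, allow_nan=False), min_size=1, max_size=40
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_at_least_half_of_exposed_controls_high(self, control_vals):
        """The inclusive median rule labels >= 50% of exposed controls high."""
        vals = pd.Series(control_vals)
        is_control = pd.Series(True, index=vals.index)
        high, _ = dichotomize_pesticide(vals, is_control)
        assert high.mean() >= 0.5


class TestClassCategories:
    def test_all_zero_counts(self):
        flags = pd.DataFrame(
            False, index=["a", "b"], columns=["maneb", "ziram"]
        )
        is_control = pd.Series([True, False], index=flags.index)
        out = classify_class_exposure(flags, "dithiocarbamate", is_control)
        assert (out["category"] == "low_or_none").all()
        assert (~out["exposed"]).all()

    def test_count_median_rule(self):
        # exposed-control counts {1,1,2,3} -> median 1.5 -> high iff >= 2
        pests = [f"p{i}" for i in range(4)]
        rows = {
            "c1": [True, False, False, False],
            "c2": [True, False, False, False],
            "c3": [True, True, False, False],
            "c4": [True, True, True, False],
            "s_one": [True, False, False, False],
            "s_two": [True, True, False, False],
        }
        flags = pd.DataFrame.from_dict(rows, orient="index", columns=pests)
        is_control = pd.Series(
            [True, True, True, True, False, False], index=flags.index
        )
        out = classify_class_exposure(flags, "organophosphate", is_control)
        assert not out.loc["s_one", "exposed"]
        assert out.loc["s_two", "exposed"]

    def test_single_pyrethroid_counts_as_any(self):
        flags = pd.DataFrame(
            {"permethrin": [True, False]}, index=["s1", "s2"]
        )
        is_control = pd.Series([False, True], index=flags.index)
        out = classify_class_exposure(flags, "pyrethroid", is_control)
        assert out.loc["s1", "category"] == "any"
        assert out.loc["s2", "category"] == "none"


class TestVectorisedEngine:
    def test_matches_record_level_path(self, small_sim, exposure_cfg):
        """The vectorised engine must reproduce the literal buffer-sum ->
        impute -> window-average -> dichotomise sequence."""
        from ambientgxe.synthetic import generate_applications, generate_cohort

        apps = generate_applications(small_sim)
        cohort = generate_cohort(small_sim, apps, exposure_cfg)
        result = compute_exposure(apps, cohort.addresses, cohort.subjects, exposure_cfg)
        profiles = result.profiles
        subjects = cohort.subjects.set_index("subject_id")
        sample = profiles.sample(n=min(40, len(profiles)), random_state=0)
        for row in sample.itertuples():
            addr = cohort.addresses
            addr = addr[
                (addr["subject_id"] == row.subject_id)
                & (addr["setting"] == row.setting)
            ]
            index_year = int(subjects.loc[row.subject_id, "index_year"])
            window = exposure_window(index_year, exposure_cfg)
            yearly = {}
            for arow in addr.itertuples():
                if arow.year in window and np.isfinite(arow.x_m):
                    yearly[arow.year] = annual_buffer_sum(
                        apps,
                        (arow.x_m, arow.y_m),
                        arow.year,
                        row.pesticide_id,
                        exposure_cfg,
                    )
            complete, _ = impute_missing_years(yearly, window)
            expected = window_average(complete, index_year, exposure_cfg)
            assert row.window_average == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_pounds(self, small_sim, exposure_cfg):
        """Raising one application's pounds never lowers any window average."""
        from ambientgxe.synthetic import generate_applications, generate_cohort

        apps = generate_applications(small_sim)
        cohort = generate_cohort(small_sim, apps, exposure_cfg)
        before = compute_exposure(
            apps, cohort.addresses, cohort.subjects, exposure_cfg
        )
        apps2 = apps.copy()
        apps2.loc[apps2.index[:50], "pounds"] *= 10.0
        after = compute_exposure(
            apps2, cohort.addresses, cohort.subjects, exposure_cfg
        )
        key = ["subject_id", "setting", "pesticide_id"]
        merged = before.profiles.merge(
            after.profiles, on=key, suffixes=("_lo", "_hi"), how="left"
        )
        assert (
            merged["window_average_hi"] >= merged["window_average_lo"] - 1e-12
        ).all()

    def test_undefined_exposure_subjects_are_flagged(self, exposure_cfg):
        apps = make_applications(
            [("permethrin", "pyrethroid", 1990, 50.0, 50.0, 10.0, 5.0)]
        )
        subjects = pd.DataFrame(
            {
                "subject_id": ["s1", "s2"],
                "status": ["case", "control"],
                "age_years": [60.0, 61.0],
                "sex": ["male", "female"],
                "smoker_ever": [False, True],
                "index_year": [2000, 2000],
                "genotype": ["AA", "GG"],
            }
        )
        rows = []
        for year in range(1974, 1991):
            rows.append(("s1", year, "residential", np.nan, np.nan))
            rows.append(("s2", year, "residential", 50.0, 50.0))
        addresses = pd.DataFrame(
            rows, columns=["subject_id", "year", "setting", "x_m", "y_m"]
        )
        result = compute_exposure(apps, addresses, subjects, exposure_cfg)
        assert result.excluded_subjects == ["s1"]
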