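"""FFQ intake derivation, outlier trimming and consumer binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietrisk.consumption import (
    ConsumptionRecord,
    MissingPortionError,
    UnknownFrequencyCategory,
    bin_consumers,
    derive_all_intakes,
    derive_intakes,
    frequency_to_events_per_day,
    trim_outliers,
)


class TestFrequencyMapping:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("no consumption", 0.0),
            ("2-4 times per week", 3 / 7),
            ("2–4 times per week", 3 / 7),  # en-dash variant
            ("once a month", 1 / 30.44),
            ("2-3 times per month", 2.5 / 30.44),
        ],
    )
    def test_default_mapping(self, category, expected):
        assert frequency_to_events_per_day(category) == pytest.approx(expected)

    def test_unmapped_category_lists_known_ones(self):
        with pytest.raises(UnknownFrequencyCategory, match="once a month"):
            frequency_to_events_per_day("other")

    def test_custom_mapping_overrides(self):
        assert frequency_to_events_per_day("other", {"other": 0.25}) == 0.25


def record(portion, category="2-4 times per week", **kw):
    return ConsumptionRecord("R1", "tomato", category, portion, **kw)


class TestDeriveIntakes:
    def test_chronic_and_acute_from_portion(self):
        r = derive_intakes(record(250.0))
        assert r.chronic_intake_kg_day == pytest.approx(3 / 7 * 0.250)
        assert r.acute_intake_kg == pytest.approx(0.250)

    def test_non_consumer_gets_zero_intakes(self):
        r = derive_intakes(record(None, "no consumption"))
        assert r.chronic_intake_kg_day == 0.0 and r.acute_intake_kg == 0.0
        assert not r.is_consumer

    def test_missing_portion_for_consumer_raises(self):
        with pytest.raises(MissingPortionError):
            derive_intakes(record(None))

    def test_derive_all_excludes_bad_records(self):
        good, bad = derive_all_intakes([record(100.0), record(None)])
        assert len(good) == 1 and len(bad) == 1

    @given(
        st.floats(0, 2000, allow_nan=False),
        st.sampled_from(["once a day", "2-4 times per week", "once a month"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_chronic_equals_rate_times_acute(self, portion, category):
        r = derive_intakes(record(portion, category))
        assert r.chronic_intake_kg_day == pytest.approx(
            r.events_per_day * r.acute_intake_kg
        )


class TestTrimOutliers:
    def test_five_percent_of_hundred_distinct(self):
        kept, removed = trim_outliers(np.arange(1.0, 101.0), 0.05)
        assert kept.size == 95 and removed == 5

    def test_zero_trim_is_identity(self):
        x = np.array([3.0, 1.0, 2.0])
        kept, removed = trim_outliers(x, 0.0)
        assert removed == 0 and np.array_equal(kept, x)

    def test_type7_quantile_cutoff(self):
        # q(0.95) of 1..20 is 19.05 under linear interpolation: only 20 goes
        kept, removed = trim_outliers(np.arange(1.0, 21.0), 0.05)
        assert removed == 1 and kept.max() == 19.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            trim_outliers([], 0.05)

    def test_bad_percentile_raises(self):
        with pytest.raises(ValueError):
            trim_outliers([1.0], 1.0)


class TestBinConsumers:
    def test_equal_count_five_groups(self):
        res = bin_consumers(np.arange(1.0, 101.0), "equal_count", k=5)
        assert np.array_equal(np.bincount(res.group_index)[1:], [20] * 5)

    def test_fractions_sum_to_one_and_means_increase(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 0.5, size=500)
        res = bin_consumers(x, "equal_count", k=5)
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        means = [x[res.group_index == g].mean() for g in range(1, res.k + 1)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_explicit_cutpoints_tie_goes_to_lower_inclusive_interval(self):
        res = bin_consumers([1.0, 2.0, 2.0, 3.0], "explicit_cutpoints", cutpoints=[2.0])
        assert res.group_index.tolist() == [1, 2, 2, 2]

    def test_non_monotone_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            bin_consumers([1.0, 2.0], "explicit_cutpoints", cutpoints=[3.0, 2.0])

    def test_non_consumers_rejected(self):
        with pytest.raises(ValueError):
            bin_consumers([0.0, 1.0], "equal_count")

    @given(st.lists(st.floats(0.01, 10, allow_nan=False), min_size=10, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_binning_invariant_to_input_order(self, values):
        """Trim-then-bin assigns each value the same group regardless of order."""
        x = np.asarray(values)
        kept, _ = trim_outliers(x, 0.05)
        if np.unique(kept).size < 2:
            return
        res_fwd = bin_consumers(kept, "equal_count", k=2)
        order = np.argsort(kept, kind="stable")[::-1]
        res_rev = bin_consumers(kept[order], "equal_count", k=2)
        assert np.array_equal(res_fwd.group_index[order], res_rev.group_index)

    def test_every_consumer_in_exactly_one_group(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, 200)
        res = bin_consumers(x, "equal_width", k=4)
        assert res.group_index.min() >= 1 and res.group_index.max() <= res.k
        assert res.group_index.size == x.size
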