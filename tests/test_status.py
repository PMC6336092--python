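import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceindex import present_status, reference_point, screen_outliers
from ceindex.errors import ReferenceUndefinedError


def panel(values, sites=None, years=None):
    n = len(values)
    return pd.DataFrame({
        "site_id": sites or [f"S{i % 4}" for i in range(n)],
        "year": years or [2009 + i % 5 for i in range(n)],
        "value": values,
    })


def brute_force_screen(values, k):
    """Literal one-pass k-sigma rule: oracle for the screening stage."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return list(values), []
    m, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return list(values), []
    keep = np.abs(v - m) <= k * sd
    return list(v[keep]), list(v[~keep])


class TestScreening:
    def test_single_extreme_among_twenty_is_excluded(self):
        # 19 x 1.0 and one 10.0: mean 1.45, sample sd ~2.012, 2sd < 8.55
        vals = [1.0] * 19 + [10.0]
        res = screen_outliers(panel(vals), k=2.0)
        assert res.mean == pytest.approx(1.45)
        assert res.sd == pytest.approx(2.0124611797, rel=1e-9)
        assert list(res.excluded["value"]) == [10.0]
        assert len(res.retained) == 19

    def test_identical_values_are_all_retained(self):
        res = screen_outliers(panel([7.0] * 5), k=2.0)
        assert res.excluded.empty
        assert len(res.retained) == 5

    def test_small_sample_cannot_exceed_two_sigma(self):
        # max |z| at n=5 is (n-1)/sqrt(n) ~ 1.79 < 2: nothing excluded
        res = screen_outliers(panel([0.0, 0.0, 0.0, 0.0, 100.0]), k=2.0)
        assert res.excluded.empty

    def test_single_value_flags_no_screening(self):
        res = screen_outliers(panel([3.0]), k=2.0)
        assert "NO_SCREENING" in res.flags
        assert len(res.retained) == 1

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=0, max_size=20))
    def test_screening_matches_brute_force_oracle(self, values):
        res = screen_outliers(panel(values), k=2.0)
        keep, drop = brute_force_screen(values, 2.0)
        assert sorted(res.retained["value"]) == pytest.approx(sorted(keep))
        assert sorted(res.excluded["value"]) == pytest.approx(sorted(drop))


class TestReferencePoint:
    def test_max_with_provenance(self):
        df = panel([1.0, 3.41, 2.0, 3.0],
                   sites=["A", "B", "C", "D"],
                   years=[2009, 2011, 2012, 2013])
        ref = reference_point(df, "food", (2009, 2013))
        assert ref.X_R == 3.41
        assert (ref.source_site, ref.source_year) == ("B", 2011)

    def test_ties_break_to_earliest_year_then_site(self):
        df = panel([7.0, 7.0, 7.0], sites=["C", "B", "A"],
                   years=[2011, 2010, 2010])
        ref = reference_point(df, "s", (2009, 2013))
        assert ref.X_R == 7.0
        assert (ref.source_site, ref.source_year) == ("A", 2010)

    def test_excluding_the_outlier_changes_the_maximum(self):
        vals = [1.0] * 19 + [10.0]
        res = screen_outliers(panel(vals), k=2.0)
        ref = reference_point(res.retained, "s", (2009, 2013))
        assert ref.X_R == 1.0

    def test_all_zero_raises_reference_undefined(self):
        with pytest.raises(ReferenceUndefinedError, match="food"):
            reference_point(panel([0.0, 0.0, 0.0]), "food", (2009, 2013))

    def test_override_short_circuits_selection(self):
        ref = reference_point(panel([1.0, 2.0]), "s", (2009, 2013),
                              override=5.0)
        assert ref.X_R == 5.0 and ref.override
        assert ref.source_site is None

    def test_removing_a_non_maximal_site_leaves_reference_unchanged(self):
        df = panel([1.0, 5.0, 2.0, 4.0], sites=["A", "B", "C", "D"])
        full = reference_point(df, "s", (2009, 2013))
        reduced = reference_point(df[df["site_id"] != "C"], "s", (2009, 2013))
        assert full.X_R == reduced.X_R == 5.0

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=20))
    def test_screen_then_max_equals_oracle(self, values):
        keep, _ = brute_force_screen(values, 2.0)
        res = screen_outliers(panel(values), k=2.0)
        if not any(v > 0 for v in keep):
            with pytest.raises(ReferenceUndefinedError):
                reference_point(res.retained, "s", (2009, 2013))
        else:
            ref = reference_point(res.retained, "s", (2009, 2013))
            assert ref.X_R == max(keep)


class TestPresentStatus:
    @pytest.mark.parametrize("X,xr,expected", [
        (3.4, 3.4, 1.0),
        (0.0, 3.4, 0.0),
        (1.7, 3.4, 0.5),
    ])
    def test_ratio(self, X, xr, expected):
        ref = reference_point(panel([xr]), "s", (2009, 2013), override=xr)
        x, flags = present_status(X, ref)
        assert x == pytest.approx(expected)
        assert flags == []

    def test_missing_value_is_na_with_flag(self):
        ref = reference_point(panel([2.0]), "s", (2009, 2013), override=2.0)
        x, flags = present_status(None, ref)
        assert math.isnan(x) and flags == ["NO_DATA"]
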