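import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceindex import (
    FactorDefinition,
    aggregate_pr,
    factor_diagnostics,
    qualitative_factor_score,
    quantitative_factor_score,
)
from ceindex.pr import FactorScore


def fs(factor_id, score):
    return FactorScore(factor_id, "svc", "site", score,
                       "missing" if score is None else "qualitative")


class TestQuantitative:
    @pytest.mark.parametrize("do,expected", [
        (2.0, -1.0),   # lower anchor: hypoxic water
        (6.0, +1.0),   # upper anchor: well-oxygenated water
        (4.0, 0.0),    # pressure/resilience split
        (3.0, -0.5),   # linear interpolation
        (0.5, -1.0),   # saturates below
        (9.0, +1.0),   # saturates above
    ])
    def test_dissolved_oxygen_model(self, do_factor, do, expected):
        assert quantitative_factor_score(do, do_factor) == pytest.approx(expected)

    def test_nan_value_scores_missing(self, do_factor):
        assert quantitative_factor_score(float("nan"), do_factor) is None

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.floats(min_value=-10, max_value=20, allow_nan=False))
    def test_bounded_and_mirrored(self, value):
        inc = FactorDefinition(factor_id="f", service_id="s",
                               kind="quantitative", lo_threshold=2.0,
                               hi_threshold=6.0, direction="increasing_good")
        dec = inc.model_copy(update={"direction": "decreasing_good"})
        si = quantitative_factor_score(value, inc)
        sd = quantitative_factor_score(value, dec)
        assert -1.0 <= si <= 1.0
        assert sd == pytest.approx(-si)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.floats(min_value=-10, max_value=20),
           st.floats(min_value=-10, max_value=20))
    def test_monotone_non_decreasing_for_increasing_good(self, a, b):
        f = FactorDefinition(factor_id="f", service_id="s",
                             kind="quantitative", lo_threshold=2.0,
                             hi_threshold=6.0)
        lo, hi = sorted((a, b))
        assert (quantitative_factor_score(hi, f)
                >= quantitative_factor_score(lo, f))


class TestQualitative:
    @pytest.mark.parametrize("state,expected", [
        ("positive", +0.5), ("negative", -0.5), ("unknown", None),
    ])
    def test_default_half_magnitude(self, qual_factor, state, expected):
        assert qualitative_factor_score(state, qual_factor) == expected

    def test_configurable_magnitude(self):
        f = FactorDefinition(factor_id="f", service_id="s",
                             kind="qualitative", qualitative_magnitude=0.8)
        assert qualitative_factor_score("negative", f) == -0.8


class TestAggregate:
    def test_symmetric_pair_averages_to_zero(self):
        pr, flags = aggregate_pr([fs("a", 0.5), fs("b", -0.5)])
        assert pr == 0.0 and flags == []

    def test_mixed_factor_mean(self):
        pr, _ = aggregate_pr(
            [fs(c, v) for c, v in zip("abcde", [-1.0, -0.5, 0.5, -0.5, 0.5])]
        )
        assert pr == pytest.approx(-0.2)

    def test_unknowns_excluded_from_mean(self):
        pr, flags = aggregate_pr([fs("a", None), fs("b", 0.5)])
        assert pr == 0.5
        assert "FACTOR_UNKNOWN" in flags

    def test_all_unknown_is_na(self):
        pr, flags = aggregate_pr([fs("a", None)])
        assert pr is None and "NO_PR" in flags

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1,
                    max_size=10))
    def test_mean_bounded_by_extremes(self, scores):
        pr, _ = aggregate_pr([fs(f"f{i}", s) for i, s in enumerate(scores)])
        assert min(scores) - 1e-12 <= pr <= max(scores) + 1e-12
        assert pr == pytest.approx(sum(scores) / len(scores))


class TestDiagnostics:
    def test_negative_factors_sorted_worst_first(self):
        scores = [fs("anoxic_water", -1.0), fs("blue_tide", -0.5),
                  fs("source_of_juveniles", +0.5)]
        assert factor_diagnostics(scores) == ["anoxic_water", "blue_tide"]

    def test_no_pressure_factors_gives_empty_list(self):
        assert factor_diagnostics([fs("a", 0.0), fs("b", 0.5)]) == []

    def test_ties_break_lexicographically(self):
        scores = [fs("zeta", -0.5), fs("alpha", -0.5)]
        assert factor_diagnostics(scores) == ["alpha", "zeta"]
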