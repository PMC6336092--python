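import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceindex import future_status, service_score, sustainability
from ceindex.config import ReportScale
from ceindex.scoring import score_service

BETA = 0.67


class TestFutureStatus:
    def test_neutral_conditions_project_present_status(self):
        x_f, flags = future_status(0.42, 0.0, 0.0, BETA)
        assert x_f == pytest.approx(0.42) and flags == []

    def test_clamps_at_reference_ceiling(self):
        # multiplier 1 + 0.67 + 0.33 = 2 doubles x = 0.5 to the boundary
        x_f, flags = future_status(0.5, 1.0, 1.0, BETA)
        assert x_f == 1.0 and flags == []
        x_f, flags = future_status(0.6, 1.0, 1.0, BETA)
        assert x_f == 1.0 and flags == ["CLAMPED_FUTURE"]

    def test_worst_case_multiplier_zeroes_the_projection(self):
        x_f, _ = future_status(0.5, -1.0, -1.0, 0.3)
        assert x_f == 0.0

    def test_na_propagates(self):
        x_f, flags = future_status(math.nan, 0.1, 0.1, BETA)
        assert math.isnan(x_f) and flags == ["NO_DATA"]


class TestServiceScore:
    @pytest.mark.parametrize("x,x_f,expected", [
        (1.0, 1.0, 100.0), (0.0, 0.0, 0.0), (0.6, 0.4, 50.0),
    ])
    def test_percent_scale(self, x, x_f, expected):
        assert service_score(x, x_f) == pytest.approx(expected)

    def test_unit_scale(self):
        assert service_score(0.6, 0.4, ReportScale.unit) == pytest.approx(0.5)


class TestSustainability:
    def test_stable_service_scores_zero(self):
        s, flags = sustainability(0.7, 0.7)
        assert s == 0.0 and flags == []

    def test_relative_change(self):
        s, _ = sustainability(0.5, 0.6)
        assert s == pytest.approx(0.20)

    def test_zero_status_is_undefined(self):
        s, flags = sustainability(0.0, 0.0)
        assert math.isnan(s) and flags == ["X_ZERO"]


class TestComposition:
    def test_closed_form_example(self):
        cell = score_service("A", "food", x=0.8, trend_T=0.1, pr=0.2,
                             beta=BETA)
        expected_s = BETA * 0.1 + (1 - BETA) * 0.2
        assert cell.S == pytest.approx(expected_s, abs=1e-12)
        assert cell.I == pytest.approx(0.8 * (2 + expected_s) / 2 * 100)

    def test_missing_pr_defaults_to_trend_only(self):
        cell = score_service("A", "research", x=0.8, trend_T=0.0, pr=None,
                             beta=BETA)
        assert math.isnan(cell.PR)
        assert cell.x_F == pytest.approx(0.8)
        assert cell.S == pytest.approx(0.0)
        assert "PR_DEFAULTED" in cell.flags

    def test_missing_status_yields_all_na_cell(self):
        cell = score_service("A", "food", x=math.nan, trend_T=0.2, pr=0.1,
                             beta=BETA)
        assert all(math.isnan(v) for v in
                   (cell.x, cell.x_F, cell.I, cell.S))
        assert "NO_DATA" in cell.flags

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(st.floats(min_value=1e-6, max_value=1.0),
           st.floats(min_value=-1, max_value=1),
           st.floats(min_value=-1, max_value=1),
           st.floats(min_value=0, max_value=1))
    def test_identity_s_equals_weighted_trend_pr(self, x, T, pr, beta):
        raw = (1 + beta * T + (1 - beta) * pr) * x
        cell = score_service("A", "s", x=x, trend_T=T, pr=pr, beta=beta)
        if raw <= 1.0:
            assert cell.S == pytest.approx(beta * T + (1 - beta) * pr,
                                           abs=1e-9)
            assert abs(cell.S) <= 1 + 1e-12
        else:
            assert "CLAMPED_FUTURE" in cell.flags
            assert cell.x_F == 1.0

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=-0.9, max_value=0.9),
           st.floats(min_value=-1, max_value=1),
           st.floats(min_value=0.0, max_value=0.02))
    def test_service_score_monotone_in_each_argument(self, x, T, pr, eps):
        # pre-clamp region: small x keeps the projection below the ceiling
        base = score_service("A", "s", x=x, trend_T=T, pr=pr, beta=BETA).I
        up_T = score_service("A", "s", x=x, trend_T=T + eps, pr=pr,
                             beta=BETA).I
        up_pr = score_service("A", "s", x=x, trend_T=T,
                              pr=min(1, pr + eps), beta=BETA).I
        assert up_T >= base - 1e-9
        assert up_pr >= base - 1e-9
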