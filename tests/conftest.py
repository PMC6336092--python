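import pytest

from ceindex import generate_panel, run_assessment, tokyo_bay_like


@pytest.fixture(scope="session")
def demo_panel():
    return generate_panel(tokyo_bay_like(seed=0))


@pytest.fixture(scope="session")
def demo_result(demo_panel):
    return run_assessment(demo_panel.config, demo_panel.indicators,
                          demo_panel.factors)


@pytest.fixture()
def do_factor():
    """The dissolved-oxygen factor model: -1 at 2 mg/L, +1 at 6 mg/L."""
    from ceindex import FactorDefinition

    return FactorDefinition(
        factor_id="anoxic_water", service_id="food_provision",
        kind="quantitative", lo_threshold=2.0, hi_threshold=6.0,
    )


@pytest.fixture()
def qual_factor():
    from ceindex import FactorDefinition

    return FactorDefinition(
        factor_id="blue_tide", service_id="food_provision", kind="qualitative",
    )
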