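import pytest

from erlangfit import GridSpec, ParamPoint, SyntheticCohortConfig, generate


@pytest.fixture(scope="session")
def nephro_series():
    """Noiseless nephroblastoma-like curve: erlang_gamma k=1.75, b=2.20, A=124."""
    series, truth = generate(SyntheticCohortConfig())
    return series, truth


@pytest.fixture(scope="session")
def exponential_series():
    """Noiseless exponential-shaped curve: erlang_gamma k=1, b=2.5, A=179."""
    series, truth = generate(
        SyntheticCohortConfig(true_params=ParamPoint(1.0, 2.5), amplitude=179.0)
    )
    return series, truth


@pytest.fixture(scope="session")
def shape_grid_fine():
    """Reduced shape-family grid with the default 0.05 step (200 x 200)."""
    return GridSpec.from_ranges(0.05, 10.0, 0.05, 0.05, 10.0, 0.05)


@pytest.fixture(scope="session")
def location_grid():
    """Reduced location-family grid: mu -10..19.8, b 0.2..20, step 0.2."""
    return GridSpec.from_ranges(-10.0, 19.8, 0.2, 0.2, 20.0, 0.2)
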