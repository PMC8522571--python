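import numpy as np
import pytest

from didsim import RngSpec, draw_panel, make_scenario


@pytest.fixture
def small_panel():
    """A quick default Scenario-1 panel with few units."""
    config = make_scenario("1", {"n_units": 60})
    return draw_panel(config, RngSpec(1234))


@pytest.fixture
def noiseless_panel_factory():
    """Factory for panels with no outcome noise (sigma_y = 0).

    The covariate keeps its unit-level spread so covariate-adjusted designs
    stay full rank; the outcome is then an exact linear function of the
    design, so correctly specified estimators recover coefficients exactly.
    """

    def make(scenario_id, seed=7, **extra):
        overrides = {"sigma_y": 0.0}
        overrides.update(extra)
        config = make_scenario(scenario_id, overrides)
        return config, draw_panel(config, RngSpec(seed))

    return make
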