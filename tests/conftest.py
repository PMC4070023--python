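import pytest

from schoolva import (SimulationConfig, bmi_sds_frame, simulate_panel,
                      synthetic_reference)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def small_config():
    """A reduced-scale panel: 50 schools, 3 years, ~1400 pupils/year."""
    return SimulationConfig(
        n_schools=50, n_neighbourhoods=80, pupils_per_school_per_cohort=14,
        years=("2006/07", "2007/08", "2008/09"), seed=12345)


@pytest.fixture(scope="session")
def small_panel(reference, small_config):
    """z-scored records (incl. generator truth) for the reduced-scale panel."""
    panel = simulate_panel(small_config, reference=reference)
    return bmi_sds_frame(panel, reference)
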