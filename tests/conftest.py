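import numpy as np
import pandas as pd
import pytest

from aquatherm.thermal_environment import TeProfile
from aquatherm.synthetic_data import default_study_configs, generate_study


def make_profile(grid, depths=None, start="2014-06-10 09:30", step_min=30,
                 tank_id="T1"):
    """Small hand-built operative-temperature profile."""
    grid = np.asarray(grid, dtype=float)
    depths = np.arange(grid.shape[0]) * 5.0 if depths is None else np.asarray(depths, float)
    times = pd.date_range(start, periods=grid.shape[1], freq=f"{step_min}min")
    return TeProfile(tank_id=tank_id, depths=depths, times=pd.DatetimeIndex(times),
                     grid=grid)


@pytest.fixture
def flat_profile():
    """Constant 20 C column: 3 depths x 5 half-hours covering 09:30-11:30."""
    return make_profile(np.full((3, 5), 20.0))


@pytest.fixture(scope="session")
def synthetic_study():
    """One canonical two-species study, shared across tests (seed 2014)."""
    cfg_a, cfg_b = default_study_configs(2014)
    return generate_study(cfg_a, cfg_b)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, synthetic_study):
    """The same study written out as CSVs + truth JSON."""
    from aquatherm.synthetic_data import write_study

    d = tmp_path_factory.mktemp("study")
    write_study(synthetic_study, d)
    return d
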