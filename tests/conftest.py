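import numpy as np
import pytest
from hypothesis import settings

import rockerflow as rf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return rf.WellGeometry()


@pytest.fixture(scope="session")
def water37():
    return rf.water_properties(37.0)


@pytest.fixture(scope="session")
def coarse_cfg():
    """Cheap solver settings for unit tests (not the production defaults)."""
    return rf.SolverConfig(n_cells=150, spinup_periods=2, record_periods=1)


@pytest.fixture
def square_record():
    """2 N/m^2 for 10% of a 1 s period, else 0, sampled at 1 kHz."""
    from rockerflow.fixtures import FixtureSpec, gen_shear_record

    return gen_shear_record(
        FixtureSpec(
            kind="shear_record",
            params={"waveform": "square", "amplitude": 2.0, "duty": 0.1},
        )
    )
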