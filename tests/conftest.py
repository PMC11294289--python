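import io

import pytest

from voxplp import AxisValues, RadarConfig, fixtures


@pytest.fixture
def assessment():
    """The published 6x4 single-round assessment matrix."""
    return fixtures.assessment_dataset()


@pytest.fixture
def worked_values():
    """Axis values of the worked radar-chart example (vertices 12,10,8,12)."""
    return fixtures.worked_profile_values()


@pytest.fixture
def config12():
    """Radar configuration with the property radius of the worked examples."""
    return RadarConfig(property_radius=fixtures.inferred_property_radius())


@pytest.fixture
def assessment_csv(assessment):
    """The assessment matrix as a canonical trial-level CSV stream."""
    from voxplp import write_trials

    buf = io.StringIO()
    write_trials(assessment, buf)
    buf.seek(0)
    return buf


@pytest.fixture
def balanced_values():
    return AxisValues(tact=12, mand=12, echoic=12, sequelic=12)
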