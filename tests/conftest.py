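import numpy as np
import pytest

from nfertdss import (
    CropParams,
    FieldParams,
    LeakageNetwork,
    Scenario,
    ScenarioSeries,
)
from nfertdss.scenarios import default_single_field, random_tiny_instance


@pytest.fixture(scope="session")
def single_field_instance():
    return default_single_field()


@pytest.fixture
def tiny_instance():
    return random_tiny_instance(7, n_fields=1, n_days=20, n_candidates=2)


@pytest.fixture
def tiny_scenario():
    """Deterministic 5-day single-field scenario with simple round numbers,
    convenient for hand-unrolled checks."""
    crop = CropParams(lue=3.0, k=0.6, eps=0.5, uptake_scale=0.01)
    series = ScenarioSeries(
        dtr=np.full((1, 5), 20.0), lai=np.array([[1.0, 1.5, 2.0, 2.5, 3.0]])
    )
    return Scenario(
        crop=crop,
        fields=(FieldParams(field_id=1, eta=0.9, n0=5.0),),
        series=series,
        leakage=LeakageNetwork.none(1),
    )
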