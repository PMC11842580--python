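import numpy as np
import pytest

from cdi.dekads import Dekad
from cdi.grid import GridSpec
from cdi.classifier import load_decision_table
from cdi.synthetic import DroughtEvent, SceneConfig, generate_scene


@pytest.fixture(scope="session")
def table():
    return load_decision_table()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_rows=6, n_cols=6, lon_origin=10.0, lat_origin=50.0)


@pytest.fixture(scope="session")
def drought_event():
    """A strong 9-dekad precipitation deficit over the south-western block."""
    return DroughtEvent(region=(slice(6, 12), slice(2, 8)),
                        start=Dekad(2020, 10), end=Dekad(2020, 18),
                        multiplier=0.2)


@pytest.fixture(scope="session")
def event_scene(drought_event):
    """12x12 scene with the reference baselines and one injected drought."""
    cfg = SceneConfig(grid=GridSpec(n_rows=12, n_cols=12, lon_origin=10.0, lat_origin=62.0),
                      seed=7)
    return generate_scene(cfg, [drought_event])


@pytest.fixture(scope="session")
def calm_scene():
    """8x8 scene with the reference baselines and no drought events."""
    cfg = SceneConfig(grid=GridSpec(n_rows=8, n_cols=8, lon_origin=10.0, lat_origin=62.0),
                      seed=3)
    return generate_scene(cfg, [])
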