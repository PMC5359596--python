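import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from vsdassay.biophysics import (
    CellModel,
    DrugModel,
    FieldGeometry,
    PulseProtocol,
)
from vsdassay.imaging import PlateMap, SceneParams, simulate_passage_pair


@pytest.fixture
def cell():
    return CellModel(center=(96.0, 96.0))


@pytest.fixture
def pulse():
    return PulseProtocol()


@pytest.fixture
def fieldgeom():
    return FieldGeometry()


@pytest.fixture
def drug():
    return DrugModel(ec50=1e-6, hill=1.0, g_max_fold=5.0)


@pytest.fixture
def noiseless_scene():
    return SceneParams(noise=False, bleach_fraction=0.0, shift_max=0)


def simulate_single_area(concentration, drug, scene, seed=1, **kw):
    """One sampling area at one concentration; returns an AreaSimulation."""
    pm = PlateMap.single_row(
        [concentration], sampling_areas_per_well=1, seed=seed
    )
    return simulate_passage_pair(pm, drug, scene=scene, **kw)[0]


@pytest.fixture
def single_area_factory():
    return simulate_single_area
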