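import numpy as np
import pytest

from disaggval.raster import RasterLayer
from disaggval.survey_metrics import (
    DensityClass,
    FieldRecord,
    LocationSurvey,
    Management,
    PlantRecord,
)
from disaggval.synthetic_data import SimulationConfig, generate_scene


@pytest.fixture(scope="session")
def ci_scene():
    """Ivory-Coast-like default scene: 69 locations in 9 regions."""
    return generate_scene(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_scene():
    """Small fast scene for extraction and pipeline tests."""
    cfg = SimulationConfig(
        seed=7, grid_nrows=60, grid_ncols=60, n_locations=25, n_regions=4
    )
    return generate_scene(cfg)


@pytest.fixture
def toy_location():
    """One monoculture 100 m2 + one intercrop 200 m2 field and 1 plant, delta=40,000."""
    return LocationSurvey(
        location_id="T1",
        longitude=0.0,
        latitude=0.0,
        quadrants=4,
        fields=[
            FieldRecord("T1", Management.MONOCULTURE, 100.0, DensityClass.UNRECORDED),
            FieldRecord("T1", Management.INTERCROP, 200.0, DensityClass.UNRECORDED),
        ],
        plants=PlantRecord("T1", 1),
    )


def make_ramp_layer(nrows=10, ncols=12, cell_size=1000.0, crs="planar_m"):
    """Deterministic ramp raster: value = row * ncols + col."""
    values = np.arange(nrows * ncols, dtype=float).reshape(nrows, ncols)
    return RasterLayer(values, 0.0, nrows * cell_size, cell_size, crs=crs, name="ramp")


@pytest.fixture
def ramp_layer():
    return make_ramp_layer()
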