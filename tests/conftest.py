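"""Shared fixtures: small synthetic recordings generated at test time.

The expensive paper-like run (100 s at 1 kHz on a 64×64 lattice, all signal
components enabled) is session-scoped and shared by the model, pipeline and
acceptance tests.
"""

import numpy as np
import pytest

from meafield import simulate as sim
from meafield.io import Recording, make_standard_layout
from meafield.model import SubthresholdFieldModel
from meafield.theory import REFERENCE_PARAMS


@pytest.fixture(scope="session")
def paper_params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def paperlike_recording():
    """100 s paper-like synthetic recording with spikes and artifacts."""
    grid = sim.FieldSimulationGrid(lattice_shape=(64, 64), time_step=1.0, duration=100_000.0)
    cfg = sim.default_config(grid=grid, seed=101)
    return sim.generate_recording(cfg)


@pytest.fixture(scope="session")
def paperlike_results(paperlike_recording):
    rec, _ = paperlike_recording
    model = SubthresholdFieldModel.from_recording(rec)
    return model.fit()


@pytest.fixture(scope="session")
def small_field_recording():
    """Artifact- and spike-free field on a 4×4 array, 100 s at 1 kHz."""
    grid = sim.FieldSimulationGrid(lattice_shape=(32, 32), time_step=1.0, duration=100_000.0)
    layout = make_standard_layout(4, 4, 0.2)
    out = sim.simulate_field(grid, REFERENCE_PARAMS, seed=77, sample_positions=layout.positions)
    return Recording(out["traces"], 1.0, layout)


@pytest.fixture
def tiny_layout():
    return make_standard_layout(2, 2, 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
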