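import numpy as np
import pytest

from mlao.datagen import SpecimenSpec, generate_specimen
from mlao.imaging import ModalityConfig
from mlao.zernike import PupilGrid


@pytest.fixture(scope="session")
def grid():
    """Desk-scale simulation grid: 64-sample pupil in a 128-point FFT."""
    return PupilGrid(n_pupil=64, n_fft=128)


@pytest.fixture(scope="session")
def grid_fine():
    """Default-resolution grid for discretization-sensitive checks."""
    return PupilGrid(n_pupil=128, n_fft=256)


@pytest.fixture(scope="session")
def noiseless_2p():
    return ModalityConfig("2P")


@pytest.fixture(scope="session")
def bead_field(grid):
    """A reproducible bead-ensemble specimen on the grid's field of view."""
    return generate_specimen(SpecimenSpec("beads", seed=42), shape=(grid.n_fft, grid.n_fft))


@pytest.fixture(scope="session")
def trained_study_model():
    """The desk-scale 2-P study model (trained once per session; several
    minutes of dataset synthesis + CNN training on one CPU)."""
    from mlao import study

    model, history, scheme = study.train_study_model(seed=1)
    return model, history, scheme
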