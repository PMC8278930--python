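import numpy as np
import pytest

from cdmelt import SampleMeta, CDSpectrumSeries


@pytest.fixture
def meta():
    return SampleMeta(protein_conc=100.0, pathlength=0.01,
                      molecular_weight=146000.0, n_residues=1320, label="F1")


@pytest.fixture
def toy_series(meta):
    """2 temperatures x 3 wavelengths, values chosen to be exactly
    representable."""
    return CDSpectrumSeries(
        temperatures=np.array([25.0, 27.0]),
        wavelengths=np.array([216.0, 217.0, 218.0]),
        signal=np.array([[-1.0, -2.0, -3.0], [-1.5, -2.5, -3.5]]),
        units="millidegrees", meta=meta)


@pytest.fixture
def wl_grid():
    return np.arange(190.0, 261.0, 1.0)
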