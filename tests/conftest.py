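import numpy as np
import pytest

import hibafish as hf
from hibafish import simulate as sim
from hibafish.config import NoiseSpec
from hibafish.imaging import FieldImage, analyze_field


@pytest.fixture(scope="session")
def imaging():
    return hf.ImagingConfig()


@pytest.fixture(scope="session")
def noise_free_field(imaging):
    """A noise-free 20-nucleus field with its ground truth and analysis."""
    stacks, gt = sim.simulate_field(
        hf.negative_cell_model(), 20, imaging, NoiseSpec.none(), seed=42)
    records = analyze_field(FieldImage("f000", stacks, imaging))
    return stacks, gt, records


@pytest.fixture()
def rng():
    return np.random.default_rng(20240815)
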