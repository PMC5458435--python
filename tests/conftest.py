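import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mammroi import PhantomSpec, default_seg_params, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_spec():
    return PhantomSpec(rows=48, cols=48, seed=7)


@pytest.fixture
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture
def small_params(small_spec):
    return default_seg_params(small_spec)
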