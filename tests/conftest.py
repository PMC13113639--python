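import os

# keep BLAS single-threaded: the workloads are small-matrix bound and thread
# pools sized from the host core count oversubscribe CPU-limited containers
for _v in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

import pgrecon as pg


@pytest.fixture
def grid64():
    return pg.GridSpec(64, 64)


@pytest.fixture
def grid16():
    return pg.GridSpec(16, 16)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
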