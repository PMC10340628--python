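import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pdscreen.cohort import CohortSpec, gen_cohort, toy_embedder


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """12-speaker, 2 s cohort for fast structural tests."""
    return gen_cohort(CohortSpec(n_pd=6, n_hc=6, duration_s=2.0, seed=11))


@pytest.fixture(scope="session")
def embedder16():
    return toy_embedder(d=16, seed=3)


@pytest.fixture()
def float64_params(monkeypatch):
    """Run nn layers in float64 so finite-difference checks are tight."""
    from pdscreen.nn import layers

    monkeypatch.setattr(layers, "DTYPE", np.float64)
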