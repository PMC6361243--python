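"""Shared fixtures: small synthetic complexes and a quick trained model.

Everything is generated programmatically at test time; training fixtures
use deliberately small boosting configurations so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from pairsite.encoding import encode_complex
from pairsite.fixtures import ToyComplexSpec, make_benchmark_set, make_toy_complex
from pairsite.model import ModelConfig
from pairsite.pipeline import train_pipeline

QUICK_CONFIG = ModelConfig(n_rounds=30, max_depth=3, n_oof_folds=2)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=11, n_res_a=16, n_res_b=18,
                                           interface_width=4))


@pytest.fixture(scope="session")
def benchmark4():
    return make_benchmark_set(4, seed=3)


@pytest.fixture(scope="session")
def encodings4(benchmark4):
    return {
        t.complex_id: encode_complex(t.pair, t.contacts,
                                     t.profiles_a, t.profiles_b)
        for t in benchmark4
    }


@pytest.fixture(scope="session")
def trained4(encodings4):
    return train_pipeline(encodings4, config=QUICK_CONFIG, seed=1,
                          fit_calibration=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
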