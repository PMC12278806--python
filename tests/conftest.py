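"""Shared fixtures: small synthetic libraries and trained models.

Everything is generated at test time from seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from rxnsvr.kernels import KernelSpec
from rxnsvr.models import SVRConfig, train
from rxnsvr.synthetic import AMINE_ALKYLATION, FixtureSpec, generate_library


@pytest.fixture(scope="session")
def template():
    return AMINE_ALKYLATION


@pytest.fixture(scope="session")
def small_library():
    """~120-record library with ambiguity, used across module tests."""
    spec = FixtureSpec(
        n_r1=15, n_r2=15, occupancy=0.55, ambiguous_fraction=0.25, seed=7
    )
    records, pool1, pool2, template, truth = generate_library(spec)
    return {
        "spec": spec,
        "records": records,
        "pool1": pool1,
        "pool2": pool2,
        "template": template,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def quick_config():
    """Reduced hyperparameter grid for fast module-level training tests."""
    return SVRConfig(c_grid=(1.0, 10.0), epsilon_grid=(0.05, 0.1), cv_seed=0)


@pytest.fixture(scope="session")
def pk_model(small_library, quick_config):
    return train(small_library["records"], KernelSpec("product"), quick_config)


@pytest.fixture(scope="session")
def baseline_model(small_library, quick_config):
    return train(small_library["records"], KernelSpec("single_tanimoto"), quick_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_fingerprint(rng, n_bits=256, density=0.15):
    from rxnsvr.chem import BitFingerprint

    n_on = max(1, int(density * n_bits))
    bits = rng.choice(n_bits, size=n_on, replace=False)
    return BitFingerprint(on_bits=tuple(int(b) for b in bits), n_bits=n_bits)


def random_pair(rng, n_bits=256):
    return (random_fingerprint(rng, n_bits), random_fingerprint(rng, n_bits))
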