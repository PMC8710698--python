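import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phf6agg.synthetic import (
    EnsembleSpec,
    build_barrel,
    build_labeled_ensemble,
    build_random_coil,
    build_sheet,
)


@pytest.fixture(scope="session")
def parallel_sheet12():
    return build_sheet(12, parallel=True)


@pytest.fixture(scope="session")
def anti_sheet2():
    return build_sheet(2, parallel=False)


@pytest.fixture(scope="session")
def barrel6():
    return build_barrel(6)


@pytest.fixture(scope="session")
def coil12():
    return build_random_coil(12, seed=11)


@pytest.fixture(scope="session")
def coil_frames():
    """A handful of random 12-chain coil frames for oracle checks."""
    out = []
    for seed in range(4):
        topo, fr = build_random_coil(12, seed=seed)
        out.append((topo, fr))
    return out


@pytest.fixture(scope="session")
def small_mixture():
    spec = EnsembleSpec(n_frames=40, seed=3)
    return build_labeled_ensemble(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
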