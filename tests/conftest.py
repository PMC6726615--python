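import math

import numpy as np
import pytest

from distfold.structio import backbone_from_torsions
from distfold.synthetic import (OracleConfig, ToyFoldSpec, make_toy_fold,
                                random_fold_spec)


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal alpha-helix."""
    L = 30
    phi = np.full(L, math.radians(-57.0))
    psi = np.full(L, math.radians(-47.0))
    return backbone_from_torsions("A" * L, phi, psi)


@pytest.fixture(scope="session")
def strand20():
    """20-residue fully extended chain."""
    L = 20
    phi = np.full(L, math.radians(-120.0))
    psi = np.full(L, math.radians(120.0))
    return backbone_from_torsions("A" * L, phi, psi)


@pytest.fixture(scope="session")
def toy_fold_small():
    """Compact 27-residue helix-turn-helix toy."""
    return make_toy_fold(ToyFoldSpec(ss="H" * 12 + "CCC" + "H" * 12), 2)


@pytest.fixture(scope="session")
def toy_fold_60():
    """60-residue random-layout toy fold."""
    return make_toy_fold(random_fold_spec(60, rng_seed=5), 5)


@pytest.fixture()
def zero_noise_oracle():
    return OracleConfig(distance_sigma=0.05, corruption_rate=0.0,
                        torsion_sigma=1e-6, rng_seed=1)
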