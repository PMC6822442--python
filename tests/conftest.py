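import numpy as np
import pandas as pd
import pytest

from wssgwas.kinship import Pedigree, UNKNOWN


@pytest.fixture
def trio():
    """Sire, dam, offspring."""
    return Pedigree(ids=np.array([1, 2, 3]),
                    sire=np.array([UNKNOWN, UNKNOWN, 0]),
                    dam=np.array([UNKNOWN, UNKNOWN, 1]))


@pytest.fixture
def family_pedigree():
    """2 founder pairs, full sibs, and an offspring of full-sib mating."""
    #  0,1 founders -> 2,3 full sibs -> 4 inbred (2 x 3)
    return Pedigree(ids=np.arange(1, 6),
                    sire=np.array([UNKNOWN, UNKNOWN, 0, 0, 2]),
                    dam=np.array([UNKNOWN, UNKNOWN, 1, 1, 3]))


def random_pedigree(rng: np.random.Generator, n_founders: int = 20,
                    n_total: int = 100) -> Pedigree:
    """Random topologically ordered pedigree; later animals draw parents
    uniformly among earlier ones (possibly unknown)."""
    sire = [UNKNOWN] * n_founders
    dam = [UNKNOWN] * n_founders
    for i in range(n_founders, n_total):
        s = int(rng.integers(0, i))
        d = int(rng.integers(0, i))
        if d == s:
            d = UNKNOWN
        sire.append(s)
        dam.append(d)
    return Pedigree(ids=np.arange(1, n_total + 1),
                    sire=np.array(sire), dam=np.array(dam))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
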