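import numpy as np
import pytest

from snppca import GenotypeMatrix


def make_matrix(values, coding="unknown", ploidy_mode="binary") -> GenotypeMatrix:
    values = np.asarray(values)
    r, c = values.shape
    return GenotypeMatrix(
        values,
        tuple(f"ind{i + 1:04d}" for i in range(r)),
        tuple(f"snp{j + 1:04d}" for j in range(c)),
        coding=coding,
        ploidy_mode=ploidy_mode,
    )


def random_polymorphic(rng, R, C) -> GenotypeMatrix:
    """Random binary matrix with no constant row or column."""
    while True:
        v = rng.integers(0, 2, size=(R, C))
        if v.std(axis=0).min() > 0 and v.std(axis=1).min() > 0:
            return make_matrix(v)


def random_recode_stable(rng, R, C) -> GenotypeMatrix:
    """Polymorphic matrix that stays polymorphic under rare1/common1 recoding
    (so all six PCA variants, including the standardized ones, are defined)."""
    from snppca import recode

    while True:
        m = random_polymorphic(rng, R, C)
        r1, _ = recode(m, "rare1")
        c1, _ = recode(m, "common1")
        ok = all(
            x.values.std(axis=0).min() > 0 and x.values.std(axis=1).min() > 0
            for x in (r1, c1)
        )
        if ok:
            return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy22():
    """The 2x2 identity-like toy whose DC interaction is 0.5*[[1,-1],[-1,1]]."""
    return make_matrix([[1, 0], [0, 1]])
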