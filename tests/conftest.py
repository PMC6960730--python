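import numpy as np
import pytest

from fiberpol import (
    MuellerMatrix,
    diagonal_depolarizer,
    diattenuator_from_vector,
    retarder_from_axis,
)


def random_unit_vector(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_factors(rng, d_max=0.9):
    """Random (depolarizer, retarder, diattenuator) triple, physical by
    construction: diagonal depolarizer with |a|,|b|,|c| <= 1, elliptical
    retarder, diattenuator with D <= d_max.

    Depolarizer coefficients carry one global sign (the +-PSD canonical
    family of the polar decomposition); mixed-sign diagonal depolarizers
    compose with a sign-flipped improper 'retarder' and are not uniquely
    recoverable."""
    abc = rng.choice([-1.0, 1.0]) * rng.uniform(0.05, 1.0, 3)
    m_delta = diagonal_depolarizer(*abc)
    m_r = retarder_from_axis(random_unit_vector(rng), rng.uniform(0.05, np.pi - 0.05))
    d = rng.uniform(0.0, d_max) * random_unit_vector(rng)
    m_d = diattenuator_from_vector(d)
    return m_delta, m_r, m_d


def random_physical_matrix(rng, d_max=0.9):
    m_delta, m_r, m_d = random_factors(rng, d_max)
    return MuellerMatrix(m_delta.m @ m_r.m @ m_d.m, normalized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
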