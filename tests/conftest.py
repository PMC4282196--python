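import numpy as np
import pytest

from dkivba import default_phantom, make_scheme
from dkivba.phantom import load_table2_fixture


@pytest.fixture(scope="session")
def scheme51():
    """The study acquisition: b = 0/1000/2000 s/mm^2, 25 directions/shell."""
    return make_scheme(25, [0, 1000, 2000])


@pytest.fixture(scope="session")
def fixture_table():
    return load_table2_fixture()


@pytest.fixture()
def small_phantom():
    """Noise-free 8^3 phantom for fast exact round trips."""
    return default_phantom(snr_b0=np.inf, grid=8, lesion_size=3)


def random_tensors(rng, n):
    """Random physiological (d6, w15) pairs: positive-definite D around
    1e-3 mm^2/s with a random orientation, kurtosis tensor as an isotropic
    base plus a small symmetric perturbation."""
    from scipy.stats import special_ortho_group

    from dkivba.dki import full_to_w15, matrix_to_d6, w15_to_full
    from dkivba.phantom import isotropic_w15

    d6 = np.empty((n, 6))
    w15 = np.empty((n, 15))
    for i in range(n):
        lam = np.sort(rng.uniform(0.3e-3, 2.0e-3, 3))[::-1]
        R = special_ortho_group.rvs(3, random_state=rng)
        d6[i] = matrix_to_d6(R @ np.diag(lam) @ R.T)
        base = w15_to_full(isotropic_w15(rng.uniform(0.5, 1.5)))
        pert = w15_to_full(rng.normal(0.0, 0.08, 15))
        w15[i] = full_to_w15(base + pert)
    return d6, w15
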