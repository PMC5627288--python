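import numpy as np
import pytest

import plexquant as pq


@pytest.fixture(scope="session")
def retina_design():
    return pq.default_design(("retina",))


@pytest.fixture(scope="session")
def small_truth(retina_design):
    """60-protein ground truth shared by identification/quant tests."""
    return pq.generate_ground_truth(
        n_proteins=60,
        frac_differential=0.2,
        fc_range=(1.5, 3.0),
        design=retina_design,
        biological_cv=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_plex_spectra(small_truth, retina_design):
    """Noise-free, interference-free, identity-impurity spectra of plex 1."""
    return pq.simulate_plex_spectra(
        small_truth,
        retina_design.plexes[0],
        impurity=pq.ImpurityMatrix.identity(),
        interference=0.0,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noisy_plex_spectra(small_truth, retina_design):
    """Spectra with impurity leakage, interference and additive noise."""
    return pq.simulate_plex_spectra(
        small_truth,
        retina_design.plexes[0],
        impurity=pq.ImpurityMatrix.default(),
        interference=("beta", 2.0, 18.0),
        noise_sd=2.0,
        seed=3,
    )


def random_impurity_matrix(rng: np.random.Generator, n: int = 10) -> "pq.ImpurityMatrix":
    """A random valid leakage matrix: strong diagonal, small off-diagonal."""
    M = np.zeros((n, n))
    for j in range(n):
        leak = {}
        for off in (-2, -1, 1, 2):
            if 0 <= j + off < n:
                leak[off] = rng.uniform(0, 0.03 if abs(off) == 1 else 0.003)
        M[j, j] = 1.0 - sum(leak.values()) - rng.uniform(0, 0.01)
        for off, v in leak.items():
            M[j + off, j] = v
    return pq.ImpurityMatrix(M, tuple(str(i) for i in range(n)))
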