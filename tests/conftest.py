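import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_spd(rng, n, lam_range=(-2.0, 2.0), max_cond=1e4):
    """Random SPD matrix with log-uniform spectrum and bounded condition."""
    lam = 10.0 ** rng.uniform(*lam_range, size=n)
    lam = np.sort(lam)
    if lam[-1] / lam[0] > max_cond:
        lam[0] = lam[-1] / max_cond
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    return q @ np.diag(lam) @ q.T


def random_symmetric(rng, n):
    x = rng.normal(size=(n, n))
    return x + x.T
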