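import numpy as np
import pytest

from multiskew import ReproductiveSample


@pytest.fixture
def rng():
    return np.random.default_rng(20201007)


def random_samples(rng, n_samples, equal_exposure=False, min_n=2, max_n=50,
                   max_total=500):
    """Random valid samples with R >= 1, for identity/property checks."""
    out = []
    while len(out) < n_samples:
        n = int(rng.integers(min_n, max_n + 1))
        t = np.ones(n) if equal_exposure else rng.uniform(0.05, 5.0, n)
        target_r = int(rng.integers(1, max_total + 1))
        rs = rng.multinomial(target_r, rng.dirichlet(np.ones(n)))
        if rs.sum() == 0:
            continue
        out.append(ReproductiveSample(rs, t))
    return out


@pytest.fixture
def monopolist():
    """One individual holds all reproduction, equal exposure."""
    return ReproductiveSample([4, 0, 0, 0])
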