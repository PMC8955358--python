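import numpy as np
import pytest

from cytobench import AssemblySpec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_spec():
    """A reduced library spec for fast end-to-end tests."""
    return AssemblySpec(
        replicates=2,
        si_targets=[-0.2, 0.2],
        alpha_grid=[10.0],
        base_seed=7,
    )


def random_spd(rng, dim=2, lo=0.5, hi=5.0):
    """Random SPD matrix for property tests (independent of the package's
    own random_covariance: eigendecomposition of a random Gram matrix)."""
    a = rng.normal(size=(dim, dim))
    gram = a @ a.T
    w, v = np.linalg.eigh(gram)
    w = lo + (hi - lo) * (w - w.min()) / max(w.max() - w.min(), 1e-12)
    return (v * w) @ v.T
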