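import numpy as np
import pytest

from promsig import BackgroundModel, FrequencyMatrix, SignatureModel, SpatialParams


@pytest.fixture(scope="session")
def bg():
    return BackgroundModel(gc=0.38)


from promsig import consensus_matrix  # noqa: F401  (fixture helper)


@pytest.fixture(scope="session")
def strong8(bg):
    """Well-specified, non-palindromic 8-bp motif for recovery fixtures."""
    return consensus_matrix("ACGGTAAC", 0.88)


@pytest.fixture(scope="session")
def medium6(bg):
    """Moderately specified 6-bp motif."""
    return consensus_matrix("ACGTTG", 0.76)


def make_model(matrix, bg, length=300, variant="multisite", **params):
    defaults = dict(rho=0.8, mu=100.0, omega=50.0, tau=0.5, lam=0.02)
    defaults.update(params)
    return SignatureModel(matrix=matrix, bg=bg,
                          params=SpatialParams(**defaults),
                          variant=variant, length=length)


def random_matrix(rng, w, concentration=0.7) -> FrequencyMatrix:
    return FrequencyMatrix(rng.dirichlet(np.ones(4) * concentration, size=w))


def random_small_model(rng, max_len=12, max_w=3):
    w = int(rng.integers(1, max_w + 1))
    L = int(rng.integers(max(w, 3), max_len + 1))
    params = SpatialParams(
        rho=float(rng.uniform(0, 1)), mu=float(rng.uniform(0, L)),
        omega=float(rng.uniform(1, L)), tau=float(rng.uniform(0, 1)),
        lam=float(rng.uniform(0.001, 0.3)), eta=float(rng.uniform(0.05, 1.0)))
    variant = "monosite" if rng.random() < 0.5 else "multisite"
    model = SignatureModel(matrix=random_matrix(rng, w),
                           bg=BackgroundModel(0.38), params=params,
                           variant=variant, length=L)
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return model, seq
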