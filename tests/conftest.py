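import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240122)


def random_psd(rng, n, rank=None):
    """Random symmetric PSD matrix with controllable rank."""
    rank = n if rank is None else rank
    b = rng.normal(size=(rank, n))
    return b.T @ b


def random_pd(rng, n):
    """Random well-conditioned symmetric positive definite matrix."""
    return random_psd(rng, n) + 0.5 * np.eye(n)


@pytest.fixture
def null_region(rng):
    """Genotype matrix plus a phenotype with no association (null data)."""
    from priorpart import GenotypeMatrix

    n, l = 300, 12
    maf = rng.uniform(0.05, 0.4, size=l)
    values = rng.binomial(2, maf, size=(n, l))
    values[:, values.std(axis=0) == 0] = rng.binomial(2, 0.3, size=(n,))[:, None]
    gm = GenotypeMatrix(
        values=values,
        variant_ids=[f"v{i}" for i in range(l)],
        positions=np.arange(1, l + 1) * 10,
    )
    y = rng.normal(size=n)
    return gm, y
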