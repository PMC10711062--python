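import numpy as np
import pytest

from meantarget import ConditionSpec, LoadingMatrix, build_population
from meantarget.fixtures import balanced_example_initial, crossloaded_population


@pytest.fixture
def balanced_example() -> LoadingMatrix:
    """18 x 3 orthogonal pattern with exactly zero block-mean cross-loadings."""
    return balanced_example_initial()


@pytest.fixture
def crossloaded() -> LoadingMatrix:
    """9 x 3 orthogonal population pattern with a shared positive cross block."""
    return crossloaded_population()


@pytest.fixture
def default_model():
    """A small correlated independent-clusters population (q=3, p/q=5)."""
    cond = ConditionSpec(
        q=3, p_per_q=5, loading_level=0.5, cross_loadings="zero", phi=0.25, n=500
    )
    return build_population(cond)


def random_orthogonal(rng: np.random.Generator, q: int) -> np.ndarray:
    """Haar-ish random orthogonal matrix via QR."""
    qmat, r = np.linalg.qr(rng.standard_normal((q, q)))
    return qmat * np.sign(np.diag(r))


def random_icm_loadings(
    rng: np.random.Generator, q: int = 3, ppq: int = 4, noise: float = 0.05
) -> LoadingMatrix:
    """A well-conditioned blockwise loading matrix with small random noise."""
    lam = np.kron(np.eye(q), rng.uniform(0.4, 0.7, size=(ppq, 1)))
    lam += noise * rng.standard_normal(lam.shape)
    return LoadingMatrix(lam)
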