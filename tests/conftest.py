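import numpy as np
import pytest

from privsvm import Hyperparams, KernelSpec, TrainingSet


def make_psd(rng: np.random.Generator, n: int, jitter: float = 0.0) -> np.ndarray:
    """Random symmetric PSD matrix (optionally strictly positive definite)."""
    A = rng.standard_normal((n, n))
    G = A @ A.T / n
    if jitter:
        G = G + jitter * np.eye(n)
    return G


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_two_point() -> tuple[TrainingSet, Hyperparams]:
    """The hand-solvable 2-sample linear problem: x = +-1, y = sign(x), C=10."""
    data = TrainingSet(
        X=np.array([[1.0], [-1.0]]),
        X_priv=None,
        pi_mask=np.zeros(2, dtype=bool),
        y=np.array([1, -1]),
    )
    hp = Hyperparams(
        C=10.0,
        kernel_main=KernelSpec(family="linear"),
        kernel_priv=KernelSpec(family="linear"),
    )
    return data, hp


@pytest.fixture
def small_lupi_set(rng) -> TrainingSet:
    """A small mixed-availability LUPI dataset for fit-level tests."""
    n, d, dt = 40, 4, 2
    t = rng.standard_normal((n, 2))
    X = np.hstack([t, np.zeros((n, d - 2))]) + 0.5 * rng.standard_normal((n, d))
    Xp = t @ rng.standard_normal((2, dt)) + 0.05 * rng.standard_normal((n, dt))
    y = np.where(t[:, 0] + t[:, 1] >= 0, 1, -1)
    y[0] = 1
    y[1] = -1  # both classes guaranteed
    mask = np.zeros(n, dtype=bool)
    mask[: n // 2] = True
    mask = mask[rng.permutation(n)]
    return TrainingSet(X=X, X_priv=Xp, pi_mask=mask, y=y)
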