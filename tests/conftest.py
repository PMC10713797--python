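import numpy as np
import pytest

from dsktl.spd import FeatureSet


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    a = rng.standard_normal((n, 2 * n))
    return scale * (a @ a.T / (2 * n) + 0.1 * np.eye(n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def labeled_features(rng) -> FeatureSet:
    """Separable two-class features: signal on column 0, noise elsewhere."""
    n, d = 60, 8
    y = np.repeat([1, 2], n // 2)
    x = rng.standard_normal((n, d))
    x[:, 0] += np.where(y == 1, 1.5, -1.5)
    return FeatureSet(x, labels=y)


def planted_features(seed: int, n: int = 100, n_dims: int = 10, n_informative: int = 3):
    """Two-class features where the first ``n_informative`` columns each
    carry an independent unit class signal at SNR 1 and the rest are pure
    noise."""
    r = np.random.default_rng(100 + seed)
    y = np.repeat([1, 2], n // 2)
    x = r.standard_normal((n, n_dims))
    sgn = np.where(y == 1, 1.0, -1.0)
    for j in range(n_informative):
        x[:, j] = sgn + r.standard_normal(n)
    return FeatureSet(x, labels=y)


def mefs_fista_oracle(x, y_onehot, laplacian, alpha, beta, gamma, n_iter=20000):
    """Independent first-order solver for the feature-selection objective:
    accelerated proximal gradient with exact row-wise group soft
    thresholding for the ℓ2,1 term."""
    import scipy.linalg

    n, d = x.shape
    c = y_onehot.shape[1]

    def smooth_val_grad(p, nu):
        resid = x @ nu - p
        val = (np.sum(resid**2) + alpha * np.trace(p.T @ laplacian @ p)
               + beta * np.sum((p - y_onehot) ** 2))
        gp = -2 * resid + 2 * alpha * laplacian @ p + 2 * beta * (p - y_onehot)
        gn = 2 * x.T @ resid
        return val, gp, gn

    hess = np.block([
        [2 * (alpha * laplacian + (beta + 1) * np.eye(n)), -2 * x],
        [-2 * x.T, 2 * x.T @ x],
    ])
    step = 1.0 / scipy.linalg.eigvalsh(hess)[-1]
    p = np.zeros((n, c))
    nu = np.zeros((d, c))
    pz, nz, t = p.copy(), nu.copy(), 1.0
    for _ in range(n_iter):
        _, gp, gn = smooth_val_grad(pz, nz)
        p_new = pz - step * gp
        nu_tmp = nz - step * gn
        norms = np.linalg.norm(nu_tmp, axis=1, keepdims=True)
        nu_new = nu_tmp * np.maximum(0.0, 1.0 - gamma * step / np.maximum(norms, 1e-30))
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        pz = p_new + (t - 1) / t_new * (p_new - p)
        nz = nu_new + (t - 1) / t_new * (nu_new - nu)
        p, nu, t = p_new, nu_new, t_new
    val, _, _ = smooth_val_grad(p, nu)
    return val + gamma * float(np.sum(np.linalg.norm(nu, axis=1)))
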