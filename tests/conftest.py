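import numpy as np
import pytest

from cellface import SynthConfig, generate_image


@pytest.fixture(scope="session")
def default_scene():
    """The default 500x500 low-contrast 20-cell scene, seed 42."""
    return generate_image(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_scene():
    """A quick 160x160 scene for pipeline tests."""
    return generate_image(
        SynthConfig(width=160, height=160, n_cells=6, radius_range=(8, 14), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_fcm(x, k, m, n_restarts=200, n_iter=120, seed=1234):
    """Independent fuzzy C-means oracle: best objective over random restarts.

    Written separately from the package (legacy RandomState stream, its own
    update formulation) so it can serve as a reference on tiny instances.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    rs = np.random.RandomState(seed)
    best_j = np.inf
    for _ in range(n_restarts):
        u = rs.rand(n, k)
        u = u / u.sum(axis=1, keepdims=True)
        for _ in range(n_iter):
            w = u**m  # (n, k)
            c = (w.T @ x) / w.sum(axis=0)[:, None]
            d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                inv = d2 ** (-1.0 / (m - 1.0))
                u = inv / inv.sum(axis=1, keepdims=True)
            for i in np.nonzero(~np.isfinite(u).all(axis=1))[0]:
                z = d2[i] == 0
                u[i] = z / z.sum()
        j_val = float((u**m * d2).sum())
        best_j = min(best_j, j_val)
    return best_j
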