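import numpy as np
import pytest

from trabec_bvtv import (
    CTModelParams,
    PhantomParams,
    generate_phantom,
    simulate_uct,
)


@pytest.fixture(scope="session")
def phantom_small():
    """64^3 mid-range phantom reused across read-only tests."""
    return generate_phantom(
        PhantomParams(target_bvtv=0.30, feature_scale=0.2, grid_shape=(64, 64, 64), seed=1)
    )


@pytest.fixture(scope="session")
def phantom_96():
    return generate_phantom(
        PhantomParams(target_bvtv=0.30, feature_scale=0.2, grid_shape=(96, 96, 96), seed=7)
    )


@pytest.fixture(scope="session")
def uct_clean_96(phantom_96):
    """Noiseless, unblurred microCT: a two-level image of the mask."""
    return simulate_uct(phantom_96, CTModelParams(psf_sigma=0.0, noise_sigma=0.0))


def procrustes_similarity(src: np.ndarray, dst: np.ndarray):
    """Closed-form least-squares similarity fit (Umeyama), used as the
    independent oracle for the registration module's linear solver."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / src.shape[0]
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, d])
    rot = u @ diag @ vt
    var_s = (xs**2).sum() / src.shape[0]
    scale = np.trace(np.diag(s) @ diag) / var_s
    t = mu_d - scale * rot @ mu_s
    return rot, float(scale), t
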