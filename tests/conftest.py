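import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import structdhi as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast landscape spec shared by raster-stage tests."""
    return sd.CouplingSpec(grid_rows=48, grid_cols=48, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_spec):
    return sd.generate_landscape(small_spec)


@pytest.fixture(scope="session")
def small_series(small_landscape, small_spec):
    return sd.generate_scene_series(small_landscape, small_spec)


def rda_oracle(X, Y):
    """Brute-force RDA oracle via the explicit hat-matrix projection.

    H = X (X'X)^-1 X' on centred X; eigendecomposition of
    (HY)'(HY)/(n-1) gives the canonical eigenvalues; R^2 is their sum
    over the total response variance.  Independent of the SVD route used
    by the implementation.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T
    F = H @ Yc
    C = F.T @ F / (n - 1)
    eig = np.linalg.eigvalsh(C)[::-1]
    eig = eig[eig > 1e-12 * max(eig.max(), 1.0)]
    total = (Yc**2).sum() / (n - 1)
    return eig, float(eig.sum() / total)


def partial_rda_oracle(X, Y, W):
    """Two-stage residual-projection oracle for partial RDA."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    W = np.asarray(W, float)
    n = X.shape[0]
    Wc = W - W.mean(axis=0)
    P = Wc @ np.linalg.pinv(Wc.T @ Wc) @ Wc.T
    R = np.eye(n) - P
    Xr = R @ (X - X.mean(axis=0))
    Yr = R @ (Y - Y.mean(axis=0))
    eig, _ = rda_oracle(Xr + Xr.mean(axis=0), Yr + Yr.mean(axis=0))
    Yc = Y - Y.mean(axis=0)
    total = (Yc**2).sum() / (n - 1)
    return eig, float(eig.sum() / total)
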