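import numpy as np
import pytest

from anchortm.anchor import build_anchor_design
from anchortm.basis import BasisSpec, default_support
from anchortm.tm_core import ResponseData


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def gaussian_linear_data(rng):
    """Exact Gaussian data from a known linear model with two anchors."""
    n, p, q = 200, 3, 2
    A = rng.normal(size=(n, q))
    H = A @ np.array([0.6, -0.4]) + rng.normal(size=n)
    X = A @ rng.normal(size=(q, p)) * 0.8 + H[:, None] + rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.25])
    y = 0.7 + X @ beta + 1.5 * H + A @ np.array([0.5, 0.5]) + rng.normal(size=n)
    return {"y": y, "X": X, "A": A, "H": H, "beta": beta}


@pytest.fixture
def lm_setup(gaussian_linear_data):
    d = gaussian_linear_data
    basis = BasisSpec("linear", support=default_support(d["y"]))
    return {
        "basis": basis,
        "data": ResponseData.from_exact(d["y"]),
        "X": d["X"],
        "design": build_anchor_design(d["A"]),
        **d,
    }


def tm_coefficients(model):
    """Convert a normal-linear TM fit back to (intercept, slopes, sigma)."""
    sigma = 1.0 / model.theta[1]
    intercept = -model.theta[0] * sigma
    slopes = model.beta * sigma
    return intercept, slopes, sigma
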