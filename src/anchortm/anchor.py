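"""Causal regularization: anchor projection and the distributional anchor loss.

The distributional anchor loss is

    L(theta, beta; xi) = -sum_i loglik_i / n + xi * ||Pi_A r||^2 / n,

with ``r`` the score-residual vector and ``Pi_A`` the orthogonal
projection onto the span of the centered, one-hot-encoded anchors.  For
the normal linear model this is equivalent to linear L2 anchor
regression with ``gamma = 2 xi + 1``, which is available in closed form
as a baseline (:func:`l2_anchor_fit`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .basis import BasisSpec, constrain_jacobian, constrain_theta, default_support
from .links import make_link
from .tm_core import (
    FitResult,
    LikelihoodParts,
    ResponseData,
    TransformationModel,
    _CaseValues,
    fit_mle,
)

__all__ = [
    "AnchorDesign",
    "AnchorFitResult",
    "build_anchor_design",
    "l2_anchor_fit",
    "anchor_loss",
    "fit_anchor_tm",
    "xi_path",
]

logger = logging.getLogger(__name__)


@dataclass
class AnchorDesign:
    """Centered, encoded anchors with their orthogonal projector.

    ``project(v)`` applies ``Pi_A`` through an orthonormal basis ``Q`` of
    the encoded column space (rank-deficient encodings are fine).
    """

    raw: pd.DataFrame = field(repr=False)
    encoded: np.ndarray = field(repr=False)
    columns: list[str]
    Q: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.encoded.shape[0]

    @property
    def rank(self) -> int:
        return self.Q.shape[1]

    def project(self, v: np.ndarray) -> np.ndarray:
        """Apply ``Pi_A`` to a vector or to the columns of a matrix."""
        return self.Q @ (self.Q.T @ np.asarray(v, dtype=float))

    def projector(self) -> np.ndarray:
        """Dense ``n x n`` projection matrix (tests and small problems only)."""
        return self.Q @ self.Q.T


def build_anchor_design(anchors) -> AnchorDesign:
    """Encode anchors (one-hot for categoricals), center, and build ``Pi_A``."""
    if isinstance(anchors, pd.Series):
        anchors = anchors.to_frame()
    if not isinstance(anchors, pd.DataFrame):
        arr = np.asarray(anchors)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        anchors = pd.DataFrame(arr, columns=[f"A{i + 1}" for i in range(arr.shape[1])])
    if anchors.shape[0] < 2:
        raise ValueError("anchor design requires at least two observations")
    enc = pd.get_dummies(anchors, dtype=float)
    M = enc.to_numpy(dtype=float)
    M = M - M.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(M, axis=0)
    if np.all(norms < 1e-12):
        raise ValueError("anchor has no variation after centering")
    # orthonormal column-space basis via SVD; tolerant to redundant columns
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    keep = s > max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    return AnchorDesign(raw=anchors, encoded=M, columns=list(enc.columns), Q=U[:, keep])


def l2_anchor_fit(y, X, design: AnchorDesign, gamma: float) -> np.ndarray:
    """Closed-form linear L2 anchor regression coefficients.

    Minimizes ``||(Id - Pi)(y - X b)||^2/n + gamma ||Pi (y - X b)||^2/n``
    by least squares on the transformed design
    ``W = Id - Pi + sqrt(gamma) Pi``.  ``gamma = 1`` is OLS; ``gamma = 0``
    partials out the anchors; large ``gamma`` approaches 2SLS.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    sg = np.sqrt(gamma)
    Wy = y - design.project(y) + sg * design.project(y)
    WX = X - design.project(X) + sg * design.project(X)
    coef, _, rank, _ = np.linalg.lstsq(WX, Wy, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular transformed design in l2_anchor_fit")
    return coef


@dataclass
class AnchorFitResult:
    xi: float
    model: TransformationModel
    nll: float
    penalty: float
    residuals: np.ndarray = field(repr=False)
    residual_anchor_corr: np.ndarray
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = np.nan
    message: str = ""
    free_params: np.ndarray | None = field(default=None, repr=False)

    @property
    def loss(self) -> float:
        return self.nll + self.penalty


def _loss_and_grad_free(z, link, basis, parts, design, xi, n):
    m = basis.dim
    theta = constrain_theta(basis, z[:m])
    beta = z[m:]
    cv = _CaseValues(link, parts, theta, beta)
    ll, g_theta, g_beta = cv.loglik_grad()
    J = constrain_jacobian(basis, z[:m])
    grad = np.concatenate([-(J.T @ g_theta), -g_beta]) / n
    value = -ll / n
    if xi > 0.0:
        r = cv.residuals()
        pr = design.project(r)
        value += xi * float(pr @ pr) / n
        Jr = cv.residual_jacobian()  # (n, m + p), d r / d (theta, beta)
        pen_grad = (2.0 * xi / n) * (pr @ Jr)
        pen_grad_free = np.concatenate([J.T @ pen_grad[:m], pen_grad[m:]])
        grad = grad + pen_grad_free
    return value, grad


def anchor_loss(model: TransformationModel, X, data, design: AnchorDesign, xi: float,
                with_grad: bool = False):
    """Distributional anchor loss at given parameters.

    Returns the scalar loss, or ``(loss, gradient)`` with the gradient
    taken with respect to the unconstrained ``(free_theta, beta)``
    parametrization when ``with_grad`` is true.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    if not isinstance(data, ResponseData):
        data = ResponseData.from_responses(data)
    n = len(data)
    X = np.zeros((n, 0)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    parts = LikelihoodParts(model.basis, X, data)
    from .basis import unconstrain_theta

    z = np.concatenate([unconstrain_theta(model.basis, model.theta), model.beta])
    value, grad = _loss_and_grad_free(z, model.link, model.basis, parts, design, xi, n)
    return (value, grad) if with_grad else value


def _result_from(link, basis, parts, design, data, xi, res, n, tol) -> AnchorFitResult:
    m = basis.dim
    theta = constrain_theta(basis, res.x[:m])
    beta = res.x[m:]
    model = TransformationModel(link, basis, theta, beta)
    cv = _CaseValues(link, parts, theta, beta)
    ll = cv.loglik().sum()
    r = cv.residuals()
    pr = design.project(r)
    penalty = xi * float(pr @ pr) / n
    corr = np.zeros(design.encoded.shape[1])
    r_c = r - r.mean()
    for j in range(design.encoded.shape[1]):
        a = design.encoded[:, j]
        denom = np.linalg.norm(a) * np.linalg.norm(r_c)
        corr[j] = float(a @ r_c / denom) if denom > 0 else 0.0
    _, grad = _loss_and_grad_free(res.x, link, basis, parts, design, xi, n)
    gnorm = float(np.max(np.abs(grad)))
    return AnchorFitResult(
        xi=float(xi),
        model=model,
        nll=float(-ll / n),
        penalty=float(penalty),
        residuals=r,
        residual_anchor_corr=corr,
        converged=gnorm <= tol,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        message=str(res.message),
        free_params=res.x.copy(),
    )


def fit_anchor_tm(
    link,
    basis: BasisSpec,
    X,
    data,
    design: AnchorDesign,
    xi: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init_free: np.ndarray | None = None,
) -> AnchorFitResult:
    """Minimize the distributional anchor loss at regularization ``xi``.

    At ``xi = 0`` the result coincides with :func:`~anchortm.tm_core.fit_mle`.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    if isinstance(link, str):
        link = make_link(link)
    if not isinstance(data, ResponseData):
        data = ResponseData.from_responses(data)
    if basis.is_continuous and basis.support is None:
        basis = basis.with_support(default_support(np.concatenate([data.lower, data.upper])))
    n = len(data)
    X = np.zeros((n, 0)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if design.n != n:
        raise ValueError(f"anchor design has {design.n} rows but data has {n}")
    parts = LikelihoodParts(basis, X, data)

    if init_free is None:
        mle = fit_mle(link, basis, X, data, tol=tol, max_iter=max_iter)
        init_free = mle.free_params
    z0 = np.asarray(init_free, dtype=float)
    res = optimize.minimize(
        _loss_and_grad_free,
        z0,
        args=(link, basis, parts, design, xi, n),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
    )
    tol_eff = tol * (1.0 + xi)  # the penalty scales the loss surface by xi
    _, grad = _loss_and_grad_free(res.x, link, basis, parts, design, xi, n)
    if float(np.max(np.abs(grad))) > tol_eff:
        polish = optimize.minimize(
            _loss_and_grad_free,
            res.x,
            args=(link, basis, parts, design, xi, n),
            jac=True,
            method="BFGS",
            options={"maxiter": 200, "gtol": 1e-9},
        )
        if polish.fun <= res.fun + 1e-12:
            res = polish
    out = _result_from(link, basis, parts, design, data, xi, res, n, tol_eff)
    if not out.converged:
        logger.warning("fit_anchor_tm(xi=%g) gradient norm %.3e above tolerance", xi, out.grad_norm)
    return out


def xi_path(link, basis, X, data, design, xi_grid, *, tol: float = 1e-6,
            max_iter: int = 1000) -> list[AnchorFitResult]:
    """Warm-started fits along an ascending grid of ``xi`` values."""
    xi_grid = list(xi_grid)
    if any(b < a for a, b in zip(xi_grid, xi_grid[1:])):
        raise ValueError("xi_grid must be sorted ascending")
    results: list[AnchorFitResult] = []
    init = None
    for xi in xi_grid:
        try:
            res = fit_anchor_tm(
                link, basis, X, data, design, xi, tol=tol, max_iter=max_iter, init_free=init
            )
            init = res.free_params
            results.append(res)
        except Exception as exc:  # record and continue the path
            logger.warning("xi_path fit failed at xi=%g: %s", xi, exc)
            results.append(exc)
    return results
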