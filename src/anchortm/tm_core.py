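"""Transformation-model likelihood, score residuals, fitting, prediction.

A transformation model is the triple (inverse link ``F_Z``, basis ``b``,
parameters ``(theta, beta)``) with conditional distribution

    F(y | x) = F_Z( b(y)' theta - x' beta ).

Responses may be exact, left-, right- or interval-censored (half-open
intervals ``(lower, upper]``), or ordinal; ordinal classes are treated as
interval censoring between adjacent thresholds.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .basis import (
    BasisSpec,
    constrain_jacobian,
    constrain_theta,
    default_support,
    evaluate_basis_deriv_matrix,
    evaluate_basis_matrix,
    unconstrain_theta,
)
from .links import InverseLink, make_link

__all__ = [
    "CensoredResponse",
    "ResponseData",
    "TransformationModel",
    "FitResult",
    "log_likelihood",
    "score_residual",
    "score_residuals",
    "fit_mle",
    "predict_cdf",
    "predict_quantile",
    "model_preset",
    "read_data",
]

logger = logging.getLogger(__name__)

TAGS = ("exact", "left", "right", "interval")


@dataclass(frozen=True)
class CensoredResponse:
    """A single response observation as a half-open interval ``(lower, upper]``.

    ``exact`` observations have ``lower == upper`` finite; ``left`` has
    ``lower = -inf``; ``right`` has ``upper = +inf``.  Ordinal responses
    carry a ``class_index`` in ``1..K`` instead of numeric bounds.
    """

    lower: float
    upper: float
    tag: str
    class_index: int | None = None

    def __post_init__(self) -> None:
        if self.tag not in TAGS and self.tag != "ordinal":
            raise ValueError(f"unknown censoring tag {self.tag!r}")
        if self.tag == "ordinal":
            if self.class_index is None or self.class_index < 1:
                raise ValueError("ordinal response requires class_index >= 1")
            return
        lo, hi = self.lower, self.upper
        if self.tag == "exact" and not (np.isfinite(lo) and lo == hi):
            raise ValueError("exact response requires finite lower == upper")
        if self.tag == "left" and not (lo == -np.inf and np.isfinite(hi)):
            raise ValueError("left censoring requires lower = -inf and finite upper")
        if self.tag == "right" and not (hi == np.inf):
            raise ValueError("right censoring requires upper = +inf")
        if self.tag == "interval" and not (lo < hi):
            raise ValueError("interval censoring requires lower < upper")

    @classmethod
    def exact(cls, y: float) -> "CensoredResponse":
        return cls(float(y), float(y), "exact")

    @classmethod
    def left(cls, upper: float) -> "CensoredResponse":
        return cls(-np.inf, float(upper), "left")

    @classmethod
    def right(cls, lower: float) -> "CensoredResponse":
        return cls(float(lower), np.inf, "right")

    @classmethod
    def interval(cls, lower: float, upper: float) -> "CensoredResponse":
        return cls(float(lower), float(upper), "interval")

    @classmethod
    def ordinal(cls, class_index: int) -> "CensoredResponse":
        return cls(np.nan, np.nan, "ordinal", class_index=int(class_index))


class ResponseData:
    """Column store of censored/ordinal responses for vectorized likelihoods."""

    def __init__(self, lower, upper, tags, class_index=None):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.tags = np.asarray(tags, dtype=object)
        self.class_index = None if class_index is None else np.asarray(class_index, dtype=int)
        if not (self.lower.shape == self.upper.shape == self.tags.shape):
            raise ValueError("response columns must have equal length")

    def __len__(self) -> int:
        return self.lower.size

    @property
    def is_ordinal(self) -> bool:
        return self.class_index is not None

    @classmethod
    def from_exact(cls, y) -> "ResponseData":
        y = np.asarray(y, dtype=float)
        return cls(y, y, np.full(y.shape, "exact", dtype=object))

    @classmethod
    def from_ordinal(cls, classes) -> "ResponseData":
        k = np.asarray(classes, dtype=int)
        nan = np.full(k.shape, np.nan)
        return cls(nan, nan, np.full(k.shape, "ordinal", dtype=object), class_index=k)

    @classmethod
    def from_responses(cls, responses) -> "ResponseData":
        responses = list(responses)
        if any(r.tag == "ordinal" for r in responses):
            if not all(r.tag == "ordinal" for r in responses):
                raise ValueError("cannot mix ordinal and continuous responses")
            return cls.from_ordinal([r.class_index for r in responses])
        return cls(
            [r.lower for r in responses],
            [r.upper for r in responses],
            np.array([r.tag for r in responses], dtype=object),
        )

    def __getitem__(self, idx) -> "ResponseData":
        return ResponseData(
            self.lower[idx],
            self.upper[idx],
            self.tags[idx],
            None if self.class_index is None else self.class_index[idx],
        )

    def to_responses(self):
        if self.is_ordinal:
            return [CensoredResponse.ordinal(k) for k in self.class_index]
        return [CensoredResponse(lo, hi, t) for lo, hi, t in zip(self.lower, self.upper, self.tags)]


@dataclass
class TransformationModel:
    """Fitted or hypothesized transformation model."""

    link: InverseLink
    basis: BasisSpec
    theta: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.theta.size != self.basis.dim:
            raise ValueError(
                f"theta has {self.theta.size} entries but the basis dimension is {self.basis.dim}"
            )

    def transformation(self, y, x=None, clamp: bool = True) -> np.ndarray:
        """Evaluate ``h(y | x) = b(y)' theta - x' beta``."""
        B = evaluate_basis_matrix(self.basis, np.atleast_1d(y), clamp=clamp)
        h = B @ self.theta
        if x is not None and self.beta.size:
            h = h - float(np.dot(np.atleast_1d(x), self.beta))
        return h


@dataclass
class FitResult:
    model: TransformationModel
    nll: float
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""
    free_params: np.ndarray | None = field(default=None, repr=False)


# -- internal likelihood engine ------------------------------------------------


class LikelihoodParts:
    """Precomputed design blocks for the four-case censored log-likelihood.

    Every observation is reduced to (optional) lower/upper latent bounds
    ``u = b(bound)' theta - x' beta``; ordinal classes become interval
    bounds between adjacent thresholds.
    """

    def __init__(self, basis: BasisSpec, X: np.ndarray, data: ResponseData, clamp: bool = False):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1) if X.size == len(data) else X.reshape(len(data), -1)
        if X.shape[0] != len(data):
            raise ValueError(f"X has {X.shape[0]} rows but there are {len(data)} responses")
        self.n = len(data)
        self.p = X.shape[1]
        self.m = basis.dim
        self.basis = basis

        if data.is_ordinal:
            if basis.kind != "ordinal":
                raise ValueError("ordinal responses require an ordinal basis")
            k = data.class_index
            K = basis.n_classes
            if np.any((k < 1) | (k > K)):
                raise ValueError(f"class labels must lie in 1..{K}")
            self.exact_idx = np.array([], dtype=int)
            self.cens_idx = np.arange(self.n)
            self.has_hi = k < K
            self.has_lo = k > 1
            B_hi = np.zeros((self.n, self.m))
            B_lo = np.zeros((self.n, self.m))
            B_hi[np.flatnonzero(self.has_hi), k[self.has_hi] - 1] = 1.0
            B_lo[np.flatnonzero(self.has_lo), k[self.has_lo] - 2] = 1.0
            self.B_hi, self.B_lo = B_hi, B_lo
            self.X_cens = X
            self.B_exact = np.zeros((0, self.m))
            self.Bp_exact = np.zeros((0, self.m))
            self.X_exact = np.zeros((0, self.p))
            self.order = np.arange(self.n)
            return

        tags = data.tags
        exact_mask = tags == "exact"
        self.exact_idx = np.flatnonzero(exact_mask)
        self.cens_idx = np.flatnonzero(~exact_mask)
        y_exact = data.lower[self.exact_idx]
        self.B_exact = (
            evaluate_basis_matrix(basis, y_exact, clamp=clamp)
            if self.exact_idx.size
            else np.zeros((0, self.m))
        )
        self.Bp_exact = (
            evaluate_basis_deriv_matrix(basis, y_exact, clamp=clamp)
            if self.exact_idx.size
            else np.zeros((0, self.m))
        )
        self.X_exact = X[self.exact_idx]

        lo = data.lower[self.cens_idx]
        hi = data.upper[self.cens_idx]
        self.has_lo = np.isfinite(lo)
        self.has_hi = np.isfinite(hi)
        nc = self.cens_idx.size
        B_lo = np.zeros((nc, self.m))
        B_hi = np.zeros((nc, self.m))
        if np.any(self.has_lo):
            B_lo[self.has_lo] = evaluate_basis_matrix(basis, lo[self.has_lo], clamp=clamp)
        if np.any(self.has_hi):
            B_hi[self.has_hi] = evaluate_basis_matrix(basis, hi[self.has_hi], clamp=clamp)
        self.B_lo, self.B_hi = B_lo, B_hi
        self.X_cens = X[self.cens_idx]
        # permutation restoring original observation order
        self.order = np.argsort(np.concatenate([self.exact_idx, self.cens_idx]), kind="stable")

    @property
    def informative(self) -> bool:
        if self.exact_idx.size:
            return True
        return bool(np.any(self.has_lo | self.has_hi))


def _interval_prob(link: InverseLink, u_lo, u_hi):
    """P(u_lo < Z <= u_hi), computed from whichever tail is better conditioned."""
    via_cdf = link.cdf(u_hi) - link.cdf(u_lo)
    via_sf = link.sf(u_lo) - link.sf(u_hi)
    return np.maximum(via_cdf, via_sf)


class _CaseValues:
    """Per-observation latent bounds and likelihood pieces at fixed parameters."""

    def __init__(self, link: InverseLink, parts: LikelihoodParts, theta, beta):
        self.link, self.parts = link, parts
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        shift_e = parts.X_exact @ beta if parts.p else np.zeros(parts.B_exact.shape[0])
        shift_c = parts.X_cens @ beta if parts.p else np.zeros(parts.B_hi.shape[0])
        self.u_exact = parts.B_exact @ theta - shift_e
        self.hprime = parts.Bp_exact @ theta
        self.u_lo = np.where(parts.has_lo, parts.B_lo @ theta - shift_c, -np.inf)
        self.u_hi = np.where(parts.has_hi, parts.B_hi @ theta - shift_c, np.inf)
        self.left = parts.has_hi & ~parts.has_lo
        self.right = parts.has_lo & ~parts.has_hi
        self.both = parts.has_lo & parts.has_hi
        self.neither = ~parts.has_lo & ~parts.has_hi

    def loglik(self) -> np.ndarray:
        """Per-observation log-likelihood contributions, in original order."""
        link = self.link
        ll_e = np.where(
            self.hprime > 0.0,
            link.log_pdf(self.u_exact) + np.log(np.maximum(self.hprime, 1e-300)),
            -np.inf,
        )
        if np.any(self.hprime <= 0.0):
            warnings.warn("non-positive transformation derivative at an exact observation", RuntimeWarning)
        ll_c = np.zeros(self.u_hi.size)
        ll_c[self.left] = link.log_cdf(self.u_hi[self.left])
        ll_c[self.right] = link.log_sf(self.u_lo[self.right])
        if np.any(self.both):
            pr = _interval_prob(link, self.u_lo[self.both], self.u_hi[self.both])
            with np.errstate(divide="ignore"):
                ll_c[self.both] = np.log(pr)
        return np.concatenate([ll_e, ll_c])[self.parts.order]

    def _weights(self):
        """d loglik / d u for the upper and lower bound of each censored row."""
        link = self.link
        w_hi = np.zeros(self.u_hi.size)
        w_lo = np.zeros(self.u_hi.size)
        w_hi[self.left] = np.exp(link.log_pdf(self.u_hi[self.left]) - link.log_cdf(self.u_hi[self.left]))
        w_lo[self.right] = -np.exp(link.log_pdf(self.u_lo[self.right]) - link.log_sf(self.u_lo[self.right]))
        if np.any(self.both):
            pr = _interval_prob(link, self.u_lo[self.both], self.u_hi[self.both])
            bad = pr <= 0.0
            if np.any(bad):
                raise FloatingPointError("zero-probability interval observation")
            w_hi[self.both] = link.pdf(self.u_hi[self.both]) / pr
            w_lo[self.both] = -link.pdf(self.u_lo[self.both]) / pr
        return w_hi, w_lo

    def loglik_grad(self):
        """Sum of contributions and its gradient w.r.t. (theta, beta)."""
        parts, link = self.parts, self.link
        ll = self.loglik()
        g = link.neg_dlogdens(self.u_exact)
        inv_hp = np.where(self.hprime > 0.0, 1.0 / np.maximum(self.hprime, 1e-300), 0.0)
        grad_theta = parts.B_exact.T @ (-g) + parts.Bp_exact.T @ inv_hp
        grad_beta = parts.X_exact.T @ g if parts.p else np.zeros(0)
        w_hi, w_lo = self._weights()
        grad_theta = grad_theta + parts.B_hi.T @ w_hi + parts.B_lo.T @ w_lo
        if parts.p:
            grad_beta = grad_beta - parts.X_cens.T @ (w_hi + w_lo)
        return ll.sum(), grad_theta, grad_beta

    def residuals(self) -> np.ndarray:
        """Score residuals, in original observation order."""
        r_e = self.link.neg_dlogdens(self.u_exact)
        w_hi, w_lo = self._weights()
        r_c = -(w_hi + w_lo)
        return np.concatenate([r_e, r_c])[self.parts.order]

    def residual_jacobian(self) -> np.ndarray:
        """d residual / d (theta, beta), an (n, m + p) matrix in original order."""
        parts, link = self.parts, self.link
        v_e = link.neg_dlogdens_prime(self.u_exact)
        Jr_e_theta = parts.B_exact * v_e[:, None]
        Jr_e_beta = -parts.X_exact * v_e[:, None] if parts.p else np.zeros((v_e.size, 0))

        w_hi, w_lo = self._weights()
        v_hi = np.zeros(self.u_hi.size)
        v_lo = np.zeros(self.u_hi.size)
        # left: r = -f/F, dr/du = t (g + t) with t = f/F = w_hi
        t = w_hi[self.left]
        v_hi[self.left] = t * (link.neg_dlogdens(self.u_hi[self.left]) + t)
        # right: r = f/S, dr/du = s (s - g) with s = f/S = -w_lo
        s = -w_lo[self.right]
        v_lo[self.right] = s * (s - link.neg_dlogdens(self.u_lo[self.right]))
        if np.any(self.both):
            pr = _interval_prob(link, self.u_lo[self.both], self.u_hi[self.both])
            r_b = -(w_hi[self.both] + w_lo[self.both])
            f_hi = link.pdf(self.u_hi[self.both])
            f_lo = link.pdf(self.u_lo[self.both])
            g_hi = link.neg_dlogdens(self.u_hi[self.both])
            g_lo = link.neg_dlogdens(self.u_lo[self.both])
            v_hi[self.both] = (f_hi / pr) * (g_hi - r_b)
            v_lo[self.both] = (f_lo / pr) * (r_b - g_lo)
        Jr_c_theta = parts.B_hi * v_hi[:, None] + parts.B_lo * v_lo[:, None]
        Jr_c_beta = (
            -parts.X_cens * (v_hi + v_lo)[:, None] if parts.p else np.zeros((v_hi.size, 0))
        )
        J = np.vstack([np.hstack([Jr_e_theta, Jr_e_beta]), np.hstack([Jr_c_theta, Jr_c_beta])])
        return J[parts.order]


# -- public single-observation API --------------------------------------------


def _single_parts(model: TransformationModel, response: CensoredResponse, x):
    x = np.zeros(0) if x is None else np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != model.beta.size:
        raise ValueError(f"covariate vector has length {x.size}, expected {model.beta.size}")
    data = ResponseData.from_responses([response])
    parts = LikelihoodParts(model.basis, x.reshape(1, -1), data)
    return _CaseValues(model.link, parts, model.theta, model.beta)


def log_likelihood(model: TransformationModel, response: CensoredResponse, x=None) -> float:
    """Log-likelihood contribution of one (possibly censored) observation."""
    return float(_single_parts(model, response, x).loglik()[0])


def score_residual(model: TransformationModel, response: CensoredResponse, x=None) -> float:
    """Score residual of one observation (closed form for all censoring types)."""
    return float(_single_parts(model, response, x).residuals()[0])


def score_residuals(model: TransformationModel, X, data: ResponseData) -> np.ndarray:
    """Vector of score residuals for a dataset.

    Responses outside the basis support (possible for held-out data) are
    clamped to the support boundary.
    """
    X = _as_matrix(X, len(data), model.beta.size)
    parts = LikelihoodParts(model.basis, X, data, clamp=True)
    return _CaseValues(model.link, parts, model.theta, model.beta).residuals()


def martingale_residuals(model: TransformationModel, X, data: ResponseData) -> np.ndarray:
    """Survival-convention residuals ``delta - Lambda_hat`` (mev link only)."""
    if model.link.name != "mev":
        raise ValueError("martingale residuals are defined for the mev link")
    return -score_residuals(model, X, data)


def _as_matrix(X, n, p):
    if X is None:
        return np.zeros((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape != (n, p):
        raise ValueError(f"X has shape {X.shape}, expected ({n}, {p})")
    return X


# -- fitting -------------------------------------------------------------------


def _nll_and_grad_free(z, link, basis, parts, n):
    m = basis.dim
    theta = constrain_theta(basis, z[:m])
    beta = z[m:]
    cv = _CaseValues(link, parts, theta, beta)
    ll, g_theta, g_beta = cv.loglik_grad()
    J = constrain_jacobian(basis, z[:m])
    grad = np.concatenate([-(J.T @ g_theta), -g_beta]) / n
    return -ll / n, grad


def _initial_free(link, basis, parts, data: ResponseData) -> np.ndarray:
    """Neutral starting values: evenly spaced latent quantiles for theta."""
    m = basis.dim
    probs = (np.arange(m) + 1.0) / (m + 1.0)
    theta0 = link.quantile(probs)
    if basis.kind == "linear":
        vals = data.lower[np.isfinite(data.lower)]
        if vals.size == 0:
            vals = data.upper[np.isfinite(data.upper)]
        mu = float(np.mean(vals)) if vals.size else 0.0
        sd = float(np.std(vals)) if vals.size else 1.0
        sd = sd if sd > 0 else 1.0
        theta0 = np.array([-mu / sd, 1.0 / sd])
    return unconstrain_theta(basis, theta0)


def fit_mle(
    link,
    basis: BasisSpec,
    X,
    data,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
    init_free: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of a transformation model.

    ``link`` may be an :class:`~anchortm.links.InverseLink` or a name.
    ``data`` is a :class:`ResponseData` (or list of responses); ``X`` the
    covariate matrix or ``None`` for an unconditional model.
    """
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
    p = X.shape[1]
    if n < basis.dim + p:
        raise ValueError(f"need at least {basis.dim + p} observations, got {n}")
    parts = LikelihoodParts(basis, X, data)
    if not parts.informative:
        raise ValueError("likelihood is constant: all responses are uninformative (-inf, +inf]")

    if init_free is None:
        free0 = _initial_free(link, basis, parts, data)
        # unconditional warm start for theta
        if p:
            parts0 = LikelihoodParts(basis, np.zeros((n, 0)), data)
            res0 = optimize.minimize(
                _nll_and_grad_free,
                free0,
                args=(link, basis, parts0, n),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
            free0 = res0.x
        z0 = np.concatenate([free0, np.zeros(p)])
    else:
        z0 = np.asarray(init_free, dtype=float)

    res = optimize.minimize(
        _nll_and_grad_free,
        z0,
        args=(link, basis, parts, n),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
    )
    _, grad = _nll_and_grad_free(res.x, link, basis, parts, n)
    gnorm = float(np.max(np.abs(grad)))
    if gnorm > tol:
        polish = optimize.minimize(
            _nll_and_grad_free,
            res.x,
            args=(link, basis, parts, n),
            jac=True,
            method="BFGS",
            options={"maxiter": 200, "gtol": 1e-9},
        )
        if polish.fun <= res.fun + 1e-12:
            res = polish
            _, grad = _nll_and_grad_free(res.x, link, basis, parts, n)
            gnorm = float(np.max(np.abs(grad)))
    converged = gnorm <= tol
    if not converged:
        logger.warning("fit_mle did not reach gradient tolerance: |grad| = %.3e", gnorm)
    m = basis.dim
    model = TransformationModel(link, basis, constrain_theta(basis, res.x[:m]), res.x[m:])
    return FitResult(
        model=model,
        nll=float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        message=str(res.message),
        free_params=res.x.copy(),
    )


# -- prediction ----------------------------------------------------------------


def predict_cdf(model: TransformationModel, y_grid, x=None) -> np.ndarray:
    """Conditional CDF ``F(y | x)`` on a response grid."""
    return np.asarray(model.link.cdf(model.transformation(y_grid, x)))


def predict_quantile(model: TransformationModel, p: float, x=None) -> float:
    """Conditional quantile: solves ``h(y | x) = F_Z^{-1}(p)`` by bisection."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    target = float(model.link.quantile(p))
    shift = float(np.dot(np.atleast_1d(x), model.beta)) if (x is not None and model.beta.size) else 0.0
    if model.basis.kind == "ordinal":
        thresholds = np.append(model.theta, np.inf)
        return int(np.argmax(thresholds - shift >= target) + 1)
    a, b = model.basis.support

    def fun(y):
        return float(model.transformation(np.array([y]), x)[0]) - target

    fa, fb = fun(a), fun(b)
    if fa >= 0.0:
        warnings.warn("requested quantile at or below the support boundary", RuntimeWarning)
        return a
    if fb <= 0.0:
        warnings.warn("requested quantile at or above the support boundary", RuntimeWarning)
        return b
    return float(optimize.bisect(fun, a, b, xtol=1e-8))


# -- presets (Lm / c-probit / c-logit / o-logit) -------------------------------


def model_preset(name: str, *, order: int = 6, n_classes: int | None = None,
                 support: tuple[float, float] | None = None):
    """Return (link, basis) for the four standard model families.

    ``lm``: probit link with a linear basis (normal linear regression);
    ``c-probit``/``c-logit``: smooth Bernstein transformation;
    ``o-logit``: proportional-odds ordinal regression.
    """
    key = name.lower().replace("_", "-")
    if key == "lm":
        return make_link("probit"), BasisSpec("linear", support=support)
    if key == "c-probit":
        return make_link("probit"), BasisSpec("bernstein", order=order, support=support)
    if key == "c-logit":
        return make_link("logit"), BasisSpec("bernstein", order=order, support=support)
    if key == "o-logit":
        if n_classes is None:
            raise ValueError("o-logit preset requires n_classes")
        return make_link("logit"), BasisSpec("ordinal", n_classes=n_classes)
    raise ValueError(f"unknown model preset {name!r}; expected lm, c-probit, c-logit or o-logit")


# -- delimited text ingestion --------------------------------------------------


def read_data(
    path_or_buf,
    *,
    response_lower: str = "response_lower",
    response_upper: str = "response_upper",
    censoring_col: str | None = "censoring",
    covariates: list[str] | None = None,
    anchors: list[str] | None = None,
    response_class: str | None = None,
    sep: str = ",",
):
    """Read (responses, X, A) from delimited text.

    Empty bound fields mean ``-inf`` (lower) / ``+inf`` (upper).  Ordinal
    responses use a single integer ``response_class`` column instead.
    Returns ``(ResponseData, X DataFrame or None, anchors DataFrame or None)``.
    """
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = _io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, sep=sep)
    if response_class is not None:
        data = ResponseData.from_ordinal(df[response_class].to_numpy())
    else:
        lo = pd.to_numeric(df[response_lower], errors="coerce").fillna(-np.inf).to_numpy()
        hi = pd.to_numeric(df[response_upper], errors="coerce").fillna(np.inf).to_numpy()
        if censoring_col is not None and censoring_col in df.columns:
            tags = df[censoring_col].astype(str).to_numpy()
        else:
            tags = np.where(
                np.isfinite(lo) & np.isfinite(hi) & (lo == hi),
                "exact",
                np.where(~np.isfinite(lo), "left", np.where(~np.isfinite(hi), "right", "interval")),
            )
        bad = set(np.unique(tags)) - set(TAGS)
        if bad:
            raise ValueError(f"unknown censoring tags in {censoring_col!r}: {sorted(bad)}")
        data = ResponseData(lo, hi, tags.astype(object))
    X = df[covariates] if covariates else None
    A = df[anchors] if anchors else None
    return data, X, A
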