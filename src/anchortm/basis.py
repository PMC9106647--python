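"""Response basis expansions and monotone reparametrization.

The transformation function of a model is ``h(y | x) = b(y)' theta - x' beta``
where ``b`` is one of three bases:

``linear``
    ``b(y) = (1, y)``; monotonicity means a positive slope.
``bernstein``
    The ``P + 1`` Bernstein polynomials of order ``P`` on a rescaled,
    bounded support; monotonicity means non-decreasing coefficients.
``ordinal``
    A dummy encoding of ``K`` ordered classes into ``K - 1`` free
    thresholds (the top threshold is implicitly ``+inf``); monotonicity
    means strictly increasing thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "BasisSpec",
    "evaluate_basis",
    "evaluate_basis_matrix",
    "evaluate_basis_deriv",
    "evaluate_basis_deriv_matrix",
    "reparametrize_monotone",
    "inverse_reparametrize",
    "monotone_jacobian",
    "default_support",
]

logger = logging.getLogger(__name__)

_KINDS = ("linear", "bernstein", "ordinal")


@dataclass(frozen=True)
class BasisSpec:
    """Specification of the response basis ``b(y)``.

    Parameters
    ----------
    kind : {"linear", "bernstein", "ordinal"}
    order : int, optional
        Polynomial order ``P >= 1`` (bernstein only).
    n_classes : int, optional
        Number of ordered classes ``K >= 2`` (ordinal only).
    support : (float, float), optional
        Finite response support ``(a, b)`` with ``a < b``
        (linear and bernstein).
    """

    kind: str
    order: int | None = None
    n_classes: int | None = None
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "bernstein":
            if self.order is None or self.order < 1:
                raise ValueError("bernstein basis requires integer order >= 1")
            self._check_support()
        elif self.kind == "linear":
            self._check_support()
        elif self.kind == "ordinal":
            if self.n_classes is None or self.n_classes < 2:
                raise ValueError("ordinal basis requires n_classes >= 2")

    def _check_support(self) -> None:
        if self.support is None:
            return
        a, b = self.support
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise ValueError(f"support must be a finite ordered pair, got {self.support}")

    @property
    def dim(self) -> int:
        """Number of basis functions / free threshold parameters."""
        if self.kind == "linear":
            return 2
        if self.kind == "bernstein":
            return self.order + 1
        return self.n_classes - 1

    @property
    def is_continuous(self) -> bool:
        return self.kind in ("linear", "bernstein")

    def with_support(self, support: tuple[float, float]) -> "BasisSpec":
        return BasisSpec(self.kind, self.order, self.n_classes, (float(support[0]), float(support[1])))

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.order is not None:
            d["order"] = int(self.order)
        if self.n_classes is not None:
            d["n_classes"] = int(self.n_classes)
        if self.support is not None:
            d["support"] = [float(self.support[0]), float(self.support[1])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        support = d.get("support")
        return cls(
            kind=d["kind"],
            order=d.get("order"),
            n_classes=d.get("n_classes"),
            support=tuple(support) if support is not None else None,
        )


def default_support(values: np.ndarray, margin: float = 0.05) -> tuple[float, float]:
    """Support covering all finite response bounds with a relative margin.

    Expands ``[min, max]`` of the finite values by ``margin`` times the
    range on each side (degenerate ranges fall back to a unit width).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite response values to build a support from")
    lo, hi = float(vals.min()), float(vals.max())
    rng = hi - lo
    if rng <= 0.0:
        rng = 1.0
    return lo - margin * rng, hi + margin * rng


def _require_support(spec: BasisSpec) -> tuple[float, float]:
    if spec.support is None:
        raise ValueError(f"{spec.kind} basis has no support set")
    return spec.support


def _check_outside(spec: BasisSpec, y: np.ndarray, clamp: bool) -> np.ndarray:
    a, b = _require_support(spec)
    outside = (y < a) | (y > b)
    if np.any(outside):
        if not clamp:
            raise ValueError(
                f"response value outside the basis support [{a}, {b}]: "
                f"{np.asarray(y)[outside][:5]}"
            )
        logger.warning(
            "extrapolating %d response value(s) beyond the support [%s, %s]",
            int(outside.sum()), a, b,
        )
    return outside


def _rescale(spec: BasisSpec, y: np.ndarray) -> np.ndarray:
    a, b = _require_support(spec)
    return (np.asarray(y, dtype=float) - a) / (b - a)


def evaluate_basis_matrix(spec: BasisSpec, y: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Evaluate ``b(y)`` row-wise for an array of responses.

    For ordinal specs ``y`` holds integer class labels in ``1..K``;
    class ``K`` maps to the all-zero row (its upper threshold is ``+inf``).
    With ``clamp=True``, Bernstein rows for responses outside the support
    continue the transformation *linearly* beyond the boundary,
    ``b(y) = b(a) + (y - a) b'(a)`` (and likewise above ``b``), so
    ``b(y)' theta`` stays monotone and finite for any response.
    """
    if spec.kind == "ordinal":
        k = np.asarray(y)
        kk = np.asarray(np.rint(k), dtype=int)
        if not np.allclose(k, kk):
            raise ValueError("ordinal responses must be integer class labels")
        if np.any((kk < 1) | (kk > spec.n_classes)):
            raise ValueError(f"class labels must lie in 1..{spec.n_classes}")
        out = np.zeros((kk.size, spec.dim))
        inner = kk < spec.n_classes
        out[np.flatnonzero(inner), kk[inner] - 1] = 1.0
        return out
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if spec.kind == "linear":
        a, b = _require_support(spec)
        if not clamp and (np.any(y < a) or np.any(y > b)):
            raise ValueError(f"response value outside the basis support [{a}, {b}]")
        return np.column_stack([np.ones_like(y), y])
    outside = _check_outside(spec, y, clamp)
    y_in = np.clip(y, *spec.support)
    t = _rescale(spec, y_in)
    P = spec.order
    j = np.arange(P + 1)
    # Bernstein polynomial of degree P == binomial pmf with success prob t
    B = binom.pmf(j[None, :], P, t[:, None])
    if np.any(outside):
        D = evaluate_basis_deriv_matrix(spec, y_in[outside])
        B[outside] = B[outside] + (y[outside] - y_in[outside])[:, None] * D
    return B


def evaluate_basis(spec: BasisSpec, y: float, clamp: bool = False) -> np.ndarray:
    """Evaluate the basis vector ``b(y)`` at a single response value."""
    return evaluate_basis_matrix(spec, np.atleast_1d(y), clamp=clamp)[0]


def evaluate_basis_deriv_matrix(spec: BasisSpec, y: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Row-wise derivative ``b'(y)`` for continuous bases."""
    if not spec.is_continuous:
        raise ValueError("basis derivative is undefined for ordinal bases")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if spec.kind == "linear":
        return np.column_stack([np.zeros_like(y), np.ones_like(y)])
    a, b = _require_support(spec)
    if clamp:
        # outside the support the extension is linear: constant derivative
        y = np.clip(y, a, b)
    elif np.any((y < a) | (y > b)):
        raise ValueError(f"response value outside the basis support [{a}, {b}]")
    t = _rescale(spec, y)
    P = spec.order
    j = np.arange(P + 1)
    lower = binom.pmf(j[None, :] - 1, P - 1, t[:, None])
    upper = binom.pmf(j[None, :], P - 1, t[:, None])
    return (P / (b - a)) * (lower - upper)


def evaluate_basis_deriv(spec: BasisSpec, y: float, clamp: bool = False) -> np.ndarray:
    return evaluate_basis_deriv_matrix(spec, np.atleast_1d(y), clamp=clamp)[0]


# -- monotone reparametrization ------------------------------------------------
#
# theta_1 = free_1, theta_{k+1} = theta_k + exp(free_{k+1}): strictly
# increasing coefficients from an unconstrained vector.  The linear basis
# instead needs only a positive slope, handled by `constrain_theta` below.


def reparametrize_monotone(free_params: np.ndarray) -> np.ndarray:
    """Map an unconstrained vector to strictly increasing coefficients."""
    free = np.asarray(free_params, dtype=float)
    theta = np.empty_like(free)
    theta[0] = free[0]
    if free.size > 1:
        theta[1:] = free[0] + np.cumsum(np.exp(free[1:]))
    return theta


def inverse_reparametrize(theta: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reparametrize_monotone`; requires strict increase."""
    theta = np.asarray(theta, dtype=float)
    diffs = np.diff(theta)
    if np.any(diffs <= 0.0):
        raise ValueError("coefficients must be strictly increasing to invert the reparametrization")
    free = np.empty_like(theta)
    free[0] = theta[0]
    free[1:] = np.log(diffs)
    return free


def monotone_jacobian(free_params: np.ndarray) -> np.ndarray:
    """Jacobian ``d theta / d free`` of :func:`reparametrize_monotone`."""
    free = np.asarray(free_params, dtype=float)
    m = free.size
    J = np.zeros((m, m))
    J[:, 0] = 1.0
    for j in range(1, m):
        J[j:, j] = np.exp(free[j])
    return J


def constrain_theta(spec: BasisSpec, free: np.ndarray) -> np.ndarray:
    """Basis-appropriate monotone map from unconstrained parameters.

    Linear bases constrain only the slope (``theta_2 = exp(free_2)``);
    bernstein and ordinal bases use the increasing reparametrization.
    """
    free = np.asarray(free, dtype=float)
    if spec.kind == "linear":
        return np.array([free[0], np.exp(free[1])])
    return reparametrize_monotone(free)


def unconstrain_theta(spec: BasisSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if spec.kind == "linear":
        if theta[1] <= 0.0:
            raise ValueError("linear basis requires a positive slope")
        return np.array([theta[0], np.log(theta[1])])
    return inverse_reparametrize(theta)


def constrain_jacobian(spec: BasisSpec, free: np.ndarray) -> np.ndarray:
    free = np.asarray(free, dtype=float)
    if spec.kind == "linear":
        return np.diag([1.0, np.exp(free[1])])
    return monotone_jacobian(free)
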