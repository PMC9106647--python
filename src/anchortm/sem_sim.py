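"""Structural-equation simulator for transformation models.

The generating process is

    A  <- eps_A                       (exogenous anchors)
    H  <- B_HH H + M_H A + eps_H      (hidden confounders)
    X  <- B_XX X + B_XH H + M_X A + eps_X
    Y  <- h^{-1}( Z + beta'X + B_YH H + M_Y A ),   Z ~ F_Z

with ``h(y) = b(y)' theta`` inverted by monotone bisection (ordinal
responses compare the shifted latent variable to the thresholds), or
alternatively a *direct* response equation ``Y = f(X) + B_YH H + M_Y A +
eps_Y`` for scenarios not generated from a transformation model.

Interventions replace the anchor law (``do``: a constant; ``push``: a
shifted/rescaled law) and leave every mechanism coefficient untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, evaluate_basis_matrix
from .links import make_link
from .tm_core import ResponseData

__all__ = [
    "ScenarioConfig",
    "SimData",
    "simulate",
    "scenario_preset",
    "apply_intervention",
    "bernstein_theta_from_function",
    "SCENARIO_NAMES",
    "STRUCTURAL_FUNCTIONS",
]

SCENARIO_NAMES = ("la", "nla", "iv1", "iv2")


def _nla_f(X: np.ndarray) -> np.ndarray:
    x2, x3 = X[:, 1], X[:, 2]
    return x2 + x3 + (x2 <= 0.0) + (x2 <= -0.5) * (x3 <= 1.0)


def _iv1_h(y: np.ndarray) -> np.ndarray:
    return 0.5 * y + 0.25 * y**3


STRUCTURAL_FUNCTIONS: dict = {"nla_f": _nla_f, "iv1_h": _iv1_h}


def bernstein_theta_from_function(h_fun, support, order: int) -> np.ndarray:
    """Bernstein coefficients fixing the transformation by evaluating an
    analytic ``h`` on ``order + 1`` evenly spaced support points."""
    if isinstance(h_fun, str):
        h_fun = STRUCTURAL_FUNCTIONS[h_fun]
    a, b = support
    grid = np.linspace(a, b, order + 1)
    theta = np.asarray(h_fun(grid), dtype=float)
    if np.any(np.diff(theta) <= 0):
        raise ValueError("transformation function must be strictly increasing on the support")
    return theta


@dataclass(frozen=True)
class ScenarioConfig:
    """All coefficients of a simulation scenario plus the seed.

    ``response_mode`` is ``"tm"`` (continuous via the transformation),
    ``"ordinal"`` (latent thresholding) or ``"direct"`` (explicit
    structural equation for ``Y`` with its own noise).
    """

    name: str
    p: int
    q: int
    d: int
    seed: int
    response_mode: str = "tm"
    beta: tuple = ()
    causal_fun: str | None = None  # direct mode: named f(X); None -> linear X beta
    B_XX: tuple = ()
    B_XH: tuple = ()
    B_HH: tuple = ()
    B_YH: tuple = ()
    M_X: tuple = ()
    M_H: tuple = ()
    M_Y: tuple = ()
    link_name: str = "probit"
    basis: BasisSpec | None = None
    theta: tuple = ()
    transform_fun: str | None = None  # tm mode: analytic h approximated on the basis
    noise_X: float = 1.0
    noise_H: float = 1.0
    noise_Y: float = 1.0  # direct mode only
    anchor_law: tuple = ("normal", 1.0)  # ("normal", scale) | ("binary", lo, hi)
    intervention: tuple | None = None  # ("do", value) | ("push", shift, scale)
    K: int | None = None
    n_train: int = 300
    n_test: int = 2000

    def _mat(self, name: str, shape) -> np.ndarray:
        value = getattr(self, name)
        arr = np.asarray(value, dtype=float)
        if arr.size == 0:
            return np.zeros(shape)
        arr = arr.reshape(shape)
        return arr

    def matrices(self) -> dict:
        p, q, d = self.p, self.q, self.d
        return {
            "B_XX": self._mat("B_XX", (p, p)),
            "B_XH": self._mat("B_XH", (p, d)),
            "B_HH": self._mat("B_HH", (d, d)),
            "B_YH": self._mat("B_YH", (1, d)),
            "M_X": self._mat("M_X", (p, q)),
            "M_H": self._mat("M_H", (d, q)),
            "M_Y": self._mat("M_Y", (1, q)),
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.basis is not None:
            d["basis"] = self.basis.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if d.get("basis") is not None:
            d["basis"] = BasisSpec.from_dict(d["basis"])
        for key in ("beta", "B_XX", "B_XH", "B_HH", "B_YH", "M_X", "M_H", "M_Y", "theta"):
            if key in d and d[key] is not None:
                d[key] = _freeze(np.asarray(d[key]))
        for key in ("anchor_law", "intervention"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _freeze(arr: np.ndarray) -> tuple:
    return tuple(map(tuple, arr)) if arr.ndim > 1 else tuple(arr.tolist())


@dataclass
class SimData:
    """A simulated dataset with its generating ground truth."""

    y: ResponseData
    X: np.ndarray
    H: np.ndarray
    A: np.ndarray
    y_numeric: np.ndarray  # continuous response values / ordinal classes
    truth: dict = field(default_factory=dict)
    n_rejected: int = 0


def _draw_anchors(config: ScenarioConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    law = config.anchor_law
    intervention = config.intervention
    if intervention is not None and intervention[0] == "do":
        value = np.broadcast_to(np.atleast_1d(np.asarray(intervention[1], dtype=float)), (config.q,))
        return np.tile(value, (n, 1))
    if law[0] == "normal":
        A = rng.normal(scale=float(law[1]), size=(n, config.q))
    elif law[0] == "binary":
        lo, hi = (float(law[1]), float(law[2])) if len(law) > 2 else (0.0, 1.0)
        A = np.where(rng.random(size=(n, config.q)) < 0.5, lo, hi)
    else:
        raise ValueError(f"unknown anchor law {law[0]!r}")
    if intervention is not None and intervention[0] == "push":
        shift = float(intervention[1])
        scale = float(intervention[2]) if len(intervention) > 2 else 1.0
        A = shift + scale * A
    return A


def _structural_draw(config: ScenarioConfig, n: int, rng: np.random.Generator):
    """One joint draw of (A, H, X, shift, Z-or-epsY) of size n."""
    mats = config.matrices()
    p, d = config.p, config.d
    A = _draw_anchors(config, n, rng)
    eps_H = rng.normal(scale=config.noise_H, size=(n, d))
    I_H = np.eye(d) - mats["B_HH"]
    H = np.linalg.solve(I_H, (A @ mats["M_H"].T + eps_H).T).T
    eps_X = rng.normal(scale=config.noise_X, size=(n, p))
    I_X = np.eye(p) - mats["B_XX"]
    X = np.linalg.solve(I_X, (H @ mats["B_XH"].T + A @ mats["M_X"].T + eps_X).T).T
    shift = (H @ mats["B_YH"].T + A @ mats["M_Y"].T).ravel()
    if config.response_mode == "direct":
        noise = rng.normal(scale=config.noise_Y, size=n)
    else:
        noise = make_link(config.link_name).sample(n, rng)
    return A, H, X, shift, noise


def _invert_bernstein(basis: BasisSpec, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Solve b(y)' theta = t for y by vectorized bisection (tol 1e-10)."""
    a, b = basis.support
    lo = np.full(t.shape, a)
    hi = np.full(t.shape, b)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        val = evaluate_basis_matrix(basis, mid) @ theta
        go_right = val < t
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
        if np.max(hi - lo) < 1e-10:
            break
    return 0.5 * (lo + hi)


def simulate(config: ScenarioConfig, n: int, seed: int | None = None) -> SimData:
    """Draw ``n`` observations from the scenario's structural equations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    beta = np.asarray(config.beta, dtype=float) if len(config.beta) else np.zeros(config.p)

    A, H, X, shift, noise = _structural_draw(config, n, rng)
    n_rejected = 0

    if config.response_mode == "direct":
        if config.causal_fun is not None:
            fX = STRUCTURAL_FUNCTIONS[config.causal_fun](X)
        else:
            fX = X @ beta
        y = fX + shift + noise
        data = ResponseData.from_exact(y)
        y_numeric = y
    elif config.response_mode == "ordinal":
        theta = np.asarray(config.theta, dtype=float)
        K = config.K
        if K is None or theta.size != K - 1:
            raise ValueError("ordinal scenario requires K and K-1 thresholds")
        t = noise + X @ beta + shift
        classes = np.searchsorted(theta, t, side="left") + 1  # class k iff theta_{k-1} < t <= theta_k
        y_numeric = classes.astype(float)
        data = ResponseData.from_ordinal(classes)
    else:  # continuous transformation model
        basis = config.basis
        if basis is None or not basis.is_continuous or basis.support is None:
            raise ValueError("tm scenario requires a continuous basis with support")
        if len(config.theta):
            theta = np.asarray(config.theta, dtype=float)
        elif config.transform_fun is not None and basis.kind == "bernstein":
            theta = bernstein_theta_from_function(config.transform_fun, basis.support, basis.order)
        else:
            raise ValueError("tm scenario requires theta or a named transform function")
        t = noise + X @ beta + shift
        if basis.kind == "bernstein":
            t_min, t_max = theta[0], theta[-1]
        else:  # linear transformation is unbounded
            t_min, t_max = -np.inf, np.inf
        bad = (t < t_min) | (t > t_max)
        for _ in range(100):
            if not np.any(bad):
                break
            k = int(bad.sum())
            n_rejected += k
            A2, H2, X2, shift2, noise2 = _structural_draw(config, k, rng)
            A[bad], H[bad], X[bad], shift[bad] = A2, H2, X2, shift2
            t[bad] = noise2 + X2 @ beta + shift2
            bad = (t < t_min) | (t > t_max)
        if np.any(bad) or n_rejected > 0.01 * n:
            raise RuntimeError(
                f"rejected {n_rejected} / {n} draws: latent values outside the "
                "transformation range; widen the support or rescale the scenario"
            )
        y_numeric = _invert_bernstein(basis, theta, t) if basis.kind == "bernstein" else (
            (t - theta[0]) / theta[1]
        )
        data = ResponseData.from_exact(y_numeric)
        theta_out = theta

    truth = {
        "beta": beta,
        "causal_fun": config.causal_fun,
        "blocks": {k: v for k, v in config.matrices().items()},
        "link": config.link_name,
    }
    if config.response_mode != "direct":
        truth["theta"] = np.asarray(config.theta, dtype=float) if len(config.theta) else (
            theta_out if config.response_mode == "tm" else None
        )
    return SimData(y=data, X=X, H=H, A=A, y_numeric=np.asarray(y_numeric, dtype=float),
                   truth=truth, n_rejected=n_rejected)


def apply_intervention(config: ScenarioConfig, kind: str, value) -> ScenarioConfig:
    """Return a copy of the scenario with a ``do``/``push`` intervention set."""
    if kind == "none":
        return dataclasses.replace(config, intervention=None)
    if kind == "do":
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size not in (1, config.q):
            raise ValueError(f"do-intervention value must have 1 or q={config.q} entries")
        return dataclasses.replace(config, intervention=("do", float(arr[0]) if arr.size == 1 else tuple(arr)))
    if kind == "push":
        if np.isscalar(value):
            return dataclasses.replace(config, intervention=("push", float(value), 1.0))
        shift, scale = value
        return dataclasses.replace(config, intervention=("push", float(shift), float(scale)))
    raise ValueError(f"unknown intervention kind {kind!r}")


def _la_skeleton(seed: int, name: str) -> dict:
    """Shared coefficients of the la / nla scenarios.

    The published table body for these scenarios is not available, so the
    blocks below are documented defaults reproducing the qualitative
    regime: two continuous anchors driving covariates, confounder and
    response; one hidden confounder feeding both X and Y; two active
    covariates (indices 2 and 3) and eight noise covariates.
    """
    p, q, d = 10, 2, 1
    coef_rng = np.random.default_rng(20220513)  # fixed: part of the scenario definition
    M_X = np.round(coef_rng.uniform(-1.0, 1.0, size=(p, q)), 2)
    beta = np.zeros(p)
    beta[1] = beta[2] = 1.0
    return dict(
        name=name,
        p=p,
        q=q,
        d=d,
        seed=seed,
        response_mode="direct",
        beta=_freeze(beta),
        B_XH=_freeze(np.ones((p, d))),
        B_YH=_freeze(np.full((1, d), 1.0)),
        M_X=_freeze(M_X),
        M_H=_freeze(np.full((d, q), 1.0)),
        M_Y=_freeze(np.full((1, q), 1.0)),
        link_name="probit",
        anchor_law=("normal", 1.0),
        n_train=300,
        n_test=2000,
    )


def scenario_preset(name: str, seed: int = 1, **overrides) -> ScenarioConfig:
    """Built-in scenario configurations.

    ``la``
        Linear Gaussian SEM; anchors influence Y, X and H; 8 of the 10
        covariates are noise (beta_j = 0 for j != 2, 3); n_train 300.
    ``nla``
        Same skeleton with the non-linear causal function
        f(X) = X2 + X3 + 1(X2<=0) + 1(X2<=-0.5)1(X3<=1); fit with c-probit.
    ``iv1``
        Binary anchors as valid instruments (M_H = M_Y = 0), continuous
        response generated from a c-probit model with an order-6
        Bernstein transformation; n_train 1000; default test
        intervention do(A = 3.6).
    ``iv2``
        Ordinal response (default K = 10), valid instruments with
        strength M_X in {0.5, 2}, beta = 0.5; interventions
        do(A in {1, 1.8, 3}); n_train 1000.
    """
    if name == "la":
        cfg = _la_skeleton(seed, "la")
    elif name == "nla":
        cfg = _la_skeleton(seed, "nla")
        cfg.update(name="nla", causal_fun="nla_f", beta=())
    elif name == "iv1":
        support = (-6.0, 6.0)
        cfg = dict(
            name="iv1",
            p=1,
            q=1,
            d=1,
            seed=seed,
            response_mode="tm",
            beta=(1.0,),
            B_XH=((1.0,),),
            B_YH=((1.0,),),
            M_X=((1.0,),),
            link_name="probit",
            basis=BasisSpec("bernstein", order=6, support=support),
            transform_fun="iv1_h",
            anchor_law=("binary", 0.0, 1.0),
            n_train=1000,
            n_test=2000,
        )
    elif name == "iv2":
        K = int(overrides.pop("K", 10))
        M_X = float(overrides.pop("instrument_strength", 0.5))
        cfg = dict(
            name="iv2",
            p=1,
            q=1,
            d=1,
            seed=seed,
            response_mode="ordinal",
            beta=(0.5,),
            B_XH=((1.0,),),
            B_YH=((1.0,),),
            M_X=((M_X,),),
            link_name="logit",
            theta=_freeze(np.linspace(-4.0, 4.0, K - 1)),
            K=K,
            anchor_law=("normal", 1.0),
            n_train=1000,
            n_test=2000,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    cfg.update(overrides)
    return ScenarioConfig(**cfg)
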