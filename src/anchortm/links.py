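"""Inverse-link distributions on the latent scale.

Each link is a fixed, parameter-free distribution ``F_Z`` with log-concave
density.  Censored likelihood contributions need ``log F_Z`` and
``log(1 - F_Z)`` far in the tails, so every quantity is available on the
log scale via scipy's distribution machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import gumbel_l, logistic, norm

__all__ = ["InverseLink", "make_link", "neg_dlogdens", "LINK_NAMES"]

LINK_NAMES = ("probit", "logit", "mev")


@dataclass(frozen=True)
class InverseLink:
    """A fixed latent distribution ``F_Z`` with the derivatives the
    likelihood, score residuals, and penalty gradients need.

    ``neg_dlogdens(z)`` is ``-f'(z) / f(z)`` and ``neg_dlogdens_prime``
    its derivative; both are analytic for the three supported links.
    """

    name: str
    _dist: object = field(repr=False)

    def cdf(self, z):
        return self._dist.cdf(z)

    def log_cdf(self, z):
        return self._dist.logcdf(z)

    def sf(self, z):
        return self._dist.sf(z)

    def log_sf(self, z):
        return self._dist.logsf(z)

    def pdf(self, z):
        return self._dist.pdf(z)

    def log_pdf(self, z):
        return self._dist.logpdf(z)

    def quantile(self, p):
        return self._dist.ppf(p)

    def sample(self, size, rng: np.random.Generator):
        return self._dist.rvs(size=size, random_state=rng)

    def neg_dlogdens(self, z):
        z = np.asarray(z, dtype=float)
        if self.name == "probit":
            return z
        if self.name == "logit":
            return 2.0 * expit(z) - 1.0
        return np.expm1(z)

    def neg_dlogdens_prime(self, z):
        z = np.asarray(z, dtype=float)
        if self.name == "probit":
            return np.ones_like(z)
        if self.name == "logit":
            return 2.0 * logistic.pdf(z)
        return np.exp(z)

    def pdf_prime(self, z):
        return -self.neg_dlogdens(z) * self.pdf(z)


_DISTS = {"probit": norm, "logit": logistic, "mev": gumbel_l}


def make_link(name: str) -> InverseLink:
    """Return the inverse link by name.

    probit -> standard normal; logit -> standard logistic;
    mev -> minimum extreme value, ``F(z) = 1 - exp(-exp(z))``.
    """
    try:
        dist = _DISTS[name]
    except KeyError:
        raise ValueError(f"unknown link {name!r}; supported links: {sorted(_DISTS)}") from None
    return InverseLink(name=name, _dist=dist)


def neg_dlogdens(link: InverseLink, z):
    """Module-level alias for ``link.neg_dlogdens(z)``."""
    return link.neg_dlogdens(z)
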