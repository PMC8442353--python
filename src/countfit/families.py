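"""Log-probability kernels for the count-data families.

Three base densities share the log-link conditional mean ``mu = exp(x'beta)``:

``poisson``
    Equidispersed: ``V[y|x] = mu``.
``nb2``
    Negative binomial with quadratic variance ``V[y|x] = mu + alpha*mu**2``
    (gamma heterogeneity; shape ``1/alpha``).
``nb1``
    Negative binomial with linear variance ``V[y|x] = mu*(1 + alpha)``,
    parameterised as a negative binomial with shape ``mu/alpha`` and success
    probability ``1/(1 + alpha)``.

Hurdle, zero-inflated and latent-class families are composed from these
kernels (plus a logit zero part) in :mod:`countfit.model`.  The gradient
helpers return derivatives with respect to ``eta = log(mu)`` and
``log(alpha)``, the unconstrained scales used by the optimizer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

BASE_FAMILIES = ("poisson", "nb1", "nb2")

#: hurdle family -> base density of its positive (zero-truncated) part
HURDLE_FAMILIES = {
    "hurdle_poisson": "poisson",
    "hurdle_nb1": "nb1",
    "hurdle_nb2": "nb2",
}

#: zero-inflated family -> base density of its count part
ZI_FAMILIES = {"zip": "poisson", "zinb2": "nb2"}

FAMILIES = BASE_FAMILIES + tuple(HURDLE_FAMILIES) + tuple(ZI_FAMILIES) + ("lcnb2",)


def _log1mexp(x: np.ndarray) -> np.ndarray:
    """log(1 - exp(x)) for x < 0, numerically stable in both regimes."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x > -np.log(2.0), np.log(-np.expm1(x)), np.log1p(-np.exp(x)))


def _validate(family: str, mu, alpha):
    if family not in BASE_FAMILIES:
        raise ValueError(f"unknown base count family {family!r}; expected one of {BASE_FAMILIES}")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    if family != "poisson":
        if alpha is None:
            raise ValueError(f"{family} requires a dispersion parameter alpha")
        if not np.isscalar(alpha) and np.ndim(alpha) != 0:
            raise ValueError("alpha must be a scalar")
        if not (alpha > 0):
            raise ValueError("alpha must be > 0")
    return mu


def _validate_y(y, minimum: int = 0) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isfinite(np.asarray(y, dtype=float))):
        raise ValueError("y must be finite")
    if np.any(np.asarray(y) != np.floor(np.asarray(y, dtype=float))):
        raise ValueError("y must contain integers")
    y = np.asarray(y, dtype=float)
    if np.any(y < minimum):
        raise ValueError(f"y must be >= {minimum}")
    return y


def count_logpmf(family: str, y, mu, alpha: float | None = None) -> np.ndarray:
    """Log pmf of a base count density at ``y`` with mean ``mu``.

    Parameters
    ----------
    family : {'poisson', 'nb1', 'nb2'}
    y : array_like of non-negative integers
    mu : array_like of positive means
    alpha : float, optional
        Dispersion, required (and > 0) for the negative-binomial families.
    """
    y = _validate_y(y)
    mu = _validate(family, mu, alpha)
    if family == "poisson":
        return y * np.log(mu) - mu - gammaln(y + 1)
    if family == "nb2":
        r = 1.0 / alpha
        return (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu))
        )
    # nb1: shape mu/alpha, success prob 1/(1+alpha)
    r = mu / alpha
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        - r * np.log1p(alpha)
        + y * (np.log(alpha) - np.log1p(alpha))
    )


def count_logp0(family: str, mu, alpha: float | None = None) -> np.ndarray:
    """Log probability of a zero count under a base density."""
    mu = _validate(family, mu, alpha)
    if family == "poisson":
        return -mu
    if family == "nb2":
        r = 1.0 / alpha
        return r * (np.log(r) - np.log(r + mu))
    return -(mu / alpha) * np.log1p(alpha)


def truncated_logpmf(family: str, y, mu, alpha: float | None = None) -> np.ndarray:
    """Log pmf of the zero-truncated base density: f(y)/(1 - f(0)), y >= 1."""
    y = _validate_y(y, minimum=1)
    ll = count_logpmf(family, y, mu, alpha)
    return ll - _log1mexp(count_logp0(family, mu, alpha))


def zero_prob_logit(z, gamma) -> np.ndarray:
    """Probability of a zero count from a logit zero part.

    Follows the convention that the linear predictor models the probability
    of *zero*: ``Pr(y=0|z) = exp(z'gamma)/(1 + exp(z'gamma))``, so a larger
    linear predictor means a larger zero probability.
    """
    z = np.asarray(z, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    return expit(z @ gamma)


# ---------------------------------------------------------------------------
# gradient helpers (used by the fitters; derivatives wrt eta and log alpha)
# ---------------------------------------------------------------------------


def _count_ll_grad(family, y, mu, alpha, truncated=False):
    """Return (ll, d ll/d eta, d ll/d log alpha) per observation.

    The log-alpha derivative is ``None`` for the Poisson.  ``truncated``
    adds the zero-truncation term - log(1 - f(0)).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if family == "poisson":
        ll = y * np.log(mu) - mu - gammaln(y + 1)
        deta = y - mu
        dloga = None
    elif family == "nb2":
        r = 1.0 / alpha
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu))
        )
        deta = y - mu * (y + r) / (r + mu)
        dll_dr = (
            digamma(y + r) - digamma(r) + np.log(r) - np.log(r + mu) + (mu - y) / (r + mu)
        )
        dloga = -r * dll_dr
    elif family == "nb1":
        r = mu / alpha
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            - r * np.log1p(alpha)
            + y * (np.log(alpha) - np.log1p(alpha))
        )
        d = digamma(y + r) - digamma(r) - np.log1p(alpha)
        deta = r * d
        dloga = -r * d + y - (y + r) * alpha / (1.0 + alpha)
    else:  # pragma: no cover
        raise ValueError(family)

    if truncated:
        logp0, p0_deta, p0_dloga = _logp0_grad(family, mu, alpha)
        log1m = _log1mexp(logp0)
        c = np.exp(logp0 - log1m)  # p0 / (1 - p0)
        ll = ll - log1m
        deta = deta + c * p0_deta
        if dloga is not None:
            dloga = dloga + c * p0_dloga
    return ll, deta, dloga


def _logp0_grad(family, mu, alpha):
    """Return (log f(0), d/d eta, d/d log alpha) for a base density."""
    mu = np.asarray(mu, dtype=float)
    if family == "poisson":
        return -mu, -mu, None
    if family == "nb2":
        r = 1.0 / alpha
        logp0 = r * (np.log(r) - np.log(r + mu))
        deta = -r * mu / (r + mu)
        dlogp0_dr = np.log(r) - np.log(r + mu) + mu / (r + mu)
        dloga = -r * dlogp0_dr
        return logp0, deta, dloga
    if family == "nb1":
        r = mu / alpha
        logp0 = -r * np.log1p(alpha)
        deta = -r * np.log1p(alpha)
        dloga = r * np.log1p(alpha) - r * alpha / (1.0 + alpha)
        return logp0, deta, dloga
    raise ValueError(family)  # pragma: no cover
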