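"""Maximum-likelihood estimation of the nine count-regression families.

The user-facing objects follow the statsmodels idiom: a :class:`CountModel`
is built from a :class:`~countfit.data.CountDataset` (or a DataFrame) and a
family name; ``fit()`` returns a :class:`CountResults` carrying estimates,
observed-information standard errors, the maximized log-likelihood, the
free-parameter count and prediction methods.

Families
--------
``poisson``, ``nb1``, ``nb2``
    One-part models with log-link mean.
``hurdle_poisson``, ``hurdle_nb1``, ``hurdle_nb2``
    Logit zero part (modelling Pr(y = 0)) plus a zero-truncated count part
    on the positives; the joint likelihood factorizes, so the two parts are
    maximized separately and their log-likelihoods added.
``zip``, ``zinb2``
    Logit structural-zero part mixed with the count density; zeros arise
    from both processes.
``lcnb2``
    Finite mixture of NB2 densities fitted by EM with random restarts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from ._optimize import (
    DesignScaler,
    FitSettings,
    OptResult,
    cov_from_hessian,
    hessian_from_grad,
    minimize_nll,
)
from .data import CountDataset
from .families import (
    BASE_FAMILIES,
    FAMILIES,
    HURDLE_FAMILIES,
    ZI_FAMILIES,
    _count_ll_grad,
    _log1mexp,
    _logp0_grad,
    count_logp0,
    count_logpmf,
    truncated_logpmf,
    zero_prob_logit,
)

_ETA_CLIP = 30.0
_LOGA_CLIP = 15.0
_PENALTY = 1e12


class DegenerateDataError(ValueError):
    """Raised when the outcome cannot identify the requested family."""


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit and has none."""


@dataclass
class ModelSpec:
    """A model family plus its estimation options."""

    family: str
    n_classes: int = 2
    settings: FitSettings = field(default_factory=FitSettings)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


# ---------------------------------------------------------------------------
# observation-level log-likelihood at arbitrary (natural-scale) parameters
# ---------------------------------------------------------------------------


def _require(params, key, family):
    if key not in params or params[key] is None:
        raise ValueError(f"family {family!r} requires parameter block {key!r}")
    return params[key]


def loglikeobs(family: str, params: dict, dataset: CountDataset) -> np.ndarray:
    """Per-row log-probability of the observed counts at given parameters.

    ``params`` uses natural-scale blocks: ``beta`` (count part, aligned with
    ``dataset.xnames``), ``gamma`` (zero part, aligned with ``znames``),
    ``alpha`` (dispersion), and for the latent-class family ``pi``,
    ``class_beta`` and ``class_alpha``.
    """
    y, X, Z = dataset.y, dataset.X, dataset.Z
    yf = y.astype(float)
    if family in BASE_FAMILIES:
        beta = np.asarray(_require(params, "beta", family), dtype=float)
        mu = np.exp(X @ beta)
        ll = count_logpmf(family, yf, mu, params.get("alpha"))
    elif family in HURDLE_FAMILIES:
        base = HURDLE_FAMILIES[family]
        beta = np.asarray(_require(params, "beta", family), dtype=float)
        gamma = np.asarray(_require(params, "gamma", family), dtype=float)
        v = Z @ gamma
        mu = np.exp(X @ beta)
        ll = np.where(y == 0, log_expit(v), 0.0)
        pos = y > 0
        if np.any(pos):
            ll_pos = log_expit(-v[pos]) + truncated_logpmf(
                base, yf[pos], mu[pos], params.get("alpha")
            )
            ll = ll.copy()
            ll[pos] = ll_pos
    elif family in ZI_FAMILIES:
        base = ZI_FAMILIES[family]
        beta = np.asarray(_require(params, "beta", family), dtype=float)
        gamma = np.asarray(_require(params, "gamma", family), dtype=float)
        v = Z @ gamma
        mu = np.exp(X @ beta)
        logp0 = count_logp0(base, mu, params.get("alpha"))
        ll_zero = np.logaddexp(log_expit(v), log_expit(-v) + logp0)
        ll_pos = log_expit(-v) + count_logpmf(base, np.maximum(yf, 1.0), mu, params.get("alpha"))
        ll = np.where(y == 0, ll_zero, ll_pos)
    elif family == "lcnb2":
        pi = np.asarray(_require(params, "pi", family), dtype=float)
        betas = _require(params, "class_beta", family)
        alphas = _require(params, "class_alpha", family)
        M = np.empty((dataset.n, pi.size))
        for c in range(pi.size):
            mu_c = np.exp(X @ np.asarray(betas[c], dtype=float))
            M[:, c] = np.log(pi[c]) + count_logpmf("nb2", yf, mu_c, alphas[c])
        ll = logsumexp(M, axis=1)
    else:
        raise ValueError(f"unknown family {family!r}")

    if not np.all(np.isfinite(ll)):
        bad = np.flatnonzero(~np.isfinite(ll))[:10]
        raise ValueError(f"non-finite log-likelihood terms at rows {bad.tolist()}")
    return ll


def model_loglik(family: str, params: dict, dataset: CountDataset) -> float:
    """Total log-likelihood of a family at given natural-scale parameters."""
    return float(loglikeobs(family, params, dataset).sum())


# ---------------------------------------------------------------------------
# scaled-space objectives
# ---------------------------------------------------------------------------


def _count_theta(theta, family, p):
    beta = theta[:p]
    alpha = None
    if family != "poisson":
        alpha = float(np.exp(np.clip(theta[p], -_LOGA_CLIP, _LOGA_CLIP)))
    return beta, alpha


def _nll_count(theta, family, y, Xs, weights=None, truncated=False):
    """Negative (weighted) log-likelihood and gradient for a base density."""
    p = Xs.shape[1]
    beta, alpha = _count_theta(theta, family, p)
    eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll, deta, dloga = _count_ll_grad(family, y, mu, alpha, truncated=truncated)
    w = weights if weights is not None else 1.0
    nll = -float(np.sum(w * ll))
    if not np.isfinite(nll):
        return _PENALTY, np.zeros_like(theta)
    grad = np.empty_like(theta)
    grad[:p] = -(Xs.T @ (w * deta))
    if family != "poisson":
        grad[p] = -float(np.sum(w * dloga))
    return nll, grad


def _nll_logit(gamma, zbin, Zs):
    """Negative log-likelihood and gradient of the logit zero part."""
    v = np.clip(Zs @ gamma, -_ETA_CLIP, _ETA_CLIP)
    ll = zbin * log_expit(v) + (1.0 - zbin) * log_expit(-v)
    nll = -float(ll.sum())
    if not np.isfinite(nll):
        return _PENALTY, np.zeros_like(gamma)
    grad = -(Zs.T @ (zbin - expit(v)))
    return nll, grad


def _nll_zi(theta, base, y, Xs, Zs):
    """Negative log-likelihood and gradient of a zero-inflated family."""
    q = Zs.shape[1]
    p = Xs.shape[1]
    gamma = theta[:q]
    beta, alpha = _count_theta(theta[q:], base, p)
    v = np.clip(Zs @ gamma, -_ETA_CLIP, _ETA_CLIP)
    eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = expit(v)
    ll_c, deta_c, dloga_c = _count_ll_grad(base, y, mu, alpha)
    logp0, p0_deta, p0_dloga = _logp0_grad(base, mu, alpha)
    zero = y == 0
    log_w = log_expit(v)
    log_1mw = log_expit(-v)
    ll_zero = np.logaddexp(log_w, log_1mw + logp0)
    ll = np.where(zero, ll_zero, log_1mw + ll_c)
    nll = -float(ll.sum())
    if not np.isfinite(nll):
        return _PENALTY, np.zeros_like(theta)
    p0 = np.exp(logp0)
    L = np.maximum(np.exp(ll_zero), 1e-300)
    dv = np.where(zero, w * (1.0 - w) * (1.0 - p0) / L, -w)
    deta = np.where(zero, (1.0 - w) * p0 * p0_deta / L, deta_c)
    grad = np.empty_like(theta)
    grad[:q] = -(Zs.T @ dv)
    grad[q : q + p] = -(Xs.T @ deta)
    if base != "poisson":
        dloga = np.where(zero, (1.0 - w) * p0 * p0_dloga / L, dloga_c)
        grad[-1] = -float(dloga.sum())
    return nll, grad


def _softmax_full(u):
    z = np.concatenate(([0.0], u))
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _nll_lc(theta, y, Xs, C):
    """Negative log-likelihood and gradient of the NB2 finite mixture."""
    p = Xs.shape[1]
    u = theta[: C - 1]
    pi = _softmax_full(u)
    ll_ic = np.empty((y.size, C))
    detas = []
    dlogas = []
    for c in range(C):
        off = (C - 1) + c * (p + 1)
        beta, alpha = _count_theta(theta[off : off + p + 1], "nb2", p)
        eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll, deta, dloga = _count_ll_grad("nb2", y, mu, alpha)
        ll_ic[:, c] = ll
        detas.append(deta)
        dlogas.append(dloga)
    M = np.log(pi)[None, :] + ll_ic
    llrow = logsumexp(M, axis=1)
    nll = -float(llrow.sum())
    if not np.isfinite(nll):
        return _PENALTY, np.zeros_like(theta)
    W = np.exp(M - llrow[:, None])
    grad = np.empty_like(theta)
    grad[: C - 1] = -(W.sum(axis=0)[1:] - y.size * pi[1:])
    for c in range(C):
        off = (C - 1) + c * (p + 1)
        grad[off : off + p] = -(Xs.T @ (W[:, c] * detas[c]))
        grad[off + p] = -float(np.sum(W[:, c] * dlogas[c]))
    return nll, grad


# ---------------------------------------------------------------------------
# fitters (all in scaled design space)
# ---------------------------------------------------------------------------


def _start_count(family, y, Xs, weights=None):
    w = weights if weights is not None else np.ones_like(y, dtype=float)
    ybar = max(float(np.sum(w * y) / np.sum(w)), 1e-3)
    p = Xs.shape[1]
    beta0 = np.zeros(p)
    beta0[0] = np.log(ybar)
    if family == "poisson":
        return beta0
    yvar = float(np.sum(w * (y - ybar) ** 2) / np.sum(w))
    if family == "nb2":
        a0 = max((yvar - ybar) / ybar**2, 0.05)
    else:
        a0 = max(yvar / ybar - 1.0, 0.05)
    return np.concatenate([beta0, [np.log(a0)]])


def _fit_count(family, y, Xs, settings, weights=None, truncated=False, start=None) -> OptResult:
    if start is None:
        if family == "poisson":
            start = _start_count("poisson", y, Xs, weights)
        else:
            pois = _fit_count("poisson", y, Xs, settings, weights, truncated=False)
            start = np.concatenate([pois.theta, _start_count(family, y, Xs, weights)[-1:]])
    return minimize_nll(
        lambda th: _nll_count(th, family, y, Xs, weights, truncated), start, settings
    )


def _fit_logit(zbin, Zs, settings, start=None) -> OptResult:
    if start is None:
        pbar = float(np.clip(zbin.mean(), 1e-4, 1 - 1e-4))
        start = np.zeros(Zs.shape[1])
        start[0] = np.log(pbar / (1 - pbar))
    return minimize_nll(lambda g: _nll_logit(g, zbin, Zs), start, settings)


def _fit_zi(family, y, Xs, Zs, settings) -> OptResult:
    base = ZI_FAMILIES[family]
    count = _fit_count(base, y, Xs, settings)
    beta, alpha = _count_theta(count.theta, base, Xs.shape[1])
    mu = np.exp(np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP))
    p0bar = float(np.mean(np.exp(count_logp0(base, mu, alpha))))
    obs0 = float(np.mean(y == 0))
    q0 = float(np.clip((obs0 - p0bar) / 2.0, 5e-3, 0.95))
    gamma0 = np.zeros(Zs.shape[1])
    gamma0[0] = np.log(q0 / (1 - q0))
    start = np.concatenate([gamma0, count.theta])
    return minimize_nll(lambda th: _nll_zi(th, base, y, Xs, Zs), start, settings)


def _em_lcnb2(y, Xs, pi, betas, las, settings, maxiter, inner):
    """One EM run from the given start; returns state plus the lnL trace.

    Each M-step warm-starts the weighted NB2 maximizations from the current
    class parameters, so the trace is non-decreasing by construction.
    """
    C = len(betas)
    p = Xs.shape[1]
    prev = -np.inf
    history = []
    converged = False
    for it in range(maxiter):
        ll_ic = np.empty((y.size, C))
        for c in range(C):
            mu_c = np.exp(np.clip(Xs @ betas[c], -_ETA_CLIP, _ETA_CLIP))
            ll_ic[:, c] = _count_ll_grad("nb2", y, mu_c, float(np.exp(las[c])))[0]
        M = np.log(pi)[None, :] + ll_ic
        llrow = logsumexp(M, axis=1)
        llf = float(llrow.sum())
        history.append(llf)
        if llf - prev <= settings.tol * (abs(llf) + 1.0) and it > 0:
            converged = True
            break
        prev = llf
        W = np.exp(M - llrow[:, None])
        pi = np.clip(W.mean(axis=0), 1e-10, None)
        pi = pi / pi.sum()
        for c in range(C):
            res_c = _fit_count(
                "nb2", y, Xs, inner, weights=W[:, c],
                start=np.concatenate([betas[c], [las[c]]]),
            )
            betas[c] = res_c.theta[:p]
            las[c] = float(res_c.theta[p])
    return pi, betas, las, history, converged


def _fit_lcnb2(y, Xs, C, settings):
    """EM with seeded random restarts around the one-component NB2 fit.

    Each restart runs a short EM burst; the best restart is then iterated
    to convergence and polished by a quasi-Newton step on the full mixture
    likelihood (which can only increase the EM solution).  Returns
    (pi, betas_scaled, logalphas, llf, converged, n_iter, history).
    """
    p = Xs.shape[1]
    base = _fit_count("nb2", y, Xs, settings)
    beta0, la0 = base.theta[:p], base.theta[p]
    rng = np.random.default_rng(settings.seed)
    inner = FitSettings(tol=settings.tol, maxiter=15, restarts=0, seed=0)
    burst = min(40, settings.maxiter)
    best = None
    for _ in range(max(1, settings.restarts)):
        betas = [
            beta0 + np.concatenate([[rng.normal(0, 0.8)], rng.normal(0, 0.15, p - 1)])
            for _ in range(C)
        ]
        las = [la0 + rng.normal(0, 0.5) for _ in range(C)]
        pi = rng.dirichlet(np.full(C, 4.0))
        state = _em_lcnb2(y, Xs, pi, betas, las, settings, burst, inner)
        if best is None or state[3][-1] > best[3][-1]:
            best = state
    pi, betas, las, history, converged = best
    nit = len(history)
    # quasi-Newton polish on the joint likelihood (monotone from its start)
    theta0 = np.concatenate(
        [np.log(pi[1:] / pi[0])] + [np.concatenate([betas[c], [las[c]]]) for c in range(C)]
    )
    # boundary optima (a class dispersion heading to zero) approach their
    # supremum through many tiny steps, so the polish runs at machine ftol
    polish = FitSettings(tol=2.3e-16, maxiter=4 * settings.maxiter,
                         restarts=0, seed=0)
    res = minimize_nll(lambda th: _nll_lc(th, y, Xs, C), theta0, polish, gtol=1e-9)
    if -res.nll >= history[-1] - 1e-9:
        u = res.theta[: C - 1]
        pi = _softmax_full(u)
        betas = [res.theta[(C - 1) + c * (p + 1) : (C - 1) + c * (p + 1) + p] for c in range(C)]
        las = [float(res.theta[(C - 1) + c * (p + 1) + p]) for c in range(C)]
        history = history + [-res.nll]
        converged = converged or res.success
    return pi, betas, las, history[-1], converged, nit, history


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class CountModel:
    """A count-regression model bound to a dataset and a family."""

    def __init__(
        self,
        dataset: CountDataset,
        family: str,
        n_classes: int = 2,
        settings: FitSettings | None = None,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.dataset = dataset
        self.family = family
        self.n_classes = int(n_classes)
        self.settings = settings or FitSettings()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        family: str,
        covariates: list[str] | None = None,
        zero_covariates: list[str] | None = None,
        **kwargs,
    ) -> "CountModel":
        ds = CountDataset.from_dataframe(data, outcome, covariates, zero_covariates)
        return cls(ds, family, **kwargs)

    @classmethod
    def from_spec(cls, spec: ModelSpec, dataset: CountDataset) -> "CountModel":
        return cls(dataset, spec.family, n_classes=spec.n_classes, settings=spec.settings)

    # -- likelihood at arbitrary parameters -------------------------------
    def loglikeobs(self, params: dict, dataset: CountDataset | None = None) -> np.ndarray:
        return loglikeobs(self.family, params, dataset or self.dataset)

    def loglike(self, params: dict, dataset: CountDataset | None = None) -> float:
        return float(self.loglikeobs(params, dataset).sum())

    # -- estimation --------------------------------------------------------
    def fit(self) -> "CountResults":
        ds = self.dataset
        y = ds.y.astype(float)
        family = self.family
        settings = self.settings
        if ds.y.max() == 0:
            raise DegenerateDataError("outcome is all zeros; the count part is unidentified")
        if family in HURDLE_FAMILIES and (np.all(ds.y > 0) or np.all(ds.y == 0)):
            raise DegenerateDataError("hurdle families need at least one zero and one positive")

        Sx = DesignScaler(ds.X)
        Xs = Sx.transform(ds.X)
        p = Xs.shape[1]

        if family in BASE_FAMILIES:
            res = _fit_count(family, y, Xs, settings)
            beta, alpha = _count_theta(res.theta, family, p)
            params = {"beta": Sx.coef_to_natural(beta), "alpha": alpha}
            k = p + (0 if family == "poisson" else 1)
            return CountResults(
                self, params, -res.nll, k, res.success, res.nit,
                se_info=[("single", family, res.theta, Xs, None, Sx, None)],
            )

        Sz = DesignScaler(ds.Z)
        Zs = Sz.transform(ds.Z)
        q = Zs.shape[1]

        if family in HURDLE_FAMILIES:
            base = HURDLE_FAMILIES[family]
            zbin = (ds.y == 0).astype(float)
            res0 = _fit_logit(zbin, Zs, settings)
            pos = ds.y > 0
            res1 = _fit_count(base, y[pos], Xs[pos], settings, truncated=True)
            beta, alpha = _count_theta(res1.theta, base, p)
            params = {
                "gamma": Sz.coef_to_natural(res0.theta),
                "beta": Sx.coef_to_natural(beta),
                "alpha": alpha,
            }
            k = q + p + (0 if base == "poisson" else 1)
            return CountResults(
                self, params, -(res0.nll + res1.nll), k,
                res0.success and res1.success, res0.nit + res1.nit,
                se_info=[
                    ("logit", None, res0.theta, None, Zs, None, Sz),
                    ("truncated", base, res1.theta, Xs[pos], None, Sx, None),
                ],
                extra={"llf_zero": -res0.nll, "llf_positive": -res1.nll,
                       "y_positive": y[pos]},
            )

        if family in ZI_FAMILIES:
            base = ZI_FAMILIES[family]
            res = _fit_zi(family, y, Xs, Zs, settings)
            gamma = res.theta[:q]
            beta, alpha = _count_theta(res.theta[q:], base, p)
            params = {
                "gamma": Sz.coef_to_natural(gamma),
                "beta": Sx.coef_to_natural(beta),
                "alpha": alpha,
            }
            k = q + p + (0 if base == "poisson" else 1)
            return CountResults(
                self, params, -res.nll, k, res.success, res.nit,
                se_info=[("zi", family, res.theta, Xs, Zs, Sx, Sz)],
            )

        # latent-class NB2
        C = self.n_classes
        pi, betas, las, llf, converged, nit, history = _fit_lcnb2(y, Xs, C, settings)
        params = {
            "pi": np.asarray(pi),
            "class_beta": [Sx.coef_to_natural(b) for b in betas],
            "class_alpha": [float(np.exp(la)) for la in las],
        }
        k = (C - 1) + C * (p + 1)
        theta_full = np.concatenate(
            [np.log(pi[1:] / pi[0])] + [np.concatenate([betas[c], [las[c]]]) for c in range(C)]
        )
        return CountResults(
            self, params, llf, k, converged, nit,
            se_info=[("lc", C, theta_full, Xs, None, Sx, None)],
            history=history,
        )


def fit_model(spec: ModelSpec, dataset: CountDataset) -> "CountResults":
    """Fit a family described by a ModelSpec to a dataset."""
    return CountModel.from_spec(spec, dataset).fit()


class CountResults:
    """Estimates, uncertainty and predictions from a fitted count model."""

    def __init__(self, model, params, llf, k, converged, nit, se_info=None, extra=None, history=None):
        self.model = model
        self.family = model.family
        self.params = params
        self.llf = float(llf)
        self.k = int(k)
        self.converged = bool(converged)
        self.nit = int(nit)
        self.nobs = model.dataset.n
        self._se_info = se_info or []
        self.extra = extra or {}
        self.history = history
        self._bse = None

    # -- information criteria ---------------------------------------------
    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + np.log(self.nobs) * self.k

    # -- flat parameter vector --------------------------------------------
    @property
    def param_names(self) -> list[str]:
        ds = self.model.dataset
        fam = self.family
        if fam in BASE_FAMILIES:
            names = [f"count:{c}" for c in ds.xnames]
            if fam != "poisson":
                names.append("alpha")
            return names
        if fam in HURDLE_FAMILIES:
            names = [f"zero:{c}" for c in ds.znames] + [f"count:{c}" for c in ds.xnames]
            if HURDLE_FAMILIES[fam] != "poisson":
                names.append("alpha")
            return names
        if fam in ZI_FAMILIES:
            names = [f"inflate:{c}" for c in ds.znames] + [f"count:{c}" for c in ds.xnames]
            if ZI_FAMILIES[fam] != "poisson":
                names.append("alpha")
            return names
        names = []
        for c in range(len(self.params["pi"])):
            names.append(f"class{c + 1}:pi")
            names += [f"class{c + 1}:{nm}" for nm in ds.xnames]
            names.append(f"class{c + 1}:alpha")
        return names

    @property
    def params_flat(self) -> pd.Series:
        fam = self.family
        vals = []
        if fam in HURDLE_FAMILIES:
            vals += list(self.params["gamma"])
        elif fam in ZI_FAMILIES:
            vals += list(self.params["gamma"])
        if fam == "lcnb2":
            for c in range(len(self.params["pi"])):
                vals.append(self.params["pi"][c])
                vals += list(self.params["class_beta"][c])
                vals.append(self.params["class_alpha"][c])
        else:
            vals += list(self.params["beta"])
            if self.params.get("alpha") is not None:
                vals.append(self.params["alpha"])
        return pd.Series(vals, index=self.param_names, dtype=float)

    # -- standard errors ---------------------------------------------------
    @property
    def bse(self) -> pd.Series:
        """Observed-information standard errors on the natural scale."""
        if self._bse is None:
            self._bse = pd.Series(self._compute_se(), index=self.param_names, dtype=float)
        return self._bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.params_flat / self.bse
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.param_names)

    def _compute_se(self) -> np.ndarray:
        ses = []
        ds = self.model.dataset
        y = ds.y.astype(float)
        for kind, fam, theta, Xs, Zs, Sx, Sz in self._se_info:
            if kind == "single":
                grad = lambda th: _nll_count(th, fam, y, Xs)[1]
                J = _jac_count(fam, theta, Sx)
            elif kind == "truncated":
                ypos = self.extra["y_positive"]
                grad = lambda th: _nll_count(th, fam, ypos, Xs, truncated=True)[1]
                J = _jac_count(fam, theta, Sx)
            elif kind == "logit":
                zbin = (ds.y == 0).astype(float)
                grad = lambda th: _nll_logit(th, zbin, Zs)[1]
                J = Sz.matrix_
            elif kind == "zi":
                base = ZI_FAMILIES[fam]
                grad = lambda th: _nll_zi(th, base, y, Xs, Zs)[1]
                q = Zs.shape[1]
                blocks = [Sz.matrix_, Sx.matrix_]
                if base != "poisson":
                    blocks.append(np.array([[np.exp(theta[-1])]]))
                J = _block_diag(blocks)
            elif kind == "lc":
                C = fam
                grad = lambda th: _nll_lc(th, y, Xs, C)[1]
                J = _jac_lc(theta, C, Sx)
            else:  # pragma: no cover
                raise ValueError(kind)
            H = hessian_from_grad(grad, theta)
            cov = cov_from_hessian(H)
            cov_nat = J @ cov @ J.T
            with np.errstate(invalid="ignore"):
                se = np.sqrt(np.clip(np.diag(cov_nat), 0.0, None))
            ses.append(se)
        out = np.concatenate(ses) if ses else np.array([])
        if self.family == "lcnb2":
            out = _reorder_lc_se(out, len(self.params["pi"]), len(ds.xnames))
        return out

    # -- predictions -------------------------------------------------------
    def loglikeobs(self, dataset: CountDataset | None = None) -> np.ndarray:
        return loglikeobs(self.family, self.params, dataset or self.model.dataset)

    def loglike(self, dataset: CountDataset | None = None) -> float:
        return float(self.loglikeobs(dataset).sum())

    def predict_prob(self, j: int, dataset: CountDataset | None = None) -> np.ndarray:
        """Per-row probability of observing the count ``j``."""
        if j < 0 or int(j) != j:
            raise ValueError("count j must be a non-negative integer")
        ds = dataset or self.model.dataset
        j = float(j)
        fam = self.family
        p = self.params
        if fam in BASE_FAMILIES:
            mu = np.exp(ds.X @ p["beta"])
            return np.exp(count_logpmf(fam, j, mu, p.get("alpha")))
        if fam in HURDLE_FAMILIES:
            base = HURDLE_FAMILIES[fam]
            w = zero_prob_logit(ds.Z, p["gamma"])
            if j == 0:
                return w
            mu = np.exp(ds.X @ p["beta"])
            return (1.0 - w) * np.exp(truncated_logpmf(base, j, mu, p.get("alpha")))
        if fam in ZI_FAMILIES:
            base = ZI_FAMILIES[fam]
            w = zero_prob_logit(ds.Z, p["gamma"])
            mu = np.exp(ds.X @ p["beta"])
            f = np.exp(count_logpmf(base, j, mu, p.get("alpha")))
            if j == 0:
                return w + (1.0 - w) * f
            return (1.0 - w) * f
        out = np.zeros(ds.n)
        for c, pic in enumerate(p["pi"]):
            mu = np.exp(ds.X @ p["class_beta"][c])
            out += pic * np.exp(count_logpmf("nb2", j, mu, p["class_alpha"][c]))
        return out

    def predict_mean(self, dataset: CountDataset | None = None) -> np.ndarray:
        """Per-row expected count (unconditional, both parts combined)."""
        ds = dataset or self.model.dataset
        fam = self.family
        p = self.params
        if fam in BASE_FAMILIES:
            return np.exp(ds.X @ p["beta"])
        if fam in HURDLE_FAMILIES:
            base = HURDLE_FAMILIES[fam]
            w = zero_prob_logit(ds.Z, p["gamma"])
            mu = np.exp(ds.X @ p["beta"])
            p0 = np.exp(count_logp0(base, mu, p.get("alpha")))
            return (1.0 - w) / (1.0 - p0) * mu
        if fam in ZI_FAMILIES:
            w = zero_prob_logit(ds.Z, p["gamma"])
            return (1.0 - w) * np.exp(ds.X @ p["beta"])
        out = np.zeros(ds.n)
        for c, pic in enumerate(p["pi"]):
            out += pic * np.exp(ds.X @ p["class_beta"][c])
        return out

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        est = self.params_flat
        try:
            se = self.bse
            pv = self.pvalues
        except Exception:  # pragma: no cover - SE failure should not mask estimates
            se = pd.Series(np.nan, index=est.index)
            pv = pd.Series(np.nan, index=est.index)
        lines = [
            f"CountModel results — family: {self.family}",
            f"  nobs: {self.nobs}   k: {self.k}   logL: {self.llf:.3f}   "
            f"AIC: {self.aic:.3f}   BIC: {self.bic:.3f}   converged: {self.converged}",
            f"  {'parameter':<28}{'estimate':>12}{'std.err.':>12}{'p-value':>10}",
        ]
        for name in est.index:
            lines.append(f"  {name:<28}{est[name]:>12.4f}{se[name]:>12.4f}{pv[name]:>10.4f}")
        if self.family in HURDLE_FAMILIES or self.family in ZI_FAMILIES:
            label = "zero" if self.family in HURDLE_FAMILIES else "inflate"
            lines.append(
                f"  note: the {label} part models Pr(y = 0) on the logit scale; "
                "Pr(y > 0) is its complement."
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "llf": self.llf,
            "k": self.k,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "nobs": self.nobs,
            "params": {k: np.asarray(v).tolist() if not np.isscalar(v) and v is not None else v
                        for k, v in self.params.items()
                        if k not in ("class_beta",)},
        }
        if "class_beta" in self.params:
            d["params"]["class_beta"] = [np.asarray(b).tolist() for b in self.params["class_beta"]]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _block_diag(blocks):
    sizes = [b.shape for b in blocks]
    out = np.zeros((sum(s[0] for s in sizes), sum(s[1] for s in sizes)))
    r = c = 0
    for b in blocks:
        out[r : r + b.shape[0], c : c + b.shape[1]] = b
        r += b.shape[0]
        c += b.shape[1]
    return out


def _jac_count(family, theta, scaler):
    if family == "poisson":
        return scaler.matrix_
    return _block_diag([scaler.matrix_, np.array([[np.exp(theta[-1])]])])


def _jac_lc(theta, C, scaler):
    """Jacobian of (pi_1..C, beta_1..C natural, alpha_1..C) wrt scaled theta."""
    p = scaler.p
    u = theta[: C - 1]
    pi = _softmax_full(u)
    # d pi_c / d u_k  (u indexes classes 2..C)
    Jpi = np.empty((C, C - 1))
    for c in range(C):
        for k in range(C - 1):
            Jpi[c, k] = pi[c] * ((1.0 if c == k + 1 else 0.0) - pi[k + 1])
    blocks = []
    for c in range(C):
        off = (C - 1) + c * (p + 1)
        blocks.append((off, scaler.matrix_, float(np.exp(theta[off + p]))))
    nnat = C + C * (p + 1)
    J = np.zeros((nnat, theta.size))
    J[:C, : C - 1] = Jpi
    row = C
    for off, A, a in blocks:
        J[row : row + p, off : off + p] = A
        J[row + p, off + p] = a
        row += p + 1
    return J


def _reorder_lc_se(se, C, p):
    """Regroup (pis..., per-class beta+alpha...) into per-class blocks."""
    pis = se[:C]
    rest = se[C:]
    out = []
    for c in range(C):
        out.append(pis[c])
        blk = rest[c * (p + 1) : (c + 1) * (p + 1)]
        out += list(blk)
    return np.asarray(out)


def predict_prob(fit: CountResults, dataset: CountDataset, j: int) -> np.ndarray:
    """Functional form of :meth:`CountResults.predict_prob`."""
    return fit.predict_prob(j, dataset)


def predict_mean(fit: CountResults, dataset: CountDataset) -> np.ndarray:
    """Functional form of :meth:`CountResults.predict_mean`."""
    return fit.predict_mean(dataset)
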