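import numpy as np
import pandas as pd
import pytest

from countfit import CountDataset, FitSettings, TrueDGP, make_dataset, simulate_counts


def toy_covariates(n: int, seed: int) -> pd.DataFrame:
    """One binary and one standard-normal covariate, the recurring toy design."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"x1": (rng.random(n) < 0.5).astype(float), "x2": rng.normal(size=n)}
    )


def toy_dataset(family: str, n: int, seed: int, **dgp_kwargs) -> CountDataset:
    cov = toy_covariates(n, seed)
    dgp = TrueDGP(family, seed=seed + 10_000, **dgp_kwargs)
    return make_dataset(cov, simulate_counts(dgp, cov))


#: coefficients shared by the simulation-based tests
BETA = {"const": 1.0, "x1": 0.4, "x2": 0.3}
GAMMA = {"const": -1.0, "x1": 0.5, "x2": 0.3}
LC_CLASSES = [
    (0.6, {"const": 0.3, "x1": 0.4, "x2": 0.2}, 0.5),
    (0.4, {"const": 1.8, "x1": -0.3, "x2": 0.1}, 1.0),
]


def dgp_for(family: str, seed: int = 0) -> TrueDGP:
    """A fully parameterised truth for any family, on the toy design."""
    if family == "poisson":
        return TrueDGP("poisson", beta=BETA, seed=seed)
    if family == "nb1":
        return TrueDGP("nb1", beta=BETA, alpha=1.5, seed=seed)
    if family == "nb2":
        return TrueDGP("nb2", beta=BETA, alpha=1.0, seed=seed)
    if family in ("hurdle_poisson", "zip"):
        return TrueDGP(family, beta=BETA, gamma=GAMMA, seed=seed)
    if family == "hurdle_nb1":
        return TrueDGP(family, beta=BETA, gamma=GAMMA, alpha=1.5, seed=seed)
    if family in ("hurdle_nb2", "zinb2"):
        return TrueDGP(family, beta=BETA, gamma=GAMMA, alpha=1.0, seed=seed)
    if family == "lcnb2":
        return TrueDGP("lcnb2", classes=LC_CLASSES, seed=seed)
    raise ValueError(family)


@pytest.fixture
def quick_settings() -> FitSettings:
    """Fewer EM restarts for tests where the default ten would be wasteful."""
    return FitSettings(restarts=4, seed=3)


# ---------------------------------------------------------------------------
# independent zoom-grid maximizer used as the MLE oracle
# ---------------------------------------------------------------------------


def grid_max(loglik, bounds, points: int = 9, rounds: int = 9, sweeps: int = 40):
    """Maximize ``loglik(theta)`` by an iteratively refined dense grid.

    ``loglik`` must accept a (m, d) array of parameter vectors and return m
    log-likelihood values.  Independent of any gradient-based fitting: pure
    enumeration — a geometric zoom around the incumbent followed by
    coordinate-wise enumeration sweeps (which handle ridged surfaces).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    best_val = -np.inf
    best_theta = (lo + hi) / 2.0
    for _ in range(rounds):
        axes = [np.linspace(a, b, points) for a, b in zip(lo, hi)]
        mesh = np.meshgrid(*axes, indexing="ij")
        thetas = np.column_stack([m.ravel() for m in mesh])
        vals = loglik(thetas)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best_theta = thetas[i]
        span = (hi - lo) / (points - 1) * 2.0
        lo = best_theta - span
        hi = best_theta + span

    d = best_theta.size
    span = np.full(d, 0.25)
    for s in range(sweeps):
        improved = False
        for k in range(d):
            grid = np.tile(best_theta, (81, 1))
            grid[:, k] = best_theta[k] + np.linspace(-span[k], span[k], 81)
            vals = loglik(grid)
            i = int(np.argmax(vals))
            if vals[i] > best_val + 1e-12:
                best_val = float(vals[i])
                best_theta = grid[i].copy()
                improved = True
        if not improved:
            span *= 0.35
            if span.max() < 1e-7:
                break
    return best_val, best_theta
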