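import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from morbcompress.ordered_beta import _build_design

#: truth used by the ordered-beta recovery simulations (reporting scale:
#: age centered at 43.5, year offset from 2008)
TRUE_BETA = np.array([-1.0, -0.15, 0.02, -0.10, -0.12, -0.02, 0.005])
TRUE_BETA_ZERO = np.array([-0.85, 0.25, -0.03, 0.20, 0.15, 0.02, -0.008])


def simulate_hurdle_data(
    seed,
    n,
    n_regions=19,
    beta=TRUE_BETA,
    beta_zero=TRUE_BETA_ZERO,
    k2=2.0,
    psi=8.0,
    sigma_u=0.3,
):
    """Draw covariates and a hurdle ordered-beta outcome with known truth."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "region": rng.integers(1, n_regions + 1, n),
            "year": rng.integers(2008, 2020, n),
            "age": rng.integers(18, 70, n),
            "sex": np.where(rng.random(n) < 0.53, "female", "male"),
            "education": np.where(rng.random(n) < 0.6, "high", "low"),
            "economic": np.where(rng.random(n) < 0.53, "difficulties", "none"),
        }
    )
    u = rng.normal(0.0, sigma_u, n_regions) if sigma_u > 0 else np.zeros(n_regions)
    X = _build_design(df, 2008)
    eta = X @ beta + u[df["region"] - 1]
    p0 = expit(X @ beta_zero)
    q1 = expit(eta - k2)
    m = expit(eta)
    y = np.empty(n)
    is0 = rng.random(n) < p0
    y[is0] = 0.0
    is1 = (~is0) & (rng.random(n) < q1)
    y[is1] = 1.0
    mid = ~(is0 | is1)
    y[mid] = np.clip(rng.beta(m[mid] * psi, (1 - m[mid]) * psi), 1e-12, 1 - 1e-12)
    df["y"] = y
    return df, u


def direct_2pl_max_loglik(X, w, grid):
    """Independent oracle: maximise the same quadrature marginal likelihood
    directly with a quasi-Newton optimiser over all item parameters."""
    from scipy import optimize
    from scipy.special import expit, logit, logsumexp

    X = np.asarray(X, dtype=float)
    n_items = X.shape[1]

    def negloglik(theta):
        b0, b1 = theta[:n_items], theta[n_items:]
        eta = b0[:, None] + b1[:, None] * grid.nodes[None, :]
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        ll = X @ logp + (1 - X) @ log1mp + np.log(grid.masses)[None, :]
        return -float(w @ logsumexp(ll, axis=1))

    prev = np.clip(X.mean(axis=0), 1e-6, 1 - 1e-6)
    x0 = np.concatenate([logit(prev), np.ones(n_items)])
    best = np.inf
    for scale in (1.0, 0.5):
        res = optimize.minimize(
            negloglik, x0 * scale, method="L-BFGS-B", options={"maxiter": 2000}
        )
        best = min(best, res.fun)
    return -best


@pytest.fixture(scope="session")
def hurdle_simulator():
    return simulate_hurdle_data


@pytest.fixture(scope="session")
def small_population():
    """A modest default-configuration population reused across tests."""
    from morbcompress import PopulationConfig, generate_population

    return generate_population(PopulationConfig(n_respondents=20_000, seed=11))
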