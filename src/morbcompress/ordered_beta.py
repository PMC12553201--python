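"""Zero/one-inflated ordered beta regression with a regional random intercept.

The rescaled multimorbidity index ``y`` lives on [0, 1] with structural mass
at 0 (no reported disease) and at 1 (the worst observed response pattern).
The outcome is modelled as a three-part mixture:

* default **hurdle** variant — the probability of an exact zero follows its
  own logistic regression (the "zero-inflation model"); conditional on
  ``y > 0``, an ordered-logit cutpoint ``k2`` splits the one-mass from the
  interior, and interior values follow a Beta distribution in mean-precision
  form with mean ``expit(X b + u_k)`` and precision ``psi``;
* **canonical** variant — the single-predictor ordered beta model with two
  cutpoints ``k1 < k2`` governing both boundary masses.

The regional random intercept ``u_k ~ N(0, sigma_u^2)`` enters the
conditional (``y > 0``) predictor and is integrated out of the likelihood by
a Laplace approximation (inner Newton per region with analytic first and
second derivatives); adaptive Gauss-Hermite quadrature is available as a
cross-check. Fixed effects follow the published design: intercept, sex, age,
economic status, education, survey year and the sex-by-age interaction.

Coefficient convention: age enters centered at 43.5 years and year as the
offset from the first survey year, so the intercept is the linear predictor
of a 43.5-year-old woman with low education and economic difficulties in the
first year, and "Sex (Male)" is the male-female contrast at age 43.5. "Age",
"Year" and the interaction are per-year slopes under any coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln, digamma, expit, gammaln, polygamma
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "ModelSpec",
    "OrderedBetaFit",
    "PredictionGrid",
    "COEF_NAMES",
    "component_probabilities",
    "continuous_density",
    "marginal_negloglik",
    "fit_ordered_beta",
    "predict_population",
    "blup",
    "coefficient_table",
]

COEF_NAMES = (
    "(Intercept)",
    "Sex (Male)",
    "Age",
    "Economic Problem (No)",
    "Educational Level (High)",
    "Year",
    "Sex (Male):Age",
)

_AGE_CENTER = 43.5  # internal centering for optimizer conditioning


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: mixture variant and random-effect structure."""

    variant: Literal["hurdle", "canonical"] = "hurdle"
    random_effect: Literal["region", "none"] = "region"

    def __post_init__(self) -> None:
        if self.variant not in ("hurdle", "canonical"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.random_effect not in ("region", "none"):
            raise ValueError(f"unknown random_effect {self.random_effect!r}")


@dataclass
class OrderedBetaFit:
    spec: ModelSpec
    coef: pd.Series  # conditional-model coefficients (reporting scale)
    coef_zero: pd.Series | None  # zero-part coefficients (hurdle) or None
    k1: float | None
    k2: float | None
    psi: float
    sigma2_u: float | None
    u_modes: np.ndarray | None
    u_sds: np.ndarray | None
    regions: np.ndarray | None
    loglik: float
    se: pd.Series
    se_zero: pd.Series | None
    cov: np.ndarray | None
    converged: bool
    n_iter: int
    message: str
    first_year: int
    has_zero_mass: bool
    has_one_mass: bool
    theta: np.ndarray = field(repr=False, default=None)
    _prep: "_Prepared" = field(repr=False, default=None)


@dataclass
class PredictionGrid:
    """Covariate profiles with population-level estimates (random effects at 0)."""

    table: pd.DataFrame  # profiles plus gamma (P(y=0)), mu (E[y|y>0]), yhat


# ---------------------------------------------------------------------------
# elementary pieces


def component_probabilities(eta, eta_zero=None, k1=None, k2=None, variant="hurdle"):
    """Probabilities of the three outcome components (P0, P_mid, P1).

    Canonical: P0 = 1 - expit(eta - k1), P1 = expit(eta - k2), the interior
    takes the telescoped remainder. Hurdle: P0 = expit(eta_zero); the
    remaining mass splits by expit(eta - k2). Both sum to one.
    """
    eta = np.asarray(eta, dtype=float)
    if variant == "canonical":
        if k1 is None or k2 is None or not k1 < k2:
            raise ValueError("canonical variant requires cutpoints k1 < k2")
        s1 = expit(eta - k1)
        s2 = expit(eta - k2)
        return 1.0 - s1, s1 - s2, s2
    if variant == "hurdle":
        if eta_zero is None or k2 is None:
            raise ValueError("hurdle variant requires eta_zero and k2")
        p0 = expit(np.asarray(eta_zero, dtype=float))
        q1 = expit(eta - k2)
        return p0, (1.0 - p0) * (1.0 - q1), (1.0 - p0) * q1
    raise ValueError(f"unknown variant {variant!r}")


def continuous_density(y, eta, u=0.0, psi=1.0):
    """Beta density of interior outcomes, mean expit(eta + u), precision psi."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("continuous_density is defined on the open interval (0, 1)")
    if psi <= 0:
        raise ValueError("precision psi must be positive")
    m = expit(np.asarray(eta, dtype=float) + u)
    a, b = m * psi, (1.0 - m) * psi
    return np.exp((a - 1) * np.log(y) + (b - 1) * np.log1p(-y) - betaln(a, b))


def _log_expit(x):
    return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Prepared:
    X: np.ndarray  # internal conditional design (age centered, year offset)
    y: np.ndarray
    region_idx: np.ndarray | None
    regions: np.ndarray | None
    n_regions: int
    i0: np.ndarray
    i1: np.ndarray
    im: np.ndarray
    w: np.ndarray
    first_year: int
    has_zero_mass: bool
    has_one_mass: bool
    n_coef: int
    u_cache: np.ndarray | None = None  # warm start for the inner Newton


def _build_design(data: pd.DataFrame, first_year: int) -> np.ndarray:
    sex = data["sex"].astype(str)
    edu = data["education"].astype(str)
    econ = data["economic"].astype(str)
    for col, levels in (
        (sex, {"male", "female"}),
        (edu, {"high", "low"}),
        (econ, {"difficulties", "none"}),
    ):
        bad = set(col.unique()) - levels
        if bad:
            raise ValueError(f"unknown covariate level(s): {sorted(bad)}")
    male = (sex == "male").to_numpy(float)
    age_c = data["age"].to_numpy(float) - _AGE_CENTER
    return np.column_stack(
        [
            np.ones(len(data)),
            male,
            age_c,
            (econ == "none").to_numpy(float),
            (edu == "high").to_numpy(float),
            data["year"].to_numpy(float) - first_year,
            male * age_c,
        ]
    )


def _prepare(
    data: pd.DataFrame,
    spec: ModelSpec,
    components: str = "strict",
    weights: np.ndarray | None = None,
    require_interior: bool = True,
) -> _Prepared:
    y = data["y"].to_numpy(float)
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("y values must lie in [0, 1]")
    if weights is None:
        w = np.ones(len(data))
    else:
        w = np.asarray(weights, dtype=float)

    first_year = int(data["year"].min())
    X = _build_design(data, first_year)

    if spec.random_effect == "region":
        regions, region_idx = np.unique(data["region"].to_numpy(), return_inverse=True)
        if len(regions) < 2:
            raise ValueError("random_effect='region' needs at least 2 regions")
    else:
        regions, region_idx = None, None

    # canonical row ordering: estimates independent of input row order
    keys = [X[:, j] for j in range(X.shape[1])]
    if region_idx is not None:
        keys.append(region_idx)
    keys.append(w)
    keys.append(y)
    order = np.lexsort(tuple(keys))
    X, y, w = X[order], y[order], w[order]
    if region_idx is not None:
        region_idx = region_idx[order]

    i0, i1 = y == 0.0, y == 1.0
    im = ~(i0 | i1)
    if require_interior and not im.any():
        raise ValueError("no interior (0 < y < 1) observations; nothing to fit")
    has_zero, has_one = bool(i0.any()), bool(i1.any())
    if components == "strict":
        missing = [s for s, ok in (("y=0", has_zero), ("y=1", has_one)) if not ok]
        if missing:
            raise ValueError(
                f"no {' or '.join(missing)} observations; fit the reduced model "
                "by passing components='auto' to drop the absent point mass(es)"
            )
    elif components != "auto":
        raise ValueError("components must be 'strict' or 'auto'")
    if spec.variant == "canonical" and not (has_zero and has_one):
        raise ValueError("canonical variant requires both boundary masses observed")

    return _Prepared(
        X=X,
        y=y,
        region_idx=region_idx,
        regions=regions,
        n_regions=0 if regions is None else len(regions),
        i0=i0,
        i1=i1,
        im=im,
        w=w,
        first_year=first_year,
        has_zero_mass=has_zero,
        has_one_mass=has_one,
        n_coef=X.shape[1],
    )


# ---------------------------------------------------------------------------
# likelihood


def _unpack(theta: np.ndarray, prep: _Prepared, spec: ModelSpec) -> dict:
    p = prep.n_coef
    pos = 0
    out = {}
    out["beta"] = theta[pos : pos + p]
    pos += p
    if spec.variant == "hurdle":
        if prep.has_zero_mass:
            out["beta_zero"] = theta[pos : pos + p]
            pos += p
        else:
            out["beta_zero"] = None
        if prep.has_one_mass:
            out["k2"] = theta[pos]
            pos += 1
        else:
            out["k2"] = None
        out["k1"] = None
    else:
        out["k1"] = theta[pos]
        out["k2"] = theta[pos] + np.exp(theta[pos + 1])
        pos += 2
        out["beta_zero"] = None
    out["psi"] = np.exp(theta[pos])
    pos += 1
    if spec.random_effect == "region":
        out["sigma_u"] = np.exp(theta[pos])
        pos += 1
    else:
        out["sigma_u"] = None
    return out


def _n_params(prep: _Prepared, spec: ModelSpec) -> int:
    p = prep.n_coef
    n = p + 1  # beta + log psi
    if spec.variant == "hurdle":
        n += p if prep.has_zero_mass else 0
        n += 1 if prep.has_one_mass else 0
    else:
        n += 2
    if spec.random_effect == "region":
        n += 1
    return n


def _obs_terms(par: dict, prep: _Prepared, spec: ModelSpec, u_obs, order: int):
    """Per-observation weighted log-likelihood and its u-derivatives.

    Returns (ll, d1, d2); d1/d2 are None unless requested via ``order``.
    The hurdle zero part carries no random effect, so zero observations have
    vanishing u-derivatives in that variant.
    """
    y, i0, i1, im, w = prep.y, prep.i0, prep.i1, prep.im, prep.w
    eta = prep.X @ par["beta"] + u_obs
    psi = par["psi"]
    ll = np.zeros(len(y))
    d1 = np.zeros(len(y)) if order >= 1 else None
    d2 = np.zeros(len(y)) if order >= 2 else None

    if spec.variant == "hurdle":
        if prep.has_zero_mass:
            eta_z = prep.X @ par["beta_zero"]
            ll[i0] = _log_expit(eta_z[i0])
            nz = ~i0
            ll[nz] += _log_expit(-eta_z[nz])
        if prep.has_one_mass:
            a = eta - par["k2"]
            s = expit(a)
            ll[i1] += _log_expit(a[i1])
            ll[im] += _log_expit(-a[im])
            if order >= 1:
                d1[i1] += 1.0 - s[i1]
                d1[im] += -s[im]
            if order >= 2:
                sp = s * (1.0 - s)
                d2[i1] += -sp[i1]
                d2[im] += -sp[im]
    else:  # canonical
        a1 = eta - par["k1"]
        a2 = eta - par["k2"]
        s1, s2 = expit(a1), expit(a2)
        ll[i0] = _log_expit(-a1[i0])
        ll[i1] = _log_expit(a2[i1])
        diff = np.clip(s1[im] - s2[im], 1e-300, None)
        ll[im] = np.log(diff)
        if order >= 1:
            sp1, sp2 = s1 * (1 - s1), s2 * (1 - s2)
            d1[i0] += -s1[i0]
            d1[i1] += 1.0 - s2[i1]
            dmid = (sp1[im] - sp2[im]) / diff
            d1[im] += dmid
            if order >= 2:
                d2[i0] += -sp1[i0]
                d2[i1] += -sp2[i1]
                curv = (sp1[im] * (1 - 2 * s1[im]) - sp2[im] * (1 - 2 * s2[im])) / diff
                d2[im] += curv - dmid**2

    # interior Beta density (mean-precision form)
    m = expit(eta[im])
    ym = y[im]
    a_, b_ = m * psi, (1 - m) * psi
    ll[im] += (
        (a_ - 1) * np.log(ym)
        + (b_ - 1) * np.log1p(-ym)
        - (gammaln(a_) + gammaln(b_) - gammaln(psi))
    )
    if order >= 1:
        dldm = psi * (np.log(ym) - np.log1p(-ym) - digamma(a_) + digamma(b_))
        mp = m * (1 - m)
        d1[im] += dldm * mp
        if order >= 2:
            d2ldm2 = -(psi**2) * (polygamma(1, a_) + polygamma(1, b_))
            d2[im] += d2ldm2 * mp**2 + dldm * mp * (1 - 2 * m)

    ll *= w
    if order >= 1:
        d1 *= w
    if order >= 2:
        d2 *= w
    return ll, d1, d2


def _inner_modes(par, prep, spec, tol=1e-10, max_iter=100):
    """Newton maximisation of the per-region joint log-density over u (vectorised).

    Warm-started from the previous call's modes; the tight tolerance makes
    the result independent of the starting point.
    """
    K = prep.n_regions
    sig2 = par["sigma_u"] ** 2
    u = np.zeros(K) if prep.u_cache is None else prep.u_cache.copy()
    idx = prep.region_idx
    for _ in range(max_iter):
        _, d1, d2 = _obs_terms(par, prep, spec, u[idx], order=2)
        g1 = np.bincount(idx, weights=d1, minlength=K) - u / sig2
        g2 = np.bincount(idx, weights=d2, minlength=K) - 1.0 / sig2
        g2 = np.minimum(g2, -1e-10)
        step = np.clip(-g1 / g2, -2.0, 2.0)
        u = u + step
        if np.max(np.abs(g1)) < tol and np.max(np.abs(step)) < 1e-8:
            break
    prep.u_cache = u.copy()
    _, _, d2 = _obs_terms(par, prep, spec, u[idx], order=2)
    g2 = np.bincount(idx, weights=d2, minlength=K) - 1.0 / sig2
    return u, np.minimum(g2, -1e-10)


def _negloglik(theta, prep, spec, method="laplace", n_quad=15):
    par = _unpack(np.asarray(theta, dtype=float), prep, spec)
    if spec.random_effect == "none":
        ll, _, _ = _obs_terms(par, prep, spec, 0.0, order=0)
        return -float(ll.sum())

    K = prep.n_regions
    sig2 = par["sigma_u"] ** 2
    u_hat, g2 = _inner_modes(par, prep, spec)
    ll_obs, _, _ = _obs_terms(par, prep, spec, u_hat[prep.region_idx], order=0)
    ll_region = np.bincount(prep.region_idx, weights=ll_obs, minlength=K)
    g_hat = ll_region - 0.5 * np.log(2 * np.pi * sig2) - u_hat**2 / (2 * sig2)
    if method == "laplace":
        log_marg = g_hat + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(-g2)
        return -float(log_marg.sum())
    if method == "aghq":
        x, wq = np.polynomial.hermite.hermgauss(n_quad)
        sd = 1.0 / np.sqrt(-g2)
        logs = np.empty((n_quad, K))
        for q in range(n_quad):
            uq = u_hat + np.sqrt(2.0) * sd * x[q]
            ll_q, _, _ = _obs_terms(par, prep, spec, uq[prep.region_idx], order=0)
            llr = np.bincount(prep.region_idx, weights=ll_q, minlength=K)
            g_q = llr - 0.5 * np.log(2 * np.pi * sig2) - uq**2 / (2 * sig2)
            logs[q] = np.log(wq[q]) + x[q] ** 2 + g_q
        from scipy.special import logsumexp

        log_marg = logsumexp(logs, axis=0) + np.log(np.sqrt(2.0) * sd)
        return -float(log_marg.sum())
    raise ValueError(f"unknown method {method!r}")


def marginal_negloglik(
    params: dict,
    data: pd.DataFrame,
    spec: ModelSpec,
    method: str = "laplace",
    components: str = "auto",
    weights: np.ndarray | None = None,
) -> float:
    """Negative marginal log-likelihood at explicit parameter values.

    ``params`` uses reporting-scale coefficients: keys ``beta`` (length 7,
    ordered as :data:`COEF_NAMES`, age centered at 43.5 and year offset from
    the first observed year), ``beta_zero`` (hurdle), ``k1``/``k2``, ``psi``
    and ``sigma_u`` (when the spec has a regional random effect).
    """
    prep = _prepare(
        data, spec, components=components, weights=weights, require_interior=False
    )
    theta = _pack_reporting(params, prep, spec)
    return _negloglik(theta, prep, spec, method=method)


def _pack_reporting(params: dict, prep: _Prepared, spec: ModelSpec) -> np.ndarray:
    parts = [np.asarray(params["beta"], dtype=float)]
    if spec.variant == "hurdle":
        if prep.has_zero_mass:
            parts.append(np.asarray(params["beta_zero"], dtype=float))
        if prep.has_one_mass:
            parts.append([float(params["k2"])])
    else:
        k1, k2 = float(params["k1"]), float(params["k2"])
        if not k1 < k2:
            raise ValueError("cutpoints must satisfy k1 < k2")
        parts.append([k1, np.log(k2 - k1)])
    parts.append([np.log(float(params["psi"]))])
    if spec.random_effect == "region":
        parts.append([np.log(float(params["sigma_u"]))])
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


# ---------------------------------------------------------------------------
# fitting


def _warm_start(prep: _Prepared, spec: ModelSpec) -> np.ndarray:
    X, y = prep.X, prep.y
    ym = np.clip(y[prep.im], 1e-4, 1 - 1e-4)
    Xm = X[prep.im]
    beta0, *_ = np.linalg.lstsq(Xm, np.log(ym / (1 - ym)), rcond=None)

    parts = [beta0]
    if spec.variant == "hurdle":
        if prep.has_zero_mass:
            # ridge-damped IRLS for the zero indicator
            t = prep.i0.astype(float)
            bz = np.zeros(prep.n_coef)
            for _ in range(25):
                p = expit(X @ bz)
                gr = X.T @ (t - p) - 1e-6 * bz
                h = (X * (p * (1 - p) + 1e-8)[:, None]).T @ X + 1e-6 * np.eye(
                    prep.n_coef
                )
                step = np.linalg.solve(h, gr)
                bz = bz + np.clip(step, -5, 5)
                if np.max(np.abs(step)) < 1e-8:
                    break
            if np.max(np.abs(bz)) > 15:
                warnings.warn(
                    "possible separation in the zero part (large warm-start "
                    "coefficients); check the zero-inflation design",
                    stacklevel=3,
                )
            parts.append(bz)
        if prep.has_one_mass:
            parts.append([1.0])  # k2 start
    else:
        parts.append([-1.0, np.log(2.0)])  # k1 = -1, k2 = 1
    parts.append([np.log(5.0)])  # psi
    if spec.random_effect == "region":
        parts.append([np.log(0.1)])  # sigma_u
    return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])


def _central_grad(theta, prep, spec, rel=1e-6):
    g = np.empty(len(theta))
    for i in range(len(theta)):
        h = rel * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        g[i] = (_negloglik(up, prep, spec) - _negloglik(dn, prep, spec)) / (2 * h)
    return g


def _scaled_grad_norm(g, theta, fval):
    return float(np.max(np.abs(g) * np.maximum(1.0, np.abs(theta))) / max(1.0, abs(fval)))


def _newton_polish(theta, fval, H, prep, spec, bounds, max_steps=3):
    """Damped Newton refinement using the numeric Hessian; returns the scaled
    gradient norm used for the convergence flag. Steps are clipped to the
    optimizer's box to keep the log-scale parameters in range."""
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    g = _central_grad(theta, prep, spec)
    scaled = _scaled_grad_norm(g, theta, fval)
    for _ in range(max_steps):
        if scaled < 1e-6:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for frac in (1.0, 0.5, 0.25, 0.1):
            cand = np.clip(theta - frac * step, lo, hi)
            with np.errstate(all="ignore"):
                fc = _negloglik(cand, prep, spec)
            if np.isfinite(fc) and fc <= fval:
                theta, fval, improved = cand, fc, True
                break
        if not improved:
            break
        g = _central_grad(theta, prep, spec)
        scaled = _scaled_grad_norm(g, theta, fval)
    return theta, fval, scaled


def fit_ordered_beta(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    components: str = "strict",
    weights: np.ndarray | None = None,
    compute_se: bool = True,
    maxiter: int = 500,
) -> OrderedBetaFit:
    """Maximum-likelihood fit of the ordered beta regression.

    ``data`` must contain ``y`` in [0, 1], the covariates ``sex``, ``age``,
    ``education``, ``economic``, ``year`` and — when the spec includes the
    regional random effect — ``region``. With ``components='strict'`` the
    data must exhibit zeros, ones and interior values; ``'auto'`` drops the
    point-mass component(s) that are absent (reduced model).
    """
    if spec is None:
        spec = ModelSpec()
    prep = _prepare(data, spec, components=components, weights=weights)

    def _bounds(n_par, has_re):
        b = [(None, None)] * n_par
        if has_re:
            b[-2] = (-5.0, 10.0)  # log psi
            b[-1] = (-8.0, 3.0)  # log sigma_u
        else:
            b[-1] = (-5.0, 10.0)  # log psi
        return b

    if spec.random_effect == "region":
        # stage 1: fixed effects from the no-random-effect model (cheap, one
        # likelihood pass per evaluation), then add sigma_u
        spec0 = ModelSpec(variant=spec.variant, random_effect="none")
        res0 = optimize.minimize(
            _negloglik,
            _warm_start(prep, spec0),
            args=(prep, spec0),
            method="L-BFGS-B",
            bounds=_bounds(_n_params(prep, spec0), False),
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        x0 = np.concatenate([res0.x, [np.log(0.1)]])
    else:
        x0 = _warm_start(prep, spec)

    n_par = _n_params(prep, spec)
    assert len(x0) == n_par
    res = optimize.minimize(
        _negloglik,
        x0,
        args=(prep, spec),
        method="L-BFGS-B",
        bounds=_bounds(n_par, spec.random_effect == "region"),
        options={"maxiter": maxiter, "ftol": 1e-9},
    )
    theta = res.x
    fval = float(res.fun)
    converged = bool(res.success)

    p = prep.n_coef
    se_all = np.full(n_par, np.nan)
    cov_rep = None
    if compute_se:
        # central-difference Hessian, then Newton polish along badly scaled
        # directions the quasi-Newton loop cannot resolve; the scaled
        # gradient-norm check defines the converged flag
        H = approx_hess(theta, _negloglik, args=(prep, spec))
        theta, fval, scaled_grad = _newton_polish(
            theta, fval, H, prep, spec, _bounds(n_par, spec.random_effect == "region")
        )
        converged = converged and scaled_grad < 1e-5
        try:
            cov_rep = np.linalg.inv(H)
            se_all = np.sqrt(np.clip(np.diag(cov_rep), 0.0, None))
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; standard errors unavailable", stacklevel=2)
    if not converged:
        warnings.warn(
            f"ordered beta fit flagged as unconverged: {res.message}", stacklevel=2
        )
    par = _unpack(theta, prep, spec)

    coef = pd.Series(par["beta"].copy(), index=list(COEF_NAMES))
    se = pd.Series(se_all[:p], index=list(COEF_NAMES))
    coef_zero = se_zero = None
    if spec.variant == "hurdle" and prep.has_zero_mass:
        coef_zero = pd.Series(par["beta_zero"].copy(), index=list(COEF_NAMES))
        se_zero = pd.Series(se_all[p : 2 * p], index=list(COEF_NAMES))

    u_modes = u_sds = None
    sigma2_u = None
    if spec.random_effect == "region":
        sigma2_u = float(par["sigma_u"] ** 2)
        u_modes, g2 = _inner_modes(par, prep, spec)
        u_sds = 1.0 / np.sqrt(-g2)

    return OrderedBetaFit(
        spec=spec,
        coef=coef,
        coef_zero=coef_zero,
        k1=None if par["k1"] is None else float(par["k1"]),
        k2=None if par["k2"] is None else float(par["k2"]),
        psi=float(par["psi"]),
        sigma2_u=sigma2_u,
        u_modes=u_modes,
        u_sds=u_sds,
        regions=prep.regions,
        loglik=-fval,
        se=se,
        se_zero=se_zero,
        cov=cov_rep,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
        first_year=prep.first_year,
        has_zero_mass=prep.has_zero_mass,
        has_one_mass=prep.has_one_mass,
        theta=theta,
        _prep=prep,
    )


# ---------------------------------------------------------------------------
# post-fit quantities


def predict_population(fit: OrderedBetaFit, profiles: pd.DataFrame) -> PredictionGrid:
    """Population-level predictions y_hat = (1 - gamma) * mu at u = 0.

    ``mu`` is the conditional mean given a nonzero outcome, mixing the
    one-mass with the Beta interior mean.
    """
    X = _build_design(profiles, fit.first_year)
    eta = X @ fit.coef.to_numpy()
    m = expit(eta)
    if fit.spec.variant == "hurdle":
        if fit.has_zero_mass:
            gamma = expit(X @ fit.coef_zero.to_numpy())
        else:
            gamma = np.zeros(len(X))
        q1 = expit(eta - fit.k2) if fit.has_one_mass else np.zeros(len(X))
        mu = q1 + (1.0 - q1) * m
    else:
        p0, pm, p1 = component_probabilities(
            eta, k1=fit.k1, k2=fit.k2, variant="canonical"
        )
        gamma = p0
        denom = np.clip(pm + p1, 1e-300, None)
        mu = (p1 + pm * m) / denom
    out = profiles.copy()
    out["gamma"] = gamma
    out["mu"] = mu
    out["yhat"] = (1.0 - gamma) * mu
    return PredictionGrid(table=out)


def blup(fit: OrderedBetaFit) -> pd.DataFrame:
    """Empirical-Bayes regional predictions (posterior modes) with conditional sds."""
    if fit.spec.random_effect != "region":
        raise ValueError("BLUPs require a fit with the regional random effect")
    return pd.DataFrame(
        {"region": fit.regions, "estimate": fit.u_modes, "sd": fit.u_sds}
    )


def coefficient_table(fit: OrderedBetaFit) -> pd.DataFrame:
    """Two-block coefficient table (conditional model, zero-inflation model)."""
    from scipy.stats import norm

    def block(name, coef, se):
        t = coef / se
        return pd.DataFrame(
            {
                "model": name,
                "term": coef.index,
                "Estimate": coef.to_numpy(),
                "Std. Error": se.to_numpy(),
                "t value": t.to_numpy(),
                "p-value": 2 * norm.sf(np.abs(t.to_numpy())),
            }
        )

    parts = [block("Conditional model", fit.coef, fit.se)]
    if fit.coef_zero is not None:
        parts.append(block("Zero-inflation model", fit.coef_zero, fit.se_zero))
    return pd.concat(parts, ignore_index=True)
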