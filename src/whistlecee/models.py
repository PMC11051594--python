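"""Statistical models for the multi-scale response analysis.

The three response variables call for three model families, all fit by
direct maximum likelihood:

* 10-min scale — ``periodDiff`` is modeled with a negative-binomial
  (NB2, variance mu + mu^2/theta) regression, optionally with a
  per-experiment random intercept integrated out by adaptive
  Gauss-Hermite quadrature.
* 20-s scale — ``pingChange`` is approximately Gaussian but
  zero-inflated: an observation is an exact zero with probability
  pi (logit-linear in covariates, typically the baseline median whistle
  count) or Gaussian otherwise, so the likelihood of each observation is
  ``pi * 1{y=0} + (1 - pi) * N(y; mu, sigma^2)``.
* 5-s scale — the same zero-inflated Gaussian with first-order
  autoregressive correlation ``phi^|dt|`` among the non-zero
  observations within an experiment, in ping order.  The zero component
  is a point mass and carries no serial correlation.

Model selection is backward elimination on the fixed terms by AIC, with
likelihood-ratio tests for the nested comparisons.  A pooled two-sample
t-test (plus the Welch form) covers the changepoint-difference
comparison between control and sonar experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "TTestResult",
    "SelectionResult",
    "fit_model",
    "fit_nb_glmm",
    "fit_zi_gaussian",
    "fit_zi_gaussian_ar1",
    "backward_select",
    "pooled_t_test",
    "welch_t_test",
]


# ---------------------------------------------------------------------------
# Specifications and results

@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` name columns of the data frame (categorical columns
    are dummy-coded, first level as reference); an intercept is always
    included.  ``zi_terms`` define the logit-linear zero-inflation
    predictor (with its own intercept); ``zi_terms=None`` disables the
    mixture.  ``correlation`` is ``None`` or ``("ar1", times, group)``.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_intercept: str | None = None
    zi_terms: tuple[str, ...] | None = None
    correlation: tuple[str, str, str] | None = None
    family: str = "gaussian"          # "gaussian" | "nbinom_log"

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        if self.zi_terms is not None:
            object.__setattr__(self, "zi_terms", tuple(self.zi_terms))
            if self.family != "gaussian":
                raise ValueError("zero inflation is only supported with the gaussian family")
        if self.correlation is not None:
            if self.correlation[0] != "ar1":
                raise ValueError("only ar1 correlation is supported")
            if self.random_intercept is not None:
                raise NotImplementedError(
                    "a random intercept combined with ar1 correlation is not supported"
                )

    def formula(self) -> str:
        parts = ["1", *self.fixed_terms]
        if self.random_intercept:
            parts.append(f"(1 | {self.random_intercept})")
        if self.correlation:
            parts.append(f"ar1({self.correlation[1]} | {self.correlation[2]})")
        return f"{self.response} ~ " + " + ".join(parts)

    def zi_formula(self) -> str:
        if self.zi_terms is None:
            return "none"
        return "~ " + (" + ".join(("1", *self.zi_terms)) if self.zi_terms else "1")


@dataclass
class ModelFit:
    """Maximum-likelihood fit: coefficient table and fit statistics."""

    spec: ModelSpec
    params: pd.DataFrame        # columns: part, name, estimate, se, z, p
    loglik: float
    df: int
    n_obs: int
    converged: bool
    dispersion: float | None = None   # NB2 theta
    sigma2: float | None = None       # Gaussian residual variance
    phi: float | None = None          # AR(1) correlation
    sigma_b: float | None = None      # random-intercept SD
    messages: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.df

    def coef(self, name: str, part: str = "cond") -> float:
        sub = self.params[(self.params["part"] == part) & (self.params["name"] == name)]
        if len(sub) != 1:
            raise KeyError(f"no unique coefficient {name!r} in part {part!r}")
        return float(sub["estimate"].iloc[0])

    def pvalue(self, name: str, part: str = "cond") -> float:
        sub = self.params[(self.params["part"] == part) & (self.params["name"] == name)]
        if len(sub) != 1:
            raise KeyError(f"no unique coefficient {name!r} in part {part!r}")
        return float(sub["p"].iloc[0])


@dataclass
class TTestResult:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    t: float
    df: float
    p: float
    kind: str = "pooled"


# ---------------------------------------------------------------------------
# Design matrices

def build_design(data: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept-plus-terms design matrix; categoricals dummy-coded
    (first level dropped as reference), numeric columns used as-is."""
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in data")
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col.astype("category"), prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Numerical helpers

def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                v = (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (
                    4.0 * h[i] * h[j]
                )
                H[i, j] = H[j, i] = v
    return H


def _safe_se(neg_ll, xhat: np.ndarray) -> np.ndarray:
    """Standard errors from the inverse observed information; NaN where the
    Hessian is not positive definite."""
    H = _num_hessian(neg_ll, xhat)
    se = np.full(xhat.size, np.nan)
    if not np.all(np.isfinite(H)):
        return se
    # pseudo-inverse keeps SEs for identifiable directions when one
    # parameter (e.g. a separated zero-inflation slope) flattens out
    cov = np.linalg.pinv(H)
    d = np.diag(cov)
    ok = d > 0
    se[ok] = np.sqrt(d[ok])
    return se


def _minimize(neg_ll, x0: np.ndarray) -> optimize.OptimizeResult:
    res = optimize.minimize(neg_ll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    # polish with a derivative-free pass when BFGS stalls on FD-gradient noise
    if not res.success or not np.isfinite(res.fun):
        res2 = optimize.minimize(
            neg_ll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 4000},
        )
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
    return res


def _wald_table(names: list[str], part: str, est: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"part": part, "name": names, "estimate": est, "se": se, "z": z, "p": p})


_GH_NODES = 25


def _adaptive_gh_loglik(cond_ll, sigma_b: float, n_nodes: int = _GH_NODES) -> float:
    """log of the Gauss-Hermite approximation of
    integral exp(cond_ll(b)) * N(b; 0, sigma_b^2) db,
    with the quadrature grid adapted to the integrand's mode and curvature
    so that node-doubling changes the result by well under 1e-4."""
    if sigma_b <= 0:
        return cond_ll(0.0)
    log_prior = lambda b: -0.5 * (b / sigma_b) ** 2 - 0.5 * np.log(2 * np.pi) - np.log(sigma_b)
    h = lambda b: cond_ll(b) + log_prior(b)
    # locate the mode of the joint; the prior keeps it within a few sigma_b
    opt = optimize.minimize_scalar(
        lambda b: -h(b), bounds=(-10 * sigma_b, 10 * sigma_b), method="bounded",
        options={"xatol": 1e-8 * max(sigma_b, 1.0)},
    )
    bhat = float(opt.x)
    step = 1e-4 * max(abs(bhat), sigma_b)
    d2 = (h(bhat + step) - 2.0 * h(bhat) + h(bhat - step)) / step**2
    scale = 1.0 / np.sqrt(-d2) if d2 < 0 else sigma_b
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)   # weight exp(-x^2/2)
    b = bhat + scale * x
    terms = np.array([h(bi) for bi in b]) + 0.5 * x**2 + np.log(w) + np.log(scale)
    return float(special.logsumexp(terms))


def _logit_parts(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(log pi, log(1 - pi)) for logit pi = z, numerically stable."""
    sp = np.logaddexp(0.0, -z)     # softplus(-z) = -log pi
    sm = np.logaddexp(0.0, z)
    return -sp, -sm


# ---------------------------------------------------------------------------
# Negative-binomial (mixed) regression

def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    # NB2: Var = mu + mu^2/theta;   scipy n = theta, p = theta/(theta+mu)
    mu = np.clip(mu, 1e-12, 1e12)
    return stats.nbinom.logpmf(y, theta, theta / (theta + mu))


def fit_nb_glmm(data: pd.DataFrame, spec: ModelSpec, gh_nodes: int = _GH_NODES) -> ModelFit:
    """Negative-binomial (NB2, log link) regression, optionally with a
    per-group random intercept integrated by adaptive Gauss-Hermite
    quadrature.  Non-integer responses are rounded half-to-even to counts
    (the pre-rounding values are left untouched in ``data``)."""
    if spec.family != "nbinom_log":
        raise ValueError("fit_nb_glmm requires family='nbinom_log'")
    y_raw = data[spec.response].to_numpy(dtype=float)
    if (y_raw < 0).any():
        raise ValueError("negative response values are not count-like")
    y = np.rint(y_raw).astype(int)
    messages: list[str] = []
    if np.any(y != y_raw):
        messages.append("non-integer response rounded half-to-even to counts")
        logger.info("fit_nb_glmm: %s", messages[-1])
    X, names = build_design(data, spec.fixed_terms)
    k = X.shape[1]
    groups = data[spec.random_intercept].to_numpy() if spec.random_intercept else None

    def unpack(x):
        beta = x[:k]
        theta = np.exp(x[k])
        sigma_b = np.exp(x[k + 1]) if spec.random_intercept else None
        return beta, theta, sigma_b

    if spec.random_intercept:
        uniq = pd.unique(groups)
        gidx = [np.flatnonzero(groups == g) for g in uniq]

        def loglik(x):
            beta, theta, sigma_b = unpack(x)
            eta = X @ beta
            total = 0.0
            for idx in gidx:
                yg, eg = y[idx], eta[idx]
                cond = lambda b: float(np.sum(_nb_logpmf(yg, np.exp(eg + b), theta)))
                total += _adaptive_gh_loglik(cond, sigma_b, gh_nodes)
            return total
    else:

        def loglik(x):
            beta, theta, _ = unpack(x)
            return float(np.sum(_nb_logpmf(y, np.exp(X @ beta), theta)))

    def neg_ll(x):
        with np.errstate(all="ignore"):
            v = loglik(x)
        return -v if np.isfinite(v) else 1e12

    x0 = np.zeros(k + (2 if spec.random_intercept else 1))
    x0[0] = np.log(np.mean(y) + 0.5)
    if spec.random_intercept:
        x0[k + 1] = np.log(0.5)
    res = _minimize(neg_ll, x0)
    beta, theta, sigma_b = unpack(res.x)
    se = _safe_se(neg_ll, res.x)
    converged = bool(np.isfinite(res.fun)) and np.all(np.isfinite(res.x))
    if not converged:
        messages.append("optimizer failed to converge")

    tab = [_wald_table(names, "cond", beta, se[:k])]
    tab.append(_wald_table(["log(theta)"], "disp", res.x[k:k + 1], se[k:k + 1]))
    if spec.random_intercept:
        tab.append(_wald_table(["log(sigma_b)"], "ranef", res.x[k + 1:k + 2], se[k + 1:k + 2]))
    return ModelFit(
        spec=spec,
        params=pd.concat(tab, ignore_index=True),
        loglik=-float(res.fun),
        df=len(res.x),
        n_obs=len(y),
        converged=converged,
        dispersion=float(theta),
        sigma_b=float(sigma_b) if sigma_b is not None else None,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Zero-inflated Gaussian

def _zi_obs_loglik(y, mu, sigma, log_pi, log_1mpi):
    """Per-observation mixture log-likelihood
    pi * 1{y=0} + (1 - pi) * N(y; mu, sigma^2)."""
    norm = stats.norm.logpdf(y, mu, sigma) + log_1mpi
    return np.where(y == 0.0, np.logaddexp(log_pi, norm), norm)


def _ols_fallback(data, spec, X, names, y, messages) -> ModelFit:
    """Plain-Gaussian closed form used when the zero component is
    unidentifiable (no exact zeros in the response)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid / n)      # ML estimate
    loglik = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0))
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tab = [_wald_table(names, "cond", beta, se)]
    tab.append(_wald_table(["log(sigma)"], "disp", np.array([0.5 * np.log(sigma2)]), np.array([np.nan])))
    return ModelFit(
        spec=spec,
        params=pd.concat(tab, ignore_index=True),
        loglik=loglik,
        df=X.shape[1] + 1,
        n_obs=n,
        converged=True,
        sigma2=sigma2,
        messages=messages,
    )


def fit_zi_gaussian(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Zero-inflated Gaussian regression by direct maximum likelihood.

    The zero-inflation probability is logit-linear in ``spec.zi_terms``.
    With a random intercept the group-level marginal likelihood is
    computed by adaptive Gauss-Hermite quadrature (the random effect
    shifts the Gaussian mean only).  Falls back to ordinary least squares
    with a warning when the data contain no exact zeros.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_zi_gaussian requires family='gaussian'")
    y = data[spec.response].to_numpy(dtype=float)
    X, names = build_design(data, spec.fixed_terms)
    messages: list[str] = []
    if spec.zi_terms is None:
        raise ValueError("spec.zi_terms must be set (possibly empty) for a ZI fit")
    if not np.any(y == 0.0):
        messages.append("no exact zeros: zero-inflation unidentifiable, plain Gaussian fit")
        warnings.warn(messages[-1])
        return _ols_fallback(data, spec, X, names, y, messages)
    Xz, znames = build_design(data, spec.zi_terms)
    k, kz = X.shape[1], Xz.shape[1]
    groups = data[spec.random_intercept].to_numpy() if spec.random_intercept else None

    def unpack(x):
        beta = x[:k]
        sigma = np.exp(x[k])
        gamma = x[k + 1:k + 1 + kz]
        sigma_b = np.exp(x[k + 1 + kz]) if spec.random_intercept else None
        return beta, sigma, gamma, sigma_b

    def loglik(x):
        beta, sigma, gamma, sigma_b = unpack(x)
        mu = X @ beta
        log_pi, log_1mpi = _logit_parts(Xz @ gamma)
        if groups is None:
            return float(np.sum(_zi_obs_loglik(y, mu, sigma, log_pi, log_1mpi)))
        total = 0.0
        for g in pd.unique(groups):
            idx = np.flatnonzero(groups == g)
            cond = lambda b: float(
                np.sum(_zi_obs_loglik(y[idx], mu[idx] + b, sigma, log_pi[idx], log_1mpi[idx]))
            )
            total += _adaptive_gh_loglik(cond, sigma_b)
        return total

    def neg_ll(x):
        with np.errstate(all="ignore"):
            v = loglik(x)
        return -v if np.isfinite(v) else 1e12

    nz = y != 0.0
    beta0, *_ = np.linalg.lstsq(X[nz], y[nz], rcond=None) if nz.sum() >= k else (np.zeros(k),)
    resid_sd = np.std(y[nz] - X[nz] @ beta0) if nz.sum() > k else max(np.std(y), 1e-2)
    x0 = np.concatenate([
        beta0,
        [np.log(max(resid_sd, 1e-3))],
        [special.logit(np.clip(np.mean(y == 0.0), 0.02, 0.98))],
        np.zeros(kz - 1),
        [np.log(0.5)] if spec.random_intercept else [],
    ])
    res = _minimize(neg_ll, x0)
    beta, sigma, gamma, sigma_b = unpack(res.x)
    se = _safe_se(neg_ll, res.x)
    converged = bool(np.isfinite(res.fun))

    tab = [
        _wald_table(names, "cond", beta, se[:k]),
        _wald_table(["log(sigma)"], "disp", res.x[k:k + 1], se[k:k + 1]),
        _wald_table(znames, "zi", gamma, se[k + 1:k + 1 + kz]),
    ]
    if spec.random_intercept:
        tab.append(_wald_table(["log(sigma_b)"], "ranef", res.x[-1:], se[-1:]))
    return ModelFit(
        spec=spec,
        params=pd.concat(tab, ignore_index=True),
        loglik=-float(res.fun),
        df=len(res.x),
        n_obs=len(y),
        converged=converged,
        sigma2=float(sigma**2),
        sigma_b=float(sigma_b) if sigma_b is not None else None,
        messages=messages,
    )


def _ar1_group_loglik(yv, muv, tv, sigma, phi):
    """Joint Gaussian log-density of the non-zero observations of one
    group under correlation phi^|dt|, via the Markov factorization."""
    ll = stats.norm.logpdf(yv[0], muv[0], sigma)
    if yv.size > 1:
        dt = np.diff(tv)
        # integer-valued dt keeps the sign coherent for phi < 0
        r = np.power(phi, dt)
        cond_mu = muv[1:] + r * (yv[:-1] - muv[:-1])
        cond_sd = sigma * np.sqrt(np.clip(1.0 - r * r, 1e-12, None))
        ll += float(np.sum(stats.norm.logpdf(yv[1:], cond_mu, cond_sd)))
    return float(ll)


def fit_zi_gaussian_ar1(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Zero-inflated Gaussian with AR(1) correlation among the non-zero
    observations within each group (``spec.correlation = ("ar1", times,
    group)``).  Exact zeros contribute their marginal mixture likelihood;
    the non-zero values of a group form a jointly Gaussian vector with
    correlation ``phi^|dt|`` in the ``times`` index, evaluated by the
    Markov factorization.  Warns when ``|phi|`` is estimated at the
    boundary."""
    if spec.correlation is None:
        raise ValueError("spec.correlation must be ('ar1', times, group)")
    _, times_col, group_col = spec.correlation
    data = data.sort_values([group_col, times_col], kind="mergesort").reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    t = data[times_col].to_numpy(dtype=float)
    g = data[group_col].to_numpy()
    X, names = build_design(data, spec.fixed_terms)
    if spec.zi_terms is None:
        raise ValueError("spec.zi_terms must be set for a ZI fit")
    messages: list[str] = []
    if not np.any(y == 0.0):
        messages.append("no exact zeros: zero-inflation unidentifiable, plain Gaussian fit")
        warnings.warn(messages[-1])
        # AR(1)-only Gaussian fit would still be possible; keep the documented
        # fallback contract of the non-correlated fit
        return _ols_fallback(data, spec, X, names, y, messages)
    Xz, znames = build_design(data, spec.zi_terms)
    k, kz = X.shape[1], Xz.shape[1]
    group_index = [np.flatnonzero(g == u) for u in pd.unique(g)]

    def unpack(x):
        return x[:k], np.exp(x[k]), np.tanh(x[k + 1]), x[k + 2:]

    def loglik(x):
        beta, sigma, phi, gamma = unpack(x)
        mu = X @ beta
        log_pi, log_1mpi = _logit_parts(Xz @ gamma)
        total = 0.0
        zero = y == 0.0
        # zeros: marginal mixture term
        norm0 = stats.norm.logpdf(0.0, mu[zero], sigma) + log_1mpi[zero]
        total += float(np.sum(np.logaddexp(log_pi[zero], norm0)))
        # non-zeros: (1 - pi) factors plus the joint AR(1) Gaussian density
        for idx in group_index:
            nz = idx[~zero[idx]]
            if nz.size == 0:
                continue
            total += float(np.sum(log_1mpi[nz]))
            total += _ar1_group_loglik(y[nz], mu[nz], t[nz], sigma, phi)
        return total

    def neg_ll(x):
        with np.errstate(all="ignore"):
            v = loglik(x)
        return -v if np.isfinite(v) else 1e12

    nz = y != 0.0
    beta0, *_ = np.linalg.lstsq(X[nz], y[nz], rcond=None) if nz.sum() >= k else (np.zeros(k),)
    resid_sd = np.std(y[nz] - X[nz] @ beta0) if nz.sum() > k else max(np.std(y), 1e-2)
    x0 = np.concatenate([
        beta0,
        [np.log(max(resid_sd, 1e-3))],
        [0.0],                      # atanh(phi) = 0
        [special.logit(np.clip(np.mean(y == 0.0), 0.02, 0.98))],
        np.zeros(kz - 1),
    ])
    res = _minimize(neg_ll, x0)
    beta, sigma, phi, gamma = unpack(res.x)
    se = _safe_se(neg_ll, res.x)
    converged = bool(np.isfinite(res.fun))
    if abs(phi) > 0.99:
        messages.append(f"AR(1) correlation at the boundary: phi = {phi:.4f}")
        warnings.warn(messages[-1])

    # delta method from atanh(phi) back to phi
    se_phi = se[k + 1] * (1.0 - phi**2) if np.isfinite(se[k + 1]) else np.nan
    tab = [
        _wald_table(names, "cond", beta, se[:k]),
        _wald_table(["log(sigma)"], "disp", res.x[k:k + 1], se[k:k + 1]),
        _wald_table(["phi"], "corr", np.array([phi]), np.array([se_phi])),
        _wald_table(znames, "zi", gamma, se[k + 2:]),
    ]
    return ModelFit(
        spec=spec,
        params=pd.concat(tab, ignore_index=True),
        loglik=-float(res.fun),
        df=len(res.x),
        n_obs=len(y),
        converged=converged,
        sigma2=float(sigma**2),
        phi=float(phi),
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Dispatch and model selection

def fit_model(data: pd.DataFrame, spec: ModelSpec, **kw) -> ModelFit:
    """Route a ModelSpec to the appropriate fitting routine."""
    if spec.family == "nbinom_log":
        return fit_nb_glmm(data, spec, **kw)
    if spec.correlation is not None:
        return fit_zi_gaussian_ar1(data, spec)
    if spec.zi_terms is not None:
        return fit_zi_gaussian(data, spec)
    # plain Gaussian: reuse the ZI machinery's OLS closed form
    X, names = build_design(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(dtype=float)
    return _ols_fallback(data, spec, X, names, y, [])


@dataclass
class SelectionResult:
    """Backward-elimination trace: every candidate fit, the AIC table and
    likelihood-ratio tests for the accepted drops."""

    best_spec: ModelSpec
    best_fit: ModelFit
    fits: list[ModelFit]
    table: pd.DataFrame          # formula, zi formula, family, dAIC, df, dispersion
    lrt: pd.DataFrame            # dropped term, chi2, df, p per accepted step


def _lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.df - reduced.df
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return chi2, df, p


def backward_select(data: pd.DataFrame, full_spec: ModelSpec, **kw) -> SelectionResult:
    """Backward elimination on the fixed terms by AIC.

    At each step the fixed term whose removal lowers AIC the most is
    dropped; elimination stops when no removal lowers AIC.  Candidates
    that fail to converge are skipped with a log entry.  The report table
    lists every fitted candidate with its AIC difference to the best
    model (``dAIC = 0`` for the selected model).
    """
    current_fit = fit_model(data, full_spec, **kw)
    if not current_fit.converged:
        raise RuntimeError("the full model did not converge")
    all_fits = [current_fit]
    lrt_rows = []
    current = full_spec
    while current.fixed_terms:
        candidates = []
        for term in current.fixed_terms:
            reduced = replace(current, fixed_terms=tuple(t for t in current.fixed_terms if t != term))
            try:
                fit = fit_model(data, reduced, **kw)
            except Exception as exc:           # noqa: BLE001 - candidate skipped, logged
                logger.warning("candidate without %s failed: %s", term, exc)
                continue
            if not fit.converged:
                logger.warning("candidate without %s did not converge; skipped", term)
                continue
            candidates.append((term, fit))
        all_fits.extend(f for _, f in candidates)
        if not candidates:
            break
        term, best_cand = min(candidates, key=lambda tf: tf[1].aic)
        if best_cand.aic < current_fit.aic:
            chi2, df, p = _lrt(current_fit, best_cand)
            lrt_rows.append({"dropped": term, "chi2": chi2, "df": df, "p": p})
            current_fit, current = best_cand, best_cand.spec
        else:
            break

    best_aic = min(f.aic for f in all_fits)
    # deduplicate by formula, keeping the best fit of each
    seen: dict[str, ModelFit] = {}
    for f in all_fits:
        key = f.spec.formula()
        if key not in seen or f.aic < seen[key].aic:
            seen[key] = f
    rows = [
        {
            "conditional_model": f.spec.formula(),
            "zi_model": f.spec.zi_formula(),
            "family": "nbinom2" if f.spec.family == "nbinom_log" else f.spec.family,
            "dAIC": f.aic - best_aic,
            "df": f.df,
            "dispersion": f.dispersion if f.dispersion is not None else f.sigma2,
        }
        for f in sorted(seen.values(), key=lambda f: f.aic)
    ]
    return SelectionResult(
        best_spec=current_fit.spec,
        best_fit=current_fit,
        fits=list(seen.values()),
        table=pd.DataFrame(rows),
        lrt=pd.DataFrame(lrt_rows, columns=["dropped", "chi2", "df", "p"]),
    )


# ---------------------------------------------------------------------------
# Two-sample t-tests

def pooled_t_test(x, y) -> TTestResult:
    """Unpaired two-sample t-test with pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(np.mean(x)), float(np.mean(y)), float(np.sqrt(v1)), float(np.sqrt(v2)),
                       n1, n2, float(t), df, float(p), kind="pooled")


def welch_t_test(x, y) -> TTestResult:
    """Unpaired two-sample t-test with unequal variances (Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        raise ValueError("zero variance in both groups")
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(np.mean(x)), float(np.mean(y)), float(np.sqrt(v1)), float(np.sqrt(v2)),
                       n1, n2, float(t), float(df), float(p), kind="welch")
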