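"""Exponential-family GLM machinery for intercept-free lagged regressions.

Each family supplies, for a linear predictor :math:`\\eta = X\\beta'`:

* the mean model (gaussian: identity; binomial: logistic; poisson: log;
  gamma: reciprocal, :math:`\\mu = 1/\\eta`; inverse-Gaussian: identity with
  a positivity constraint),
* the exact log-likelihood :math:`L_i` including all constant terms,
* the diagonal Fisher weight matrix :math:`W_i` (with robust variants for
  binomial and over/underdispersed poisson),
* a dispersion estimate :math:`\\hat\\phi_i`, and
* maximum-likelihood estimation of :math:`\\beta` by IRLS.

Means outside a family's domain (nonpositive gamma / inverse-Gaussian
means) yield a ``-inf`` likelihood sentinel so that subset search rejects
the candidate rather than scoring a meaningless fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .panel import DesignMatrix

_EPS = 1e-10
_ETA_MAX = 30.0  # exp overflow guard for log links


@dataclass
class GLMFit:
    """Result of an IRLS fit: coefficients, dispersion and diagnostics."""

    beta: np.ndarray
    dispersion: float
    converged: bool
    iterations: int


class Family:
    """Base class; subclasses implement the per-family pieces."""

    name: str = ""

    # -- mean model -----------------------------------------------------
    def mean(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def valid_mean(self, eta: np.ndarray) -> bool:
        """Whether the linear predictor maps into the mean domain."""
        return True

    def null_mean(self, y: np.ndarray) -> np.ndarray:
        """Mean used for the empty (zero-regressor) model."""
        raise NotImplementedError

    # -- likelihood / weights / dispersion ------------------------------
    def log_likelihood(self, y: np.ndarray, eta: np.ndarray, dispersion: float) -> float:
        raise NotImplementedError

    def weights(self, y: np.ndarray, eta: np.ndarray, dispersion: float,
                robust: bool = False) -> np.ndarray:
        raise NotImplementedError

    def dispersion(self, y: np.ndarray, eta: np.ndarray, n_params: int) -> float:
        raise NotImplementedError

    # -- IRLS ingredients ------------------------------------------------
    def _init_mu(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _link(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _dlink(self, mu: np.ndarray) -> np.ndarray:
        """d eta / d mu."""
        raise NotImplementedError

    def _variance(self, mu: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _clip_mu(self, mu: np.ndarray) -> np.ndarray:
        return mu

    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"

    def mean(self, eta):
        return eta

    def null_mean(self, y):
        return np.zeros_like(y)

    def log_likelihood(self, y, eta, dispersion):
        m = y.size
        rss = float(np.sum((y - eta) ** 2))
        return -0.5 * m * np.log(2 * np.pi * dispersion) - rss / (2 * dispersion)

    def weights(self, y, eta, dispersion, robust=False):
        return np.ones_like(eta)

    def dispersion(self, y, eta, n_params):
        return max(float(np.mean((y - eta) ** 2)), _EPS)

    def _init_mu(self, y):
        return y.astype(float)

    def _link(self, mu):
        return mu

    def _dlink(self, mu):
        return np.ones_like(mu)

    def _variance(self, mu):
        return np.ones_like(mu)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2))


class Binomial(Family):
    name = "binomial"

    def mean(self, eta):
        return special.expit(eta)

    def null_mean(self, y):
        return np.full_like(y, 0.5)

    def log_likelihood(self, y, eta, dispersion):
        # sum_t y_t eta_t - log(1 + exp(eta_t)), stable via log1p/softplus
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def weights(self, y, eta, dispersion, robust=False):
        mu = special.expit(eta)
        if robust:
            return (y - mu) ** 2
        return mu * (1 - mu)

    def dispersion(self, y, eta, n_params):
        return 1.0

    def _init_mu(self, y):
        return (y + 0.5) / 2.0

    def _link(self, mu):
        return np.log(mu / (1 - mu))

    def _dlink(self, mu):
        return 1.0 / (mu * (1 - mu))

    def _variance(self, mu):
        return mu * (1 - mu)

    def _clip_mu(self, mu):
        return np.clip(mu, 1e-8, 1 - 1e-8)

    def deviance(self, y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2 * np.sum(t1 + t2))


class Poisson(Family):
    name = "poisson"

    #: |dispersion - 1| threshold below which the plain (non-robust)
    #: weight matrix exp(eta) is used.
    equidispersion_tol = 0.1

    def mean(self, eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def null_mean(self, y):
        return np.ones_like(y)

    def log_likelihood(self, y, eta, dispersion):
        mu = self.mean(eta)
        return float(np.sum(y * eta - mu - special.gammaln(y + 1)))

    def weights(self, y, eta, dispersion, robust=False):
        mu = self.mean(eta)
        if robust or abs(dispersion - 1.0) > self.equidispersion_tol:
            return (y - mu) ** 2
        return mu

    def dispersion(self, y, eta, n_params):
        mu = self.mean(eta)
        dof = max(y.size - n_params, 1)
        pearson = float(np.sum((y - mu) ** 2 / np.maximum(mu, _EPS)))
        return max(pearson / dof, _EPS)

    def _init_mu(self, y):
        return y + 0.5

    def _link(self, mu):
        return np.log(mu)

    def _dlink(self, mu):
        return 1.0 / mu

    def _variance(self, mu):
        return mu

    def _clip_mu(self, mu):
        return np.clip(mu, 1e-8, None)

    def deviance(self, y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2 * np.sum(t - (y - mu)))


class Gamma(Family):
    """Gamma with reciprocal mean model mu_t = 1/eta_t and dispersion kappa
    (the inverse shape): shape a = 1/kappa, scale b_t = kappa*mu_t.

    The dispersion is estimated once per target from the marginal series
    (maximum-likelihood gamma fit), not per candidate subset.
    """

    name = "gamma"

    def mean(self, eta):
        with np.errstate(divide="ignore"):
            return 1.0 / eta

    def valid_mean(self, eta):
        return bool(np.all(eta > 0))

    def null_mean(self, y):
        # eta = 0 is outside the reciprocal-link domain; use marginal mean
        return np.full_like(y, float(np.mean(y)))

    def log_likelihood(self, y, eta, dispersion):
        if not self.valid_mean(eta):
            return -np.inf
        mu = 1.0 / eta
        return self.log_likelihood_mu(y, mu, dispersion)

    def log_likelihood_mu(self, y, mu, kappa):
        if np.any(mu <= 0):
            return -np.inf
        a = 1.0 / kappa
        return float(
            np.sum((a - 1) * np.log(y) - y / (kappa * mu) - a * np.log(kappa * mu)
                   - special.gammaln(a))
        )

    def weights(self, y, eta, dispersion, robust=False):
        if not self.valid_mean(eta):
            return np.full_like(eta, np.nan)
        return 1.0 / eta ** 2  # = mu^2

    def dispersion(self, y, eta, n_params):
        # marginal ML fit of the target series (gamfit analogue)
        shape, _, _ = stats.gamma.fit(y, floc=0)
        return max(1.0 / shape, _EPS)

    def _init_mu(self, y):
        return np.maximum(y, _EPS)

    def _link(self, mu):
        return 1.0 / mu

    def _dlink(self, mu):
        return -1.0 / mu ** 2

    def _variance(self, mu):
        return mu ** 2

    def _clip_mu(self, mu):
        return np.clip(mu, 1e-6, 1e8)

    def deviance(self, y, mu):
        return float(2 * np.sum(-np.log(y / mu) + (y - mu) / mu))


class InverseGaussian(Family):
    """Inverse-Gaussian with identity mean mu_t = eta_t (> 0 required) and
    dispersion xi (inverse shape); variance xi * mu^3."""

    name = "inverse_gaussian"

    def mean(self, eta):
        return eta

    def valid_mean(self, eta):
        return bool(np.all(eta > 0))

    def null_mean(self, y):
        return np.full_like(y, float(np.mean(y)))

    def log_likelihood(self, y, eta, dispersion):
        if not self.valid_mean(eta):
            return -np.inf
        mu = eta
        return float(
            np.sum(-0.5 * np.log(2 * np.pi * dispersion * y ** 3)
                   - (y - mu) ** 2 / (2 * dispersion * mu ** 2 * y))
        )

    def weights(self, y, eta, dispersion, robust=False):
        if not self.valid_mean(eta):
            return np.full_like(eta, np.nan)
        return 1.0 / eta  # = 1/mu

    def dispersion(self, y, eta, n_params):
        mu = np.clip(eta, _EPS, None)
        return max(float(np.mean((y - mu) ** 2 / (mu ** 2 * y))), _EPS)

    def _init_mu(self, y):
        return np.maximum(y, _EPS)

    def _link(self, mu):
        return mu

    def _dlink(self, mu):
        return np.ones_like(mu)

    def _variance(self, mu):
        return mu ** 3

    def _clip_mu(self, mu):
        return np.clip(mu, 1e-6, None)

    def deviance(self, y, mu):
        return float(np.sum((y - mu) ** 2 / (mu ** 2 * y)))


FAMILIES: dict[str, Family] = {
    f.name: f for f in (Gaussian(), Binomial(), Poisson(), Gamma(), InverseGaussian())
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(FAMILIES)}")


def fit_mle(design: DesignMatrix, family: Family, *, tol: float = 1e-8,
            max_iter: int = 100, dispersion: float | None = None) -> GLMFit:
    """Intercept-free maximum-likelihood fit of ``y ~ family(X beta')`` by IRLS.

    Convergence: relative change in deviance below ``tol``.  Degenerate or
    separable problems return the best iterate flagged ``converged=False``;
    rank-deficient weighted solves fall back to a tiny ridge jitter.

    Parameters
    ----------
    dispersion : float, optional
        Fixed dispersion (e.g. the per-target gamma kappa); if omitted it is
        estimated from the final fit via :meth:`Family.dispersion`.
    """
    X, y = design.X, design.target_vector
    m, q = X.shape
    if q == 0:
        mu = family.null_mean(y)
        phi = dispersion if dispersion is not None else _null_dispersion(family, y, mu)
        return GLMFit(np.empty(0), phi, True, 0)

    mu = family._clip_mu(family._init_mu(y))
    beta = np.zeros(q)
    dev = family.deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = family._dlink(mu)
        z = family._link(mu) + (y - mu) * g
        w = 1.0 / (family._variance(mu) * g ** 2)
        w = np.clip(w, _EPS, 1e10)
        sw = np.sqrt(w)
        A = X * sw[:, None]
        b = z * sw
        beta_new, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not np.all(np.isfinite(beta_new)):
            # ridge jitter for degenerate columns
            G = A.T @ A + 1e-8 * np.eye(q)
            beta_new = np.linalg.solve(G, A.T @ b)
        eta = X @ beta_new
        mu = family._clip_mu(family.mean(eta))
        dev_new = family.deviance(y, mu)
        beta = beta_new
        if not np.isfinite(dev_new):
            break
        if abs(dev_new - dev) <= tol * (abs(dev) + tol):
            converged = True
            dev = dev_new
            break
        dev = dev_new

    eta = X @ beta
    if dispersion is not None:
        phi = dispersion
    else:
        phi = family.dispersion(y, eta, q)
    return GLMFit(beta, phi, converged, it)


def _null_dispersion(family: Family, y: np.ndarray, mu: np.ndarray) -> float:
    if family.name == "gaussian":
        return max(float(np.mean((y - mu) ** 2)), _EPS)
    if family.name == "binomial":
        return 1.0
    if family.name == "poisson":
        return family.dispersion(y, np.log(np.clip(mu, _EPS, None)), 0)
    if family.name == "gamma":
        return family.dispersion(y, 1.0 / mu, 0)
    return family.dispersion(y, mu, 0)


def log_likelihood(family: Family, design: DesignMatrix, beta: np.ndarray,
                   dispersion: float) -> float:
    """Exact log-likelihood L_i at the given coefficients and dispersion."""
    y = design.target_vector
    if design.n_cols == 0 or beta.size == 0:
        return _null_log_likelihood(family, y, dispersion)
    eta = design.X @ np.asarray(beta, dtype=float)
    return family.log_likelihood(y, eta, dispersion)


def _null_log_likelihood(family: Family, y: np.ndarray, dispersion: float) -> float:
    mu = family.null_mean(y)
    if family.name == "gaussian":
        return family.log_likelihood(y, mu, dispersion)
    if family.name == "binomial":
        return family.log_likelihood(y, np.zeros_like(y), dispersion)
    if family.name == "poisson":
        return family.log_likelihood(y, np.zeros_like(y), dispersion)
    if family.name == "gamma":
        return family.log_likelihood_mu(y, mu, dispersion)
    return family.log_likelihood(y, mu, dispersion)  # inverse_gaussian, identity mean


def weight_matrix(family: Family, design: DesignMatrix, beta: np.ndarray,
                  dispersion: float = 1.0, robust: bool = False) -> np.ndarray:
    """Diagonal of the (n-d) x (n-d) Fisher weight matrix W_i at beta."""
    if design.n_cols == 0 or np.asarray(beta).size == 0:
        eta = _null_eta(family, design.target_vector)
    else:
        eta = design.X @ np.asarray(beta, dtype=float)
    return family.weights(design.target_vector, eta, dispersion, robust=robust)


def _null_eta(family: Family, y: np.ndarray) -> np.ndarray:
    mu = family.null_mean(y)
    if family.name in ("gaussian", "inverse_gaussian"):
        return mu
    if family.name == "gamma":
        return 1.0 / mu
    return np.zeros_like(y)  # binomial / poisson: eta = 0


def estimate_dispersion(family: Family, design: DesignMatrix, fit: GLMFit) -> float:
    """Per-family dispersion estimate phi-hat at the fitted coefficients."""
    y = design.target_vector
    if design.n_cols == 0:
        mu = family.null_mean(y)
        return _null_dispersion(family, y, mu)
    eta = design.X @ fit.beta
    return family.dispersion(y, eta, design.n_cols)
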