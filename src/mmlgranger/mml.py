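"""MML87 message-length code for a candidate parent set.

For a target series with log-likelihood :math:`L_i`, ML coefficients
:math:`\\hat\\beta_i` (length :math:`d k_i`), dispersion
:math:`\\hat\\phi_i`, Fisher weight diagonal :math:`W_i` and ridge
hyperparameter :math:`\\lambda_i`, the message length of the candidate set
:math:`\\gamma_i` with :math:`k_i` selected series is

.. math::

    \\mathrm{MML} = -L_i + \\tfrac12 \\log\\det(X_i' W_i X_i + \\lambda_i I)
        + \\tfrac{k_i}{2}\\log(2\\pi\\lambda_i)
        + \\tfrac{\\lambda_i}{2\\hat\\phi_i}\\hat\\beta_i\\hat\\beta_i'
        + \\tfrac12\\log(n-d) - \\tfrac{k_i+1}{2}\\log(2\\pi)
        + \\tfrac12\\log((k_i+1)\\pi)

plus the structure code :math:`I(\\gamma_i) = \\log\\binom{p}{k_i} +
\\log(p+1)`.  The HMML score of the set is the minimum of this total over
:math:`\\lambda_i` in the box :math:`H = [0.1, 1000]`, with
:math:`\\hat\\beta_i, \\hat\\phi_i` held fixed during the search.  All
message lengths are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .families import Family, GLMFit, estimate_dispersion, fit_mle, log_likelihood, weight_matrix
from .panel import CandidateSet, DesignMatrix, subset_design


@dataclass
class MMLScore:
    """Decomposed message length for one (target, subset, lambda)."""

    neg_log_lik: float
    fisher_logdet: float
    prior_terms: float
    constant_terms: float
    structure_code: float
    lam: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.neg_log_lik + self.fisher_logdet + self.prior_terms
                      + self.constant_terms + self.structure_code)

    def to_record(self) -> dict:
        return {
            "neg_log_lik": self.neg_log_lik,
            "fisher_logdet": self.fisher_logdet,
            "prior_terms": self.prior_terms,
            "constant_terms": self.constant_terms,
            "structure_code": self.structure_code,
            "lambda": self.lam,
            "total": self.total,
        }


@dataclass(frozen=True)
class LambdaSearch:
    """Hyperparameter search box and simplex settings for the ridge lambda."""

    lo: float = 0.1
    hi: float = 1000.0
    n_grid: int = 13
    tol: float = 1e-6
    max_iter: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("lambda search domain must satisfy 0 < lo < hi")


def structure_code(p: int, k: int, *, product_form: bool = False) -> float:
    """Cost in nats of stating which k of p series are selected.

    ``I(gamma) = log C(p, k) + log(p + 1)``; ``product_form=True`` uses
    ``log(p*k)`` in place of the binomial coefficient (degenerate at k=0,
    where it falls back to 0).
    """
    if not 0 <= k <= p:
        raise ValueError("need 0 <= k <= p")
    if product_form:
        first = np.log(p * k) if k > 0 else 0.0
    else:
        first = float(special.gammaln(p + 1) - special.gammaln(k + 1)
                      - special.gammaln(p - k + 1))
    return first + np.log(p + 1.0)


def mml_code(design: DesignMatrix, fit: GLMFit, family: Family, lam: float,
             *, k: int | None = None, robust: bool = False,
             count_coefficients: bool = False) -> MMLScore:
    """Assemble the message-length decomposition at a fixed lambda.

    Parameters
    ----------
    k : int, optional
        Number of selected series; inferred as n_cols/d when omitted.
    count_coefficients : bool
        Use d*k (the coefficient count) instead of k in the prior and
        constant terms.  Default keeps k, the selected-series count.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    m = design.n_rows
    if k is None:
        k = design.n_cols // design.d
    k_eff = design.n_cols if count_coefficients else k

    L = log_likelihood(family, design, fit.beta, fit.dispersion)
    sc = structure_code(design.p, k)
    if not np.isfinite(L):
        # domain-violating mean: candidate rejected outright
        s = MMLScore(np.inf, 0.0, 0.0, 0.0, sc, lam)
        return s

    if design.n_cols == 0:
        fisher = 0.0  # det of the empty matrix is 1
        prior = 0.0
    else:
        w = weight_matrix(family, design, fit.beta, fit.dispersion, robust=robust)
        A = design.X.T @ (design.X * w[:, None])
        A[np.diag_indices_from(A)] += lam
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'WX + lambda*I not positive definite")
        fisher = 0.5 * logdet
        prior = (k_eff / 2.0) * np.log(2 * np.pi * lam) \
            + (lam / (2.0 * fit.dispersion)) * float(fit.beta @ fit.beta)
    const = (0.5 * np.log(m) - (k_eff + 1) / 2.0 * np.log(2 * np.pi)
             + 0.5 * np.log((k_eff + 1) * np.pi))
    return MMLScore(-L, fisher, prior, const, sc, lam)


def _lambda_profile(design: DesignMatrix, fit: GLMFit, family: Family,
                    robust: bool, count_coefficients: bool):
    """Precompute the eigenvalues of X'WX so the lambda search is O(dk) per
    evaluation: log det(X'WX + lam I) = sum log(eig_j + lam)."""
    k = design.n_cols // design.d
    k_eff = design.n_cols if count_coefficients else k
    m = design.n_rows
    L = log_likelihood(family, design, fit.beta, fit.dispersion)
    sc = structure_code(design.p, k)
    const = (0.5 * np.log(m) - (k_eff + 1) / 2.0 * np.log(2 * np.pi)
             + 0.5 * np.log((k_eff + 1) * np.pi))
    if not np.isfinite(L):
        return None
    if design.n_cols == 0:
        return lambda lam: -L + const + sc
    w = weight_matrix(family, design, fit.beta, fit.dispersion, robust=robust)
    A = design.X.T @ (design.X * w[:, None])
    eig = np.linalg.eigvalsh(0.5 * (A + A.T))
    bb = float(fit.beta @ fit.beta)
    phi = fit.dispersion

    def total(lam: float) -> float:
        vals = eig + lam
        if np.any(vals <= 0):
            return np.inf
        return (-L + 0.5 * float(np.sum(np.log(vals)))
                + (k_eff / 2.0) * np.log(2 * np.pi * lam)
                + (lam / (2.0 * phi)) * bb + const + sc)

    return total


def hmml(design_full: DesignMatrix, cand: CandidateSet, family: Family,
         search: LambdaSearch = LambdaSearch(), *,
         dispersion: float | None = None, robust: bool = False,
         count_coefficients: bool = False,
         return_detail: bool = False):
    """Lambda-minimized message length of one candidate set (its HMML score).

    The ML fit and dispersion are computed once for the candidate
    (Algorithm-1 ordering) and held fixed while lambda is minimized over
    the box by a coarse log-grid scan followed by a Nelder-Mead simplex on
    log(lambda), clamped to the box.

    Returns the scalar score, or ``(score, MMLScore, GLMFit)`` when
    ``return_detail`` is set.  Infeasible candidates (mean-domain
    violations at the fit) score ``+inf``.
    """
    design = subset_design(design_full, cand)
    fit = fit_mle(design, family, dispersion=dispersion)
    total = _lambda_profile(design, fit, family, robust, count_coefficients)
    if total is None:
        if return_detail:
            return np.inf, None, fit
        return np.inf

    if design.n_cols == 0:
        lam_best = search.lo
        best = total(lam_best)
    else:
        grid = np.geomspace(search.lo, search.hi, search.n_grid)
        vals = [total(l) for l in grid]
        i0 = int(np.argmin(vals))
        lam0, best = grid[i0], vals[i0]

        lo_u, hi_u = np.log(search.lo), np.log(search.hi)

        def obj(u):
            return total(float(np.exp(np.clip(u[0], lo_u, hi_u))))

        res = optimize.minimize(obj, x0=[np.log(lam0)], method="Nelder-Mead",
                                options={"xatol": search.tol, "fatol": search.tol,
                                         "maxiter": search.max_iter})
        lam_nm = float(np.exp(np.clip(res.x[0], lo_u, hi_u)))
        val_nm = total(lam_nm)
        if val_nm < best:
            lam_best, best = lam_nm, val_nm
        else:
            lam_best = lam0

    if return_detail:
        k = design.n_cols // design.d
        score = mml_code(design, fit, family, lam_best, k=k, robust=robust,
                         count_coefficients=count_coefficients)
        return best, score, fit
    return best
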