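"""Sum-of-single-effects variational fine-mapping on z-scores and LD.

The multi-causal flavour relaxes the one-causal-variant assumption using the
sum-of-single-effects (SuSiE) model: the block's joint effect vector (on the
z-score scale) is a sum of L "single effect" vectors, each of which has
exactly one non-zero coordinate.  Working from summary data, the z-scores of
a block with LD matrix R are modelled as

    z ~ N(R b, R),    b = sum_l b_l,    b_l = gamma_l * mu_l,

with gamma_l a one-hot indicator (prior pi over variants) and the non-zero
effect mu_l ~ N(0, sigma0_l^2).  Fitting is coordinate ascent on a
variational approximation that factorizes over components: for each
component in turn, the other components' posterior-mean effects are
regressed out of z, a single-effect regression (SER) is fitted to the
residual z-scores in closed form via per-variant Wakefield Bayes factors,
and (optionally, "auto" prior) the component's prior variance sigma0_l^2 is
set by maximizing the SER marginal likelihood, with 0 allowed (component
switched off).

The objective ("ELBO") is the evidence lower bound of the equivalent
sufficient-statistic regression (X'X = R, X'y = z, residual variance 1), up
to an additive constant that is unknowable from z and R alone; it is
non-decreasing across iterations and its change is the convergence
criterion.  The fitter is deterministic: all components start at zero.

The per-variant posterior inclusion probability is
PIP_i = 1 - prod_l (1 - alpha_{l,i}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

logger = logging.getLogger(__name__)


@dataclass
class SusieFit:
    """Variational fit of the sum-of-single-effects model for one block.

    alpha, mu, mu2 are L x p: per-component inclusion probabilities and
    posterior first/second moments of the (z-scale) effect given inclusion.
    ``prior_variances`` is the per-component sigma0^2 (L,) for scalar priors
    or (L, p) when a per-variant informed prior was supplied.
    """

    alpha: np.ndarray
    mu: np.ndarray
    mu2: np.ndarray
    prior_variances: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    prior_weights: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.alpha.shape[0]

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    @property
    def posterior_mean(self) -> np.ndarray:
        """Posterior mean z-scale effect per variant, summed over components."""
        return (self.alpha * self.mu).sum(axis=0)


def pip(fit: SusieFit, prior_tol: float = 1e-9) -> np.ndarray:
    """Posterior inclusion probability: 1 - prod_l (1 - alpha_{l,i}).

    Components whose prior variance was driven (numerically) to zero carry
    no effect — their alpha row is the flat prior — and are excluded from
    the product, as is standard for sum-of-single-effects PIPs.
    """
    pv = np.atleast_1d(fit.prior_variances)
    active = pv.max(axis=-1) > prior_tol if pv.ndim == 2 else pv > prior_tol
    if not np.any(active):
        return np.zeros(fit.p)
    return 1.0 - np.prod(1.0 - fit.alpha[active], axis=0)


def _ser(z_resid: np.ndarray, v: np.ndarray, log_pw: np.ndarray):
    """Closed-form single-effect regression on residual z-scores.

    Observations have unit variance (diag(R)=1, residual variance 1), so per
    variant the Wakefield log-BF under prior N(0, v_j) is
    -0.5*log(1+v_j) + 0.5*z_j^2*v_j/(1+v_j).
    Returns (alpha, mu, post_var, lbf, log marginal likelihood).
    """
    shrink = v / (1.0 + v)  # posterior variance, also the shrinkage factor
    lbf = -0.5 * np.log1p(v) + 0.5 * z_resid ** 2 * shrink
    logw = log_pw + lbf
    loglik = logsumexp(logw)
    alpha = np.exp(logw - loglik)
    mu = shrink * z_resid
    return alpha, mu, shrink, lbf, loglik


def _optimize_prior_variance(z_resid: np.ndarray, log_pw: np.ndarray) -> float:
    """Maximize the SER marginal likelihood over sigma0^2 >= 0.

    Returns 0 when switching the component off is at least as good (the
    marginal likelihood at sigma0^2=0 is exactly logsumexp(log_pw) = 0 for
    normalized weights).
    """

    def neg_loglik(log_v: float) -> float:
        v = np.exp(log_v)
        shrink = v / (1.0 + v)
        lbf = -0.5 * np.log1p(v) + 0.5 * z_resid ** 2 * shrink
        return -float(logsumexp(log_pw + lbf))

    res = minimize_scalar(neg_loglik, bounds=(-30.0, 15.0), method="bounded",
                          options={"xatol": 1e-8})
    best = float(np.exp(res.x))
    # compare against the switched-off component (loglik exactly 0)
    if -res.fun <= 0.0 or best < 1e-12:
        return 0.0
    return best


def susie_rss(
    z,
    R,
    L: int = 10,
    prior_variance=1.0,
    estimate_prior_variance: bool = False,
    prior_weights=None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> SusieFit:
    """Fit the sum-of-single-effects model to one block's z-scores.

    Parameters
    ----------
    z : array (p,)
        Per-variant z-scores (beta/se).
    R : array (p, p) or LDMatrix
        Correlation matrix with unit diagonal, PSD (repair upstream).
    L : int
        Number of single-effect components; capped at p.
    prior_variance : float or array (p,)
        Initial (auto) or fixed (informed) prior effect variance on the z
        scale.  A per-variant array encodes an effect-scale W via W/se^2.
    estimate_prior_variance : bool
        If True, each component's scalar sigma0^2 is re-optimized every
        iteration by maximizing its single-effect marginal likelihood
        (optimum 0 allowed: component inert).
    prior_weights : array (p,), optional
        Within-block prior over which variant a component selects; uniform
        by default.
    tol, max_iter
        Convergence is declared when the objective changes by less than
        ``tol`` between iterations; hitting ``max_iter`` first returns a
        partial fit with ``converged=False`` and a warning (some LD blocks
        genuinely need many iterations).
    """
    R = getattr(R, "R", R)  # accept LDMatrix
    z = np.asarray(z, dtype=float)
    R = np.asarray(R, dtype=float)
    p = z.size
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    if R.shape != (p, p):
        raise ValueError("dim(R) must match length(z)")
    if not (1 <= L):
        raise ValueError("L must be >= 1")
    L = min(L, p)

    if prior_weights is None:
        log_pw = np.full(p, -np.log(p))
    else:
        pw = np.asarray(prior_weights, dtype=float)
        pw = pw / pw.sum()
        with np.errstate(divide="ignore"):
            log_pw = np.log(pw)

    per_variant_prior = np.ndim(prior_variance) == 1
    if per_variant_prior:
        if estimate_prior_variance:
            raise ValueError("per-variant prior variance cannot be combined with auto estimation")
        V0 = np.broadcast_to(np.asarray(prior_variance, dtype=float), (L, p)).copy()
    else:
        V0 = np.full((L, p), float(prior_variance))
    sigma0 = V0[:, 0].copy()  # scalar per component (auto mode bookkeeping)

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    s2 = np.zeros((L, p))
    b = np.zeros((L, p))  # alpha * mu per component
    Rb = np.zeros(p)      # R @ total posterior mean
    elbo_trace: list[float] = []
    converged = False

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for l in range(L):
            Rb -= R @ b[l]
            z_resid = z - Rb
            if estimate_prior_variance:
                sigma0[l] = _optimize_prior_variance(z_resid, log_pw)
                V0[l, :] = sigma0[l]
            v = V0[l]
            if np.all(v == 0.0):
                alpha[l] = np.exp(log_pw)
                mu[l] = 0.0
                s2[l] = 0.0
            else:
                alpha[l], mu[l], s2[l], _, _ = _ser(z_resid, v, log_pw)
            b[l] = alpha[l] * mu[l]
            Rb += R @ b[l]
        elbo_trace.append(_elbo(z, R, alpha, mu, s2, V0, log_pw))
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break
    if not converged:
        logger.warning("susie_rss did not converge in %d iterations (last objective change %.3g)",
                       max_iter, abs(elbo_trace[-1] - elbo_trace[-2]) if len(elbo_trace) > 1 else np.nan)

    mu2 = mu ** 2 + s2
    prior_variances = V0 if per_variant_prior else sigma0.copy()
    return SusieFit(
        alpha=alpha, mu=mu, mu2=mu2, prior_variances=prior_variances,
        elbo_trace=np.asarray(elbo_trace), converged=converged, n_iter=n_iter,
        prior_weights=np.exp(log_pw),
    )


def _elbo(z, R, alpha, mu, s2, V0, log_pw) -> float:
    """Evidence lower bound of the sufficient-stat regression (sigma^2=1),
    up to an additive constant (the unobservable y'y term is set to p)."""
    p = z.size
    b_l = alpha * mu                      # (L, p)
    b_bar = b_l.sum(axis=0)
    e_b2 = (alpha * (mu ** 2 + s2)).sum()  # sum_l sum_j E[b_lj^2], diag(R)=1
    quad = float(b_bar @ R @ b_bar) - float(np.einsum("lp,pq,lq->", b_l, R, b_l))
    erss = p - 2.0 * float(b_bar @ z) + quad + e_b2
    kl = 0.0
    for l in range(alpha.shape[0]):
        v = V0[l]
        if np.all(v == 0.0):
            continue
        a = alpha[l]
        nz = a > 0
        kl_alpha = float(np.sum(a[nz] * (np.log(a[nz]) - log_pw[nz])))
        with np.errstate(divide="ignore", invalid="ignore"):
            kl_normal = 0.5 * (np.log1p(v) + (s2[l] + mu[l] ** 2) / v - 1.0)
        kl += kl_alpha + float(np.sum(a[nz] * kl_normal[nz]))
    return -0.5 * erss - kl
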