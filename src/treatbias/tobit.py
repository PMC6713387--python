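"""Gaussian linear regression with subject-specific right censoring.

Treated subjects' phenotype measurements are viewed as right-censored
observations of the untreated phenotype they would have shown: the latent
value is known only to exceed the observed one.  Censored rows contribute
survivor-function terms log S((y - mu)/sigma) to the likelihood, uncensored
rows contribute density terms.  Maximised by quasi-Newton iteration with an
analytic gradient; the covariance of the estimates comes from the observed
information, with per-row score contributions exposed for sandwich /
clustered variance estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr
from statsmodels.tools.numdiff import approx_hess2

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class TobitFit:
    """Result of one censored-regression maximum-likelihood fit.

    ``params`` is (beta..., log_sigma); ``cov`` the inverse observed
    information on that parameter scale; ``score_rows`` the per-observation
    score contributions at the optimum (rows sum to ~0 at convergence).
    """

    params: np.ndarray
    cov: np.ndarray | None
    score_rows: np.ndarray | None
    loglik: float
    converged: bool
    n_censored: int

    @property
    def beta(self):
        return self.params[:-1]

    @property
    def sigma(self):
        return float(np.exp(self.params[-1]))


def _score_rows(params, y, X, cens):
    """Per-row gradient of the log-likelihood w.r.t. (beta, log_sigma)."""
    beta, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    z = (y - X @ beta) / s
    n, k = X.shape
    dmu = np.empty(n)
    dls = np.empty(n)
    unc = ~cens
    # density rows: d/dmu = z/s ; d/dlog s = z^2 - 1
    dmu[unc] = z[unc] / s
    dls[unc] = z[unc] ** 2 - 1.0
    # survivor rows: hazard h = phi(z)/S(z); d/dmu = h/s ; d/dlog s = h z
    if cens.any():
        zc = z[cens]
        log_phi = -0.5 * zc**2 - _LOG_SQRT_2PI
        h = np.exp(log_phi - log_ndtr(-zc))
        dmu[cens] = h / s
        dls[cens] = h * zc
    out = np.empty((n, k + 1))
    out[:, :k] = X * dmu[:, None]
    out[:, k] = dls
    return out


def _negloglik(params, y, X, cens):
    beta, log_s = params[:-1], params[-1]
    s = np.exp(log_s)
    z = (y - X @ beta) / s
    ll = 0.0
    unc = ~cens
    if unc.any():
        zu = z[unc]
        ll += np.sum(-0.5 * zu**2 - _LOG_SQRT_2PI - log_s)
    if cens.any():
        ll += np.sum(log_ndtr(-z[cens]))
    return -ll


def _neggrad(params, y, X, cens):
    return -_score_rows(params, y, X, cens).sum(axis=0)


def tobit_fit(y, X, censored, max_iter=200, gtol=1e-8) -> TobitFit:
    """Fit the right-censored Gaussian regression of ``y`` on ``X``.

    ``censored`` marks rows whose observed value is a lower bound of the
    latent outcome.  Initialised from the all-rows least-squares fit.
    Returns a non-converged :class:`TobitFit` (``converged=False``) rather
    than raising when the optimiser fails, all rows are censored, or the
    design is singular.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    n, k = X.shape
    bad = TobitFit(
        params=np.full(k + 1, np.nan),
        cov=None,
        score_rows=None,
        loglik=np.nan,
        converged=False,
        n_censored=int(cens.sum()),
    )
    if cens.all() or n <= k:
        return bad
    if np.linalg.matrix_rank(X) < k:
        return bad
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sd0 = float(np.sqrt(resid @ resid / max(n - k, 1)))
    x0 = np.concatenate([beta0, [np.log(max(sd0, 1e-8))]])

    res = optimize.minimize(
        _negloglik,
        x0,
        args=(y, X, cens),
        jac=_neggrad,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    # Newton polish: BFGS often stops on precision loss with the gradient
    # already tiny; a few Newton steps with the numeric Hessian finish the
    # job (and the Hessian is needed for the covariance anyway).
    x = res.x
    fval = float(res.fun)
    hess = approx_hess2(x, _negloglik, args=(y, X, cens))
    for _ in range(10):
        grad = _neggrad(x, y, X, cens)
        if np.max(np.abs(grad)) <= gtol * (1.0 + abs(fval)):
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        trial, scale = x, 1.0
        for _ in range(20):
            cand = x + scale * step
            fcand = _negloglik(cand, y, X, cens)
            if fcand <= fval:
                trial, fval = cand, float(fcand)
                break
            scale *= 0.5
        if trial is x:
            break
        x = trial
        hess = approx_hess2(x, _negloglik, args=(y, X, cens))
    grad_norm = float(np.max(np.abs(_neggrad(x, y, X, cens))))
    # scale-aware convergence: the log-likelihood is a sum over n rows
    if not (grad_norm <= 1e-6 * (1.0 + abs(fval))):
        return bad
    res_x = x
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return bad
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return bad
    return TobitFit(
        params=res_x,
        cov=cov,
        score_rows=_score_rows(res_x, y, X, cens),
        loglik=-fval,
        converged=True,
        n_censored=int(cens.sum()),
    )
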