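"""Treatment-modelling strategies for genetic quantitative-trait analyses.

All eight strategies share one contract: they take a long-format cohort
table (one row per subject and period, columns ``subject_id, genotype,
period, treatment, confounder, phenotype``) and return an
:class:`EstimatorResult` for the life-time genetic effect gamma -- the
association of the variant with the final phenotype when treatment is held
at its reference level -- except for the prior-to-treatment estimator,
which targets the baseline effect lambda_0.

Strategies
----------
marginal
    Final phenotype regressed on genotype alone; the traditional model.
conditional1
    Period-specific regressions on genotype and lagged treatment, ignoring
    confounders and phenotype history; gamma estimated by summing the T
    period effects.
conditional2
    Period-specific regressions additionally conditioning on the lagged
    confounder and phenotype; gamma composed through the first-order
    Markov recursion (see :func:`compose_lifetime`).
conditional3
    conditional2 plus a genotype-by-treatment interaction; the genetic
    main effect targets the treatment reference level.
untreated
    Per-period marginal fits restricted to then-untreated subjects.
constant
    An out-of-sample treatment-effect estimate is added back to treated
    subjects' phenotypes before per-period marginal fits.
censored
    Per-period censored (Tobit-type) regression treating treated subjects'
    values as right-censored observations of their untreated level.
prior_to_treatment
    Baseline phenotype on genotype; targets lambda_0, not gamma.

The strategies that sum per-period effects report, by default, standard
errors from subject-level influence functions aggregated across periods
("cluster"): the same subjects enter every period fit and the per-period
estimates are correlated whenever the fitted models omit the phenotype
history, so independence-summed variances would understate the sampling
variance even under the strict null.  For the censored fits this likewise
yields sandwich standard errors, which remain valid although the censoring
model is misspecified under informative treatment assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tobit import tobit_fit

__all__ = [
    "EstimatorResult",
    "PeriodFit",
    "LinearFit",
    "fit_linear",
    "fit_marginal",
    "fit_conditional1",
    "fit_conditional2",
    "fit_conditional3",
    "fit_untreated",
    "fit_constant",
    "fit_censored",
    "fit_prior_to_treatment",
    "compose_lifetime",
    "estimate_all",
    "results_to_frame",
    "STRATEGIES",
    "STRATEGY_NAMES",
]

_Z95 = float(stats.norm.ppf(0.975))

GAMMA = "gamma_lifetime"
LAMBDA0 = "lambda_baseline"


# ---------------------------------------------------------------------------
# results


@dataclass
class EstimatorResult:
    """Point estimate, Wald inference and target label for one strategy."""

    strategy: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float
    estimand: str
    failed: bool = False

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "estimate": self.estimate,
            "std_error": self.std_error,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "estimand": self.estimand,
            "failed": self.failed,
        }


def _failed(strategy, estimand) -> EstimatorResult:
    nan = float("nan")
    return EstimatorResult(strategy, nan, nan, nan, nan, nan, estimand, True)


def _result(strategy, estimand, est, se) -> EstimatorResult:
    if not (np.isfinite(est) and np.isfinite(se) and se > 0):
        return _failed(strategy, estimand)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EstimatorResult(
        strategy,
        float(est),
        float(se),
        float(est - _Z95 * se),
        float(est + _Z95 * se),
        float(p),
        estimand,
        False,
    )


# ---------------------------------------------------------------------------
# least-squares backend


@dataclass
class LinearFit:
    beta: np.ndarray
    cov: np.ndarray | None
    resid: np.ndarray
    sigma2: float
    xtx_inv: np.ndarray | None
    rank_deficient: bool


def fit_linear(y, X) -> LinearFit:
    """Ordinary least squares with classical covariance.

    A singular or rank-deficient cross-product is flagged
    (``rank_deficient=True``, ``cov=None``) instead of raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if rank < k or n <= k:
        return LinearFit(beta, None, resid, np.nan, None, True)
    sigma2 = float(resid @ resid / (n - k))
    xtx_inv = np.linalg.inv(X.T @ X)
    return LinearFit(beta, sigma2 * xtx_inv, resid, sigma2, xtx_inv, False)


# ---------------------------------------------------------------------------
# wide view of the cohort table


@dataclass
class _Wide:
    G: np.ndarray
    Y: np.ndarray
    D: np.ndarray
    U: np.ndarray | None
    n: int
    T: int

    def take(self, idx) -> "_Wide":
        return _Wide(
            self.G[idx],
            self.Y[idx],
            self.D[idx],
            None if self.U is None else self.U[idx],
            len(idx),
            self.T,
        )


def _as_wide(data: pd.DataFrame) -> _Wide:
    required = ["subject_id", "genotype", "period", "treatment", "phenotype"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    df = data.sort_values(["subject_id", "period"], kind="mergesort")
    periods = np.unique(df["period"].to_numpy())
    T = int(periods.max())
    if periods.min() != 0 or len(periods) != T + 1:
        raise ValueError("periods must be contiguous integers starting at 0")
    n_rows = len(df)
    if n_rows % (T + 1):
        raise ValueError("expected exactly one record per (subject, period)")
    n = n_rows // (T + 1)
    per = df["period"].to_numpy().reshape(n, T + 1)
    if not np.array_equal(per, np.tile(np.arange(T + 1), (n, 1))):
        raise ValueError("expected exactly one record per (subject, period)")
    sid = df["subject_id"].to_numpy().reshape(n, T + 1)
    if not (sid == sid[:, :1]).all():
        raise ValueError("expected exactly one record per (subject, period)")
    G = df["genotype"].to_numpy().reshape(n, T + 1)
    if not (G == G[:, :1]).all():
        raise ValueError("genotype must be constant within subject")
    Y = df["phenotype"].to_numpy(dtype=float).reshape(n, T + 1)
    D = df["treatment"].to_numpy(dtype=float).reshape(n, T + 1)
    U = None
    if "confounder" in df.columns:
        u = df["confounder"].to_numpy(dtype=float).reshape(n, T + 1)
        if np.isfinite(u).all():
            U = u
    return _Wide(G[:, 0].astype(float), Y, D, U, n, T)


def _usable(wide: _Wide) -> bool:
    return wide.n >= 3 and len(np.unique(wide.G)) >= 2


# ---------------------------------------------------------------------------
# per-period slope fits with subject-level influence functions


def _slope_fit(y, cols, rows, n_total):
    """OLS slope of ``y`` on genotype within ``rows``, extra columns pruned.

    ``cols`` is an ordered list of (name, full-length vector) with the
    genotype named ``"g"``.  Degenerate non-genotype columns are dropped;
    a degenerate genotype or rank-deficient design returns None.  Returns
    (slope, classical variance, influence vector over all subjects).
    """
    idx = np.arange(n_total) if rows is None else np.flatnonzero(rows)
    if idx.size < 3:
        return None
    names, arrs = [], []
    for name, v in cols:
        vv = np.asarray(v, dtype=float)[idx]
        if name != "g" and np.ptp(vv) == 0.0:
            continue
        names.append(name)
        arrs.append(vv)
    X = np.column_stack([np.ones(idx.size)] + arrs)
    if np.ptp(X[:, 1 + names.index("g")]) == 0.0:
        return None
    fit = fit_linear(y[idx], X)
    if fit.rank_deficient:
        return None
    j = 1 + names.index("g")
    lam = float(fit.beta[j])
    var = float(fit.cov[j, j])
    psi = np.zeros(n_total)
    psi[idx] = (X @ fit.xtx_inv[:, j]) * fit.resid
    return lam, var, psi


def _sum_periods(parts, se_method):
    """Sum per-period slopes; variance by cluster or independence rule."""
    est = float(sum(p[0] for p in parts))
    if se_method == "independent":
        var = float(sum(p[1] for p in parts))
    elif se_method == "cluster":
        psi_tot = np.sum([p[2] for p in parts], axis=0)
        var = float(psi_tot @ psi_tot)
    else:
        raise ValueError("se_method must be 'cluster' or 'independent'")
    return est, np.sqrt(var)


# ---------------------------------------------------------------------------
# simple single-period strategies


def fit_marginal(data: pd.DataFrame) -> EstimatorResult:
    """Last observed phenotype regressed on genotype alone."""
    wide = _as_wide(data)
    if not _usable(wide):
        return _failed("marginal", GAMMA)
    part = _slope_fit(wide.Y[:, -1], [("g", wide.G)], None, wide.n)
    if part is None:
        return _failed("marginal", GAMMA)
    return _result("marginal", GAMMA, part[0], np.sqrt(part[1]))


def fit_prior_to_treatment(data: pd.DataFrame) -> EstimatorResult:
    """Baseline phenotype on genotype; targets lambda_0, not gamma."""
    wide = _as_wide(data)
    if not _usable(wide):
        return _failed("prior_to_treatment", LAMBDA0)
    part = _slope_fit(wide.Y[:, 0], [("g", wide.G)], None, wide.n)
    if part is None:
        return _failed("prior_to_treatment", LAMBDA0)
    return _result("prior_to_treatment", LAMBDA0, part[0], np.sqrt(part[1]))


# ---------------------------------------------------------------------------
# summed per-period strategies (assume omega3 == 0)


def fit_conditional1(data: pd.DataFrame, se_method="cluster") -> EstimatorResult:
    """Per-period fits on genotype and lagged treatment, effects summed.

    A period in which everyone shares one treatment level degrades to a
    plain per-period marginal fit (the treatment column is dropped).
    """
    wide = _as_wide(data)
    if wide.T < 1 or not _usable(wide):
        return _failed("conditional1", GAMMA)
    parts = []
    for t in range(1, wide.T + 1):
        part = _slope_fit(
            wide.Y[:, t],
            [("g", wide.G), ("d", wide.D[:, t - 1])],
            None,
            wide.n,
        )
        if part is None:
            return _failed("conditional1", GAMMA)
        parts.append(part)
    return _result("conditional1", GAMMA, *_sum_periods(parts, se_method))


def fit_untreated(data: pd.DataFrame, se_method="cluster") -> EstimatorResult:
    """Per-period marginal fits restricted to then-untreated subjects."""
    wide = _as_wide(data)
    if wide.T < 1 or not _usable(wide):
        return _failed("untreated", GAMMA)
    parts = []
    for t in range(1, wide.T + 1):
        part = _slope_fit(
            wide.Y[:, t], [("g", wide.G)], wide.D[:, t - 1] == 0, wide.n
        )
        if part is None:
            return _failed("untreated", GAMMA)
        parts.append(part)
    return _result("untreated", GAMMA, *_sum_periods(parts, se_method))


def fit_constant(
    data: pd.DataFrame, correction: float = 10.0, se_method="cluster"
) -> EstimatorResult:
    """Add an assumed treatment effect back before per-period marginal fits.

    ``correction`` is the (out-of-sample) magnitude added to treated
    subjects' phenotypes, i.e. the negative of the assumed treatment
    effect; the default +10 matches a presumed effect of -10.
    """
    if not np.isfinite(correction):
        raise ValueError("correction must be finite")
    wide = _as_wide(data)
    if wide.T < 1 or not _usable(wide):
        return _failed("constant", GAMMA)
    parts = []
    for t in range(1, wide.T + 1):
        y = wide.Y[:, t] + correction * wide.D[:, t - 1]
        part = _slope_fit(y, [("g", wide.G)], None, wide.n)
        if part is None:
            return _failed("constant", GAMMA)
        parts.append(part)
    return _result("constant", GAMMA, *_sum_periods(parts, se_method))


def fit_censored(data: pd.DataFrame, se_method="cluster") -> EstimatorResult:
    """Per-period censored regressions of phenotype on genotype.

    Within each period, subjects treated during the preceding interval
    contribute right-censored observations (their untreated phenotype
    would have been at least as high); covariables are deliberately not
    modelled.  Per-period genetic effects are summed.
    """
    wide = _as_wide(data)
    if wide.T < 1 or not _usable(wide):
        return _failed("censored", GAMMA)
    X = np.column_stack([np.ones(wide.n), wide.G])
    parts = []
    for t in range(1, wide.T + 1):
        cens = wide.D[:, t - 1] == 1
        fit = tobit_fit(wide.Y[:, t], X, cens)
        if not fit.converged:
            return _failed("censored", GAMMA)
        lam = float(fit.beta[1])
        var = float(fit.cov[1, 1])
        psi = fit.score_rows @ fit.cov[:, 1]
        parts.append((lam, var, psi))
    return _result("censored", GAMMA, *_sum_periods(parts, se_method))


# ---------------------------------------------------------------------------
# conditional models with phenotype history, composed via the Markov chain


@dataclass
class PeriodFit:
    """Genetic and autoregressive effect of one analysed period.

    ``omega3_hat`` is identically 0 (with zero variance) for periods or
    strategies that do not model the lag; ``cov`` is the symmetric 2x2
    covariance block of (lambda_hat, omega3_hat).
    """

    period: int
    lambda_hat: float
    omega3_hat: float
    cov: np.ndarray


def compose_lifetime(fits, se_method="delta", resampler=None, n_boot=200):
    """Life-time genetic effect from period fits of a first-order Markov chain.

    With per-period direct effects lambda_t and autoregressive
    coefficients omega3_t, the effect of the variant on the final
    phenotype with treatment at its reference level is::

        gamma = lambda_T + sum_{t<T} lambda_t * prod_{s=t+1..T} omega3_s

    The cumulative product is the lag-1 path from Y_t to Y_T.  Standard
    error by the delta method over the period-specific estimates (whose
    independence across periods holds when each period's model conditions
    on the preceding phenotype) or, with ``se_method="bootstrap"``, as the
    standard deviation of composed estimates over ``n_boot`` calls of
    ``resampler`` (a callable returning a refitted PeriodFit sequence from
    one subject-level resample, as wired up by the conditional
    strategies).

    Returns ``(gamma_hat, std_error)``; raises ValueError when a period
    between 0 and T is missing.
    """
    fits = sorted(fits, key=lambda f: f.period)
    periods = [f.period for f in fits]
    T = periods[-1]
    if periods != list(range(T + 1)):
        raise ValueError(f"period fits must cover 0..T, got {periods}")
    lam = np.array([f.lambda_hat for f in fits])
    om3 = np.array([f.omega3_hat for f in fits])  # om3[0] unused
    # w[t] = prod_{s=t+1..T} om3[s]
    w = np.ones(T + 1)
    for t in range(T - 1, -1, -1):
        w[t] = w[t + 1] * om3[t + 1]
    gamma = float(lam @ w)

    if se_method == "bootstrap":
        if resampler is None:
            raise ValueError("bootstrap composition requires a resampler")
        ests = []
        for _ in range(n_boot):
            bf = resampler()
            if bf is None:
                continue
            ests.append(compose_lifetime(bf, se_method="delta")[0])
        if len(ests) < 2:
            return gamma, float("nan")
        return gamma, float(np.std(ests, ddof=1))
    if se_method != "delta":
        raise ValueError("se_method must be 'delta' or 'bootstrap'")

    var = 0.0
    for s in range(T + 1):
        dlam = w[s]
        if s == 0:
            dom3 = 0.0
        else:
            # gamma depends on om3[s] through every w[t] with t < s
            dom3 = 0.0
            for t in range(s):
                prod = 1.0
                for r in range(t + 1, T + 1):
                    if r != s:
                        prod *= om3[r]
                dom3 += lam[t] * prod
        grad = np.array([dlam, dom3])
        var += float(grad @ fits[s].cov @ grad)
    return gamma, float(np.sqrt(var))


def _conditional_period_fits(wide: _Wide, interaction: bool):
    """PeriodFit sequence for the confounder-adjusted conditional models."""
    if wide.U is None:
        return None
    base = _slope_fit(wide.Y[:, 0], [("g", wide.G)], None, wide.n)
    if base is None:
        return None
    fits = [PeriodFit(0, base[0], 0.0, np.diag([base[1], 0.0]))]
    for t in range(1, wide.T + 1):
        cols = [
            ("g", wide.G),
            ("d", wide.D[:, t - 1]),
            ("u", wide.U[:, t - 1]),
            ("yprev", wide.Y[:, t - 1]),
        ]
        if interaction:
            cols.append(("gd", wide.G * wide.D[:, t - 1]))
        names, arrs = [], []
        for name, v in cols:
            if name != "g" and np.ptp(v) == 0.0:
                continue
            names.append(name)
            arrs.append(v)
        X = np.column_stack([np.ones(wide.n)] + arrs)
        fit = fit_linear(wide.Y[:, t], X)
        if fit.rank_deficient:
            return None
        jg = 1 + names.index("g")
        cov = np.zeros((2, 2))
        cov[0, 0] = fit.cov[jg, jg]
        om3 = 0.0
        if "yprev" in names:
            jy = 1 + names.index("yprev")
            om3 = float(fit.beta[jy])
            cov[1, 1] = fit.cov[jy, jy]
            cov[0, 1] = cov[1, 0] = fit.cov[jg, jy]
        fits.append(PeriodFit(t, float(fit.beta[jg]), om3, cov))
    return fits


def _fit_conditional(name, data, interaction, se_method, n_boot, seed):
    wide = _as_wide(data)
    if wide.T < 1 or not _usable(wide):
        return _failed(name, GAMMA)
    fits = _conditional_period_fits(wide, interaction)
    if fits is None:
        return _failed(name, GAMMA)
    if se_method == "bootstrap":
        rng = np.random.default_rng(seed)

        def resampler():
            idx = rng.integers(0, wide.n, wide.n)
            return _conditional_period_fits(wide.take(idx), interaction)

        gamma, se = compose_lifetime(
            fits, se_method="bootstrap", resampler=resampler, n_boot=n_boot
        )
    else:
        gamma, se = compose_lifetime(fits, se_method=se_method)
    return _result(name, GAMMA, gamma, se)


def fit_conditional2(
    data: pd.DataFrame, se_method="delta", n_boot=200, seed=0
) -> EstimatorResult:
    """Period fits conditioning on lagged treatment, confounder and phenotype.

    Correctly specified under mediation and confounding (but not under a
    gene-by-treatment interaction); the life-time effect is composed
    through the Markov recursion.
    """
    return _fit_conditional("conditional2", data, False, se_method, n_boot, seed)


def fit_conditional3(
    data: pd.DataFrame, se_method="delta", n_boot=200, seed=0
) -> EstimatorResult:
    """conditional2 with a genotype-by-treatment interaction term.

    The reported period effects are the genotype main effects, i.e. the
    genetic association with treatment held at its reference level; when
    nobody is treated the interaction column is dropped and the fit
    coincides with conditional2.
    """
    return _fit_conditional("conditional3", data, True, se_method, n_boot, seed)


# ---------------------------------------------------------------------------
# registry


STRATEGIES = {
    "marginal": fit_marginal,
    "conditional1": fit_conditional1,
    "conditional2": fit_conditional2,
    "conditional3": fit_conditional3,
    "untreated": fit_untreated,
    "constant": fit_constant,
    "censored": fit_censored,
    "prior_to_treatment": fit_prior_to_treatment,
}

STRATEGY_NAMES = tuple(STRATEGIES)


def estimate_all(data, strategies=None, options=None):
    """Apply a set of strategies to one cohort; failures become rows.

    ``options`` maps strategy name to keyword arguments (e.g.
    ``{"constant": {"correction": 10.0}}``).  Unexpected exceptions are
    downgraded to failed results with a warning so that a replication run
    never aborts.
    """
    strategies = STRATEGY_NAMES if strategies is None else tuple(strategies)
    options = options or {}
    out = []
    for name in strategies:
        if name not in STRATEGIES:
            raise ValueError(f"unknown strategy {name!r}")
        estimand = LAMBDA0 if name == "prior_to_treatment" else GAMMA
        try:
            out.append(STRATEGIES[name](data, **options.get(name, {})))
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"strategy {name} raised {exc!r}; recorded as failed")
            out.append(_failed(name, estimand))
    return out


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
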