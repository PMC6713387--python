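"""Closed-form truths and bias decompositions.

The life-time genetic effect gamma of a scenario follows directly from the
generation recursion: with treatment at its reference level the phenotype
chain is linear in the genotype, so the effect of the variant on Y_T is
the direct effect at T plus every earlier direct effect propagated through
the lag-1 autoregressive coefficients.

For the two-period designs the expectation of the traditional marginal
estimator decomposes exactly.  Writing the slope as cov(Y_1, G)/var(G)::

    gamma* = lambda_1 + omega3 lambda_0          (= gamma)
             + omega1 * cov(D_0, G)/var(G)       (mediation)
             + omega4 * cov(G D_0, G)/var(G)     (interaction)

The mediation weight is the total genotype-to-treatment path coefficient
on the linear-probability scale (direct arrow plus the indirect route via
the baseline phenotype).  Because treatment follows a logistic model, that
coefficient has no closed form; it is computed numerically from one large
simulated cohort with the scenario's actual noise distribution (the
nonlinearity of the logistic link makes the coefficient depend on the
residual spread, so noise must not be suppressed).  Under randomization
the interaction weight reduces to the treated fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import ScenarioConfig, simulate_cohort

__all__ = [
    "BiasDecomposition",
    "true_gamma",
    "mediation_bias",
    "interaction_bias",
    "g_treatment_paths",
    "decompose",
]


@dataclass
class BiasDecomposition:
    """Truth and marginal-estimator expectation for a two-period scenario.

    ``gamma_star = gamma + mediation_term + interaction_term`` holds by
    construction of the covariance decomposition; the individual terms are
    validated against simulation in the test suite.
    """

    gamma: float
    gamma_star: float
    mediation_term: float
    interaction_term: float


def true_gamma(config: ScenarioConfig) -> float:
    """Life-time genetic effect with treatment at its reference level.

    gamma = lambda_T + sum_{t<T} lambda_t * prod_{s=t+1..T} omega3_s,
    defined on the generated effect scale (for a dominant generation the
    truth is the per-g_eff effect; evaluating additively coded estimators
    against it is the misspecification experiment).
    """
    T = config.n_periods
    lam = np.asarray(config.lambda_t)
    om3 = np.asarray(config.omega3_t)
    w = np.ones(T + 1)
    for t in range(T - 1, -1, -1):
        w[t] = w[t + 1] * om3[t]  # om3[t] multiplies Y_t into Y_{t+1}
    return float(lam @ w)


def mediation_bias(alpha_total: float, omega1: float) -> float:
    """Bias of the marginal estimator due to treatment mediation.

    ``alpha_total`` is the total genotype-to-treatment path coefficient on
    the linear-probability scale (see :func:`g_treatment_paths`).
    """
    return float(alpha_total * omega1)


def interaction_bias(
    lambda0: float, omega3: float, omega4: float, treated_fraction: float
) -> float:
    """Bias of the marginal estimator due to gene-by-treatment interaction.

    Under randomized treatment the interaction term omega4 * g * D
    projects onto the genotype with weight equal to the treated fraction,
    so the bias is ``omega4 * treated_fraction``.  ``lambda0`` and
    ``omega3`` are accepted because the classical two-period expectation
    is written in terms of them, but they enter gamma* and gamma equally
    and cancel from the bias.
    """
    if not (0.0 <= treated_fraction <= 1.0):
        raise ValueError("treated_fraction must be in [0, 1]")
    del lambda0, omega3
    return float(omega4 * treated_fraction)


def g_treatment_paths(config: ScenarioConfig, n=400_000, seed=1_000_003):
    """Numeric genotype-to-treatment path coefficients at baseline.

    Simulates one large cohort under ``config`` and returns
    ``(alpha_total, interaction_weight)`` where ``alpha_total`` is the
    linear-probability regression coefficient of D_0 on the genotype and
    ``interaction_weight = cov(G D_0, G)/var(G)`` is the projection weight
    of the interaction product onto the genotype.
    """
    big = config.replace(n_subjects=int(n), seed=int(seed))
    df = simulate_cohort(big)
    base = df[df["period"] == 0]
    g = base["genotype"].to_numpy(dtype=float)
    d = base["treatment"].to_numpy(dtype=float)
    vg = g.var()
    if vg == 0:
        return 0.0, 0.0
    alpha_total = float(np.cov(d, g, ddof=0)[0, 1] / vg)
    iw = float(np.cov(g * d, g, ddof=0)[0, 1] / vg)
    return alpha_total, iw


def decompose(config: ScenarioConfig, n=400_000, seed=1_000_003) -> BiasDecomposition:
    """Exact two-period decomposition of the marginal estimator's target.

    Only defined for two-period (T=1), additively generated scenarios;
    the path weights are computed numerically via
    :func:`g_treatment_paths`.
    """
    if config.n_periods != 1:
        raise ValueError("decompose is the two-period (T=1) decomposition")
    if config.genetic_model != "additive":
        raise ValueError("decompose requires additive generation")
    gamma = true_gamma(config)
    alpha_total, iw = g_treatment_paths(config, n=n, seed=seed)
    med = mediation_bias(alpha_total, config.omega1)
    inter = float(config.omega4 * iw)
    return BiasDecomposition(gamma, gamma + med + inter, med, inter)
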