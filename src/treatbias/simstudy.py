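"""Replication engine: run a scenario, apply strategies, score the results.

Each replication simulates one cohort (optionally masking unobserved
periods), applies the requested treatment-modelling strategies and records
their results; failures are data, never fatal.  Summaries score every
strategy against its own target: the prior-to-treatment estimator against
the baseline genetic effect lambda_0, all others against the life-time
effect gamma, both computed analytically from the scenario configuration.

Metrics per strategy over the effective (non-failed) replications:

bias
    mean(estimate) - truth
rmse
    sqrt(mean((estimate - truth)^2)), which satisfies
    rmse^2 = bias^2 + var(estimate)
coverage
    share of 95% confidence intervals containing the truth
rejection_rate
    share of replications with p < 0.05 (type-I error under the null,
    power under an alternative)

Replications use independently spawned child seeds from one master seed,
so results are reproducible and invariant to the worker count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analytic
from .dgp import ScenarioConfig, mask_observations, simulate_cohort
from .estimators import GAMMA, LAMBDA0, STRATEGY_NAMES, estimate_all

__all__ = [
    "run_replications",
    "truths_for",
    "summarise",
    "run_scenario",
    "reproduce_table",
    "format_summary",
]

RESULT_COLUMNS = (
    "rep",
    "strategy",
    "estimate",
    "std_error",
    "ci_low",
    "ci_high",
    "p_value",
    "estimand",
    "failed",
)


def _one_rep(config, strategies, options, child_seed, rep):
    rng = np.random.default_rng(child_seed)
    data = simulate_cohort(config, rng)
    if config.observed_periods is not None:
        data = mask_observations(data, config.observed_periods)
    rows = []
    for res in estimate_all(data, strategies, options):
        d = res.to_dict()
        d["rep"] = rep
        rows.append(d)
    return rows


def run_replications(
    config: ScenarioConfig,
    strategies=None,
    seed=None,
    n_reps=None,
    options=None,
    workers=1,
) -> pd.DataFrame:
    """Per-replication results table for ``config``.

    ``seed`` overrides ``config.seed`` and ``n_reps`` overrides
    ``config.n_reps``.  ``workers > 1`` parallelises over replications
    with joblib; child seeds are spawned up front, so summaries do not
    depend on the worker count.
    """
    strategies = STRATEGY_NAMES if strategies is None else tuple(strategies)
    seed = config.seed if seed is None else int(seed)
    n_reps = config.n_reps if n_reps is None else int(n_reps)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    if workers and workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=workers)(
            delayed(_one_rep)(config, strategies, options, children[i], i)
            for i in range(n_reps)
        )
    else:
        chunks = [
            _one_rep(config, strategies, options, children[i], i)
            for i in range(n_reps)
        ]
    rows = [r for chunk in chunks for r in chunk]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def truths_for(config: ScenarioConfig) -> dict:
    """Per-strategy truth: lambda_0 for prior-to-treatment, gamma otherwise."""
    gamma = analytic.true_gamma(config)
    lam0 = float(config.lambda_t[0])
    return {name: (lam0 if name == "prior_to_treatment" else gamma)
            for name in STRATEGY_NAMES}


def summarise(results: pd.DataFrame, truths: dict) -> pd.DataFrame:
    """Score a per-replication results table against per-strategy truths.

    Returns one row per strategy with bias, rmse, coverage, rejection
    rate, failure count, effective replication count and the Monte-Carlo
    standard error of the bias.  A strategy whose replications all failed
    keeps its row with NaN metrics and ``n_reps_effective = 0``.
    """
    out = []
    for strategy, grp in results.groupby("strategy", sort=False):
        truth = float(truths[strategy])
        ok = grp[~grp["failed"].astype(bool)]
        n_failed = int(len(grp) - len(ok))
        m = len(ok)
        if m == 0:
            out.append(
                {
                    "strategy": strategy,
                    "truth_used": truth,
                    "bias": np.nan,
                    "rmse": np.nan,
                    "coverage": np.nan,
                    "rejection_rate": np.nan,
                    "n_failed": n_failed,
                    "n_reps_effective": 0,
                    "mc_se_bias": np.nan,
                }
            )
            continue
        est = ok["estimate"].to_numpy()
        err = est - truth
        bias = float(err.mean())
        rmse = float(np.sqrt(np.mean(err**2)))
        cover = float(
            ((ok["ci_low"] <= truth) & (truth <= ok["ci_high"])).mean()
        )
        reject = float((ok["p_value"] < 0.05).mean())
        out.append(
            {
                "strategy": strategy,
                "truth_used": truth,
                "bias": bias,
                "rmse": rmse,
                "coverage": cover,
                "rejection_rate": reject,
                "n_failed": n_failed,
                "n_reps_effective": m,
                "mc_se_bias": float(est.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)


def run_scenario(
    config: ScenarioConfig,
    strategies=None,
    seed=None,
    n_reps=None,
    options=None,
    workers=1,
):
    """Convenience wrapper: replications plus their summary.

    Returns ``(results, summary)``.
    """
    results = run_replications(
        config, strategies, seed=seed, n_reps=n_reps, options=options,
        workers=workers,
    )
    summary = summarise(results, truths_for(config))
    return results, summary


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """One scenario column pair in the conventional table layout."""
    return pd.DataFrame(
        {
            "strategy": summary["strategy"],
            "bias (rmse)": [
                f"{b:.2f} ({r:.2f})"
                for b, r in zip(summary["bias"], summary["rmse"])
            ],
            "coverage (rejection rate)": [
                f"{c:.2f} ({j:.2f})"
                for c, j in zip(summary["coverage"], summary["rejection_rate"])
            ],
        }
    )


def reproduce_table(scenario: str, reps: int = 2000, seed: int = 0, workers=1):
    """Eight-strategy summary grid for scenario S3A or S3B.

    Runs the full strategy battery at genetic effect 0 and 0.5 and formats
    the cells as "bias (rmse)" and "coverage (rejection rate)".  Returns
    ``(formatted, raw)`` where ``raw`` maps the genetic effect to the
    numeric summary.
    """
    from .dgp import scenario_preset

    key = str(scenario).upper()
    if key not in ("S3A", "S3B"):
        raise ValueError("reproduce_table covers scenarios S3A and S3B")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    raw = {}
    formatted = None
    for lam in (0.0, 0.5):
        config = scenario_preset(key, lam, n_reps=int(reps), seed=int(seed))
        _, summary = run_scenario(config, workers=workers)
        raw[lam] = summary
        block = format_summary(summary)
        block.columns = ["strategy"] + [
            f"lambda={lam:g}: {c}" for c in block.columns[1:]
        ]
        formatted = (
            block if formatted is None
            else formatted.merge(block, on="strategy")
        )
    return formatted, raw
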