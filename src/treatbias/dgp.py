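"""Longitudinal cohort simulator for gene--treatment--phenotype studies.

The generator produces cohorts in which a quantitative phenotype follows a
first-order Markov process: each period's value depends on the previous
value (autoregressive coefficient ``omega3``), the treatment governing the
interval that just ended (``omega1``), a lag-1 Gaussian confounder process
(``omega2``), a per-period direct genetic effect (``lambda_t``) and,
optionally, a gene-by-treatment interaction (``omega4``).  Treatment is a
Bernoulli indicator prescribed on the lagged phenotype and confounder via a
logistic model (or randomized at baseline), and may itself change over time
with a persistence term.  The genotype is a single biallelic variant drawn
in Hardy-Weinberg equilibrium.

Scenario presets reproduce the canonical designs used to study when
treatment biases genetic association estimates:

``S1``
    Two-period randomized trial; the gene-by-treatment interaction
    ``omega4`` is iterated over a grid.
``S2A`` / ``S2B``
    Two-period observational study in which treatment is prescribed on the
    baseline phenotype (mediation of the genetic effect); the direct
    genetic effect (A) or the treatment effect (B) is iterated.
``S3A``
    Six-period observational study with time-varying treatment.
``S3B``
    Identical generation to S3A, but flagged so that estimation only sees
    the baseline and final periods (observation filter, not a generation
    change).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "ScenarioConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "scenario_preset",
    "mask_observations",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_COLUMNS",
    "SCENARIO_GRIDS",
]

GENETIC_MODELS = ("additive", "dominant")
RESIDUAL_DISTS = ("normal", "t2")

#: column order of the long-format cohort table
COHORT_COLUMNS = (
    "subject_id",
    "genotype",
    "period",
    "treatment",
    "confounder",
    "phenotype",
)

#: grid of values iterated per scenario preset
SCENARIO_GRIDS = {
    "S1": tuple(np.arange(0.5, 5.01, 0.5).round(6)),  # omega4
    "S2A": tuple(np.arange(0.0, 1.81, 0.2).round(6)),  # lambda
    "S2B": tuple((-np.arange(0.0, 36.1, 4.0)).round(6)),  # omega1
    "S3A": (0.0, 0.5),  # lambda
    "S3B": (0.0, 0.5),  # lambda
}


@dataclass
class ScenarioConfig:
    """Every path coefficient and distributional choice of one scenario.

    Defaults correspond to the observational two-period design with a
    moderate positive genetic effect; use :func:`scenario_preset` for the
    canonical scenario grids.

    Parameters
    ----------
    n_subjects : cohort size per replication.
    n_periods : T; the phenotype is measured at t = 0..T.
    maf : minor-allele frequency in [0, 0.5].
    genetic_model : genotype coding used in *generation* ("additive" or
        "dominant"); estimators always use the raw allele count, so the
        dominant setting is the model-misspecification experiment.
    lambda_t : direct genetic effect on Y at each period (length T+1).
    omega0_t : period intercepts (length T+1).
    omega1 : treatment effect on the next-period phenotype.
    omega2 : confounder effect on the phenotype.
    omega3_t : lag-1 autoregressive phenotype effect Y_{t-1} -> Y_t
        (length T).
    omega4 : gene-by-treatment interaction effect.
    a0, a1, a2, a3 : treatment-model log-odds intercept, lagged-phenotype
        effect, confounder effect and previous-treatment persistence.
    alpha_G : direct genotype effect on the treatment log-odds (0 means no
        direct G -> D arrow; mediation may still run via Y).
    randomized : treatment at t=0 drawn Bernoulli(expit(a0)), ignoring
        a1, a2 and alpha_G (RCT).
    treatment_time_varying : if False, treatment is fixed after t=0.
    residual_dist : phenotype residual family, "normal" or "t2"
        (t with 2 degrees of freedom; not variance-standardised because the
        variance is infinite -- scaled by ``residual_sd`` directly).
    residual_sd : scale of the phenotype residuals.
    confounder_rho : lag-1 correlation of the confounder process.
    n_reps : Monte-Carlo replications when the config drives a study.
    seed : RNG seed.
    observed_periods : if set, estimation only sees these periods
        (e.g. ``(0, 5)`` for scenario S3B); generation is unaffected.
    """

    n_subjects: int = 1000
    n_periods: int = 1
    maf: float = 0.3
    genetic_model: str = "additive"
    lambda_t: tuple = (0.5, 0.5)
    omega0_t: tuple = (0.0, 0.0)
    omega1: float = -10.0
    omega2: float = 1.0
    omega3_t: tuple = (0.5,)
    omega4: float = 0.0
    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    alpha_G: float = 0.0
    randomized: bool = False
    treatment_time_varying: bool = False
    residual_dist: str = "normal"
    residual_sd: float = 1.0
    confounder_rho: float = 0.5
    n_reps: int = 2000
    seed: int = 0
    observed_periods: tuple | None = None

    def __post_init__(self):
        self.lambda_t = tuple(float(v) for v in np.atleast_1d(self.lambda_t))
        self.omega0_t = tuple(float(v) for v in np.atleast_1d(self.omega0_t))
        self.omega3_t = tuple(float(v) for v in np.atleast_1d(self.omega3_t))
        for name in ("maf", "omega1", "omega2", "omega4", "a0", "a1", "a2",
                     "a3", "alpha_G", "residual_sd", "confounder_rho"):
            setattr(self, name, float(getattr(self, name)))
        for name in ("n_subjects", "n_periods", "n_reps", "seed"):
            setattr(self, name, int(getattr(self, name)))
        if self.observed_periods is not None:
            self.observed_periods = tuple(int(t) for t in self.observed_periods)
        self.validate()

    def validate(self) -> None:
        T = self.n_periods
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if T < 1:
            raise ValueError("n_periods must be >= 1")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")
        if self.genetic_model not in GENETIC_MODELS:
            raise ValueError(f"genetic_model must be one of {GENETIC_MODELS}")
        if self.residual_dist not in RESIDUAL_DISTS:
            raise ValueError(f"residual_dist must be one of {RESIDUAL_DISTS}")
        if len(self.lambda_t) != T + 1:
            raise ValueError(f"lambda_t must have length T+1={T + 1}")
        if len(self.omega0_t) != T + 1:
            raise ValueError(f"omega0_t must have length T+1={T + 1}")
        if len(self.omega3_t) != T:
            raise ValueError(f"omega3_t must have length T={T}")
        if not self.residual_sd > 0:
            raise ValueError("residual_sd must be > 0")
        if not (-1.0 <= self.confounder_rho <= 1.0):
            raise ValueError("confounder_rho must be in [-1, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.observed_periods is not None:
            obs = self.observed_periods
            if len(obs) < 1 or sorted(set(obs)) != list(obs):
                raise ValueError("observed_periods must be sorted and unique")
            if obs[0] != 0 or obs[-1] > T:
                raise ValueError(
                    "observed_periods must start at 0 and lie within 0..T"
                )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("lambda_t", "omega0_t", "omega3_t"):
            d[key] = list(d[key])
        if d["observed_periods"] is not None:
            d["observed_periods"] = list(d["observed_periods"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config file must contain a mapping")
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


def simulate_genotypes(n, maf, genetic_model="additive", rng=None):
    """Draw ``n`` minor-allele counts under Hardy-Weinberg equilibrium.

    The trinomial HWE distribution ((1-p)^2, 2p(1-p), p^2) over {0, 1, 2}
    is exactly Binomial(2, p).  The returned vector is always the raw
    allele count; dominant coding (``genetic_model="dominant"``) is applied
    inside the phenotype equation of :func:`simulate_cohort`, never here.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if genetic_model not in GENETIC_MODELS:
        raise ValueError(f"genetic_model must be one of {GENETIC_MODELS}")
    rng = np.random.default_rng(rng)
    return rng.binomial(2, maf, size=int(n)).astype(np.int64)


def _residuals(rng, shape, dist, sd):
    if dist == "normal":
        return sd * rng.standard_normal(shape)
    # t(2): infinite variance, deliberately not standardised
    return sd * rng.standard_t(2, size=shape)


def simulate_cohort(config: ScenarioConfig, rng=None) -> pd.DataFrame:
    """Generate one long-format cohort under ``config``.

    Generation recursion, per subject i (g_eff is the allele count under
    additive coding, 1{G>=1} under dominant coding)::

        U_0 ~ N(0,1);  U_t = rho U_{t-1} + sqrt(1-rho^2) eps_t
        Y_0 = omega0_0 + lambda_0 g_eff + omega2 U_0 + e_0
        D_0 ~ Bern(expit(a0))                        if randomized
            ~ Bern(expit(a0 + a1 Y_0 + a2 U_0 + alpha_G g_eff))  otherwise
        Y_t = omega0_t + lambda_t g_eff + omega1 D_{t-1} + omega2 U_{t-1}
              + omega3_t Y_{t-1} + omega4 g_eff D_{t-1} + e_t
        D_t ~ Bern(expit(a0 + a1 Y_t + a2 U_t + a3 D_{t-1} + alpha_G g_eff))
              while treatment varies and t < T; D_t = D_{t-1} otherwise

    ``D_t`` is the treatment governing the interval ending at t+1.  The
    returned table has one row per (subject, period) with columns
    ``subject_id, genotype, period, treatment, confounder, phenotype``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n, T = config.n_subjects, config.n_periods
    g = simulate_genotypes(n, config.maf, config.genetic_model, rng)
    if config.genetic_model == "dominant":
        g_eff = (g >= 1).astype(float)
    else:
        g_eff = g.astype(float)

    # fixed draw order: confounder innovations, residuals, treatment uniforms
    u_innov = rng.standard_normal((n, T + 1))
    e = _residuals(rng, (n, T + 1), config.residual_dist, config.residual_sd)
    d_unif = rng.random((n, T + 1))

    om0 = np.asarray(config.omega0_t)
    lam = np.asarray(config.lambda_t)
    om3 = np.asarray(config.omega3_t)
    rho = config.confounder_rho

    U = np.empty((n, T + 1))
    Y = np.empty((n, T + 1))
    D = np.empty((n, T + 1), dtype=np.int64)

    U[:, 0] = u_innov[:, 0]
    Y[:, 0] = om0[0] + lam[0] * g_eff + config.omega2 * U[:, 0] + e[:, 0]
    if config.randomized:
        p0 = expit(config.a0)
    else:
        p0 = expit(
            config.a0
            + config.a1 * Y[:, 0]
            + config.a2 * U[:, 0]
            + config.alpha_G * g_eff
        )
    D[:, 0] = d_unif[:, 0] < p0

    for t in range(1, T + 1):
        U[:, t] = rho * U[:, t - 1] + np.sqrt(1.0 - rho**2) * u_innov[:, t]
        Y[:, t] = (
            om0[t]
            + lam[t] * g_eff
            + config.omega1 * D[:, t - 1]
            + config.omega2 * U[:, t - 1]
            + om3[t - 1] * Y[:, t - 1]
            + config.omega4 * g_eff * D[:, t - 1]
            + e[:, t]
        )
        if config.treatment_time_varying and t < T:
            p = expit(
                config.a0
                + config.a1 * Y[:, t]
                + config.a2 * U[:, t]
                + config.a3 * D[:, t - 1]
                + config.alpha_G * g_eff
            )
            D[:, t] = d_unif[:, t] < p
        else:
            D[:, t] = D[:, t - 1]

    subj = np.repeat(np.arange(n), T + 1)
    return pd.DataFrame(
        {
            "subject_id": subj,
            "genotype": np.repeat(g, T + 1),
            "period": np.tile(np.arange(T + 1), n),
            "treatment": D.ravel(),
            "confounder": U.ravel(),
            "phenotype": Y.ravel(),
        }
    )


def mask_observations(data: pd.DataFrame, periods) -> pd.DataFrame:
    """Restrict a cohort to the given periods, relabelling them 0..k-1.

    Emulates an analyst who only observes a subset of the follow-up (e.g.
    baseline and end of study) and therefore treats the retained periods
    as if they were adjacent: lagged covariates at the relabelled period k
    are the values observed at the previous *retained* period.
    """
    periods = sorted(set(int(t) for t in periods))
    missing = set(periods) - set(data["period"].unique())
    if missing:
        raise ValueError(f"periods not present in data: {sorted(missing)}")
    out = data[data["period"].isin(periods)].copy()
    relabel = {p: i for i, p in enumerate(periods)}
    out["period"] = out["period"].map(relabel)
    return out.reset_index(drop=True)


def _calibrated_a0(a1, alpha_G, lambda0, omega0_0, maf, genetic_model):
    """Intercept putting the baseline treated fraction near one half.

    Centres the treatment-model linear predictor at zero in expectation:
    a0 = -(a1 E[Y_0] + alpha_G E[g_eff]) with E[U_0] = 0.
    """
    if genetic_model == "dominant":
        eg = 1.0 - (1.0 - maf) ** 2
    else:
        eg = 2.0 * maf
    ey0 = omega0_0 + lambda0 * eg
    return -(a1 * ey0 + alpha_G * eg)


def scenario_preset(name: str, grid_value: float, **overrides) -> ScenarioConfig:
    """Fully populated :class:`ScenarioConfig` for one scenario grid point.

    ``grid_value`` iterates omega4 (S1), lambda (S2A), omega1 (S2B) or
    lambda (S3A/S3B) and must belong to the scenario's grid (see
    :data:`SCENARIO_GRIDS`).  Keyword overrides (e.g. ``n_reps`` or
    ``seed``) are applied after the preset is built.
    """
    key = str(name).upper()
    if key not in SCENARIO_GRIDS:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_GRIDS)}"
        )
    grid = SCENARIO_GRIDS[key]
    if not any(np.isclose(grid_value, v) for v in grid):
        raise ValueError(
            f"grid_value {grid_value} not in the {key} grid {grid}"
        )
    grid_value = float(grid_value)

    log12, log15, log4 = np.log(1.2), np.log(1.5), np.log(4.0)
    if key == "S1":
        cfg = ScenarioConfig(
            n_periods=1,
            lambda_t=(0.5, 0.5),
            omega0_t=(0.0, 0.0),
            omega3_t=(0.5,),
            omega1=-10.0,
            omega4=grid_value,
            a0=0.0,
            randomized=True,
            treatment_time_varying=False,
        )
    elif key in ("S2A", "S2B"):
        lam = grid_value if key == "S2A" else 0.5
        om1 = -10.0 if key == "S2A" else grid_value
        cfg = ScenarioConfig(
            n_periods=1,
            lambda_t=(lam, lam),
            omega0_t=(0.0, 0.0),
            omega3_t=(0.5,),
            omega1=om1,
            omega4=0.0,
            a1=log12,
            a2=log15,
            a0=_calibrated_a0(log12, 0.0, lam, 0.0, 0.3, "additive"),
            randomized=False,
            treatment_time_varying=False,
        )
    else:  # S3A / S3B
        T = 5
        lam = grid_value
        cfg = ScenarioConfig(
            n_periods=T,
            lambda_t=(lam,) * (T + 1),
            omega0_t=(0.0,) * (T + 1),
            omega3_t=(0.5,) * T,
            omega1=-10.0,
            omega4=0.0,
            a1=log12,
            a2=log15,
            a3=log4,
            a0=_calibrated_a0(log12, 0.0, lam, 0.0, 0.3, "additive"),
            randomized=False,
            treatment_time_varying=True,
            observed_periods=(0, 5) if key == "S3B" else None,
        )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg


def write_cohort_csv(data: pd.DataFrame, path) -> None:
    data.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False, float_format="%.6g")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a long-format cohort table, validating the column contract.

    The ``confounder`` column is optional (strategies that need it fail
    gracefully when it is absent).
    """
    df = pd.read_csv(path)
    required = [c for c in COHORT_COLUMNS if c != "confounder"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
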