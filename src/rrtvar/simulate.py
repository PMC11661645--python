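"""Monte-Carlo engine: populations, scrambles, SRSWR samples, MSE tables.

The study design emulated here: generate a finite trivariate-normal
population, attach scrambled responses once (the ``z_i`` are then fixed
unit characteristics), draw ``R`` simple-random-with-replacement samples of
size ``n``, evaluate every configured estimator on each sample and compare
empirical bias/MSE with the first-order theory evaluated on the realized
population moments.

Reference points.  The estimand is the realized finite-population variance
``sigma_y^2`` (divisor N-1).  The closed-form theory, however, targets the
model-unscrambled value ``u0 = sigma*^2/scale``, which differs from
``sigma_y^2`` by a fixed O(1/sqrt(N)) offset of the single scramble
realization.  The theory columns reported for comparison are therefore
re-referenced exactly via

    bias_vs_y = bias + offset,
    mse_vs_y  = mse + 2*offset*bias + offset^2,   offset = u0 - sigma_y^2,

with the model-referenced values kept alongside (``*_model`` keys).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .estimators import (
    CONSTANT_KEYS,
    EstimatorSpec,
    KnownAuxiliary,
    SampleStats,
    estimate,
)
from .models import ScramblingParams
from .moments import PopulationMoments, population_moments
from .synthpop import (
    FIXTURE_SIGMA2_S,
    FIXTURE_SIGMA2_T,
    FinitePopulation,
    PopulationSpec,
    builtin_specs,
    generate_population,
    scramble,
    scrambled_values,
)
from . import theory

_MOD = 2**31  # derived seeds stay below 2^31

#: Exponent grid of the three-constant generalized class.
SALEEM_GRID = (
    (0, 0), (1, 1), (1, 0), (0, 1), (-1, -1), (-1, 0), (0, -1), (-1, 1), (1, -1)
)

#: Exponent settings of the proposed difference-in-exponential class.
PROPOSED_GRID = (
    (1, 1, 1), (0, 1, 1), (-1, 1, 1), (0.5, 1, 1),
    (0, -1, -1), (0, 1, -1), (0, -1, 1),
)


@dataclass
class SimulationConfig:
    spec: PopulationSpec
    params: ScramblingParams
    n: int
    R: int
    seed: int
    estimators: list[EstimatorSpec]
    constants_policy: str = "optimal_from_population"
    rescramble_each_rep: bool = False
    mode: str = "canonical"

    def __post_init__(self) -> None:
        if not 2 <= self.n < self.spec.N:
            raise InvalidParameterError("need 2 <= n < N")
        if self.R < 100:
            raise InvalidParameterError("need R >= 100 replications")
        if self.constants_policy not in ("optimal_from_population", "fixed"):
            raise InvalidParameterError(
                f"unknown constants policy {self.constants_policy!r}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "spec": self.spec.to_json(),
                "params": self.params.to_json(),
                "n": self.n, "R": self.R, "seed": self.seed,
                "estimators": [e.to_json() for e in self.estimators],
                "constants_policy": self.constants_policy,
                "rescramble_each_rep": self.rescramble_each_rep,
                "mode": self.mode,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulationResult:
    records: list[dict]
    population_summary: dict
    sigma2_y: float
    u0: float
    offset: float
    seed: int
    config_hash: str
    n: int
    R: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def estimator_label(spec: EstimatorSpec) -> str:
    e = spec.exponents
    if spec.family == "saleem_gen":
        return f"saleem_gen({e.get('lambda1', 0):g},{e.get('lambda2', 0):g})"
    if spec.family == "proposed":
        return (f"proposed({e.get('pi1', 0):g},{e.get('pi2', 0):g},"
                f"{e.get('pi3', 0):g})")
    return spec.family


def resolve_constants(
    spec: EstimatorSpec,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
) -> EstimatorSpec:
    """Replace the 'optimal' token by closed-form optima from population
    moments (the known-moments idealization of the optimum plug-ins)."""
    if spec.constants != "optimal":
        return spec
    if spec.family == "genratio":
        a_opt = theory.optimal_constants("genratio", params, pm, n)["wpsig"]
        exps = dict(spec.exponents)
        # realize the optimal product w*psi*g with g = 1, psi = 1
        exps.update({"g": 1.0, "w": a_opt, "a": 1.0, "b": 0.0})
        return EstimatorSpec("genratio", exps, {})
    keys = CONSTANT_KEYS[spec.family]
    if not keys:
        return spec.with_constants({})
    consts = theory.optimal_constants(
        spec.family, params, pm, n, spec.exponents
    )
    return spec.with_constants(consts)


def _sample_stats(
    pop: FinitePopulation,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SampleStats:
    idx = rng.integers(0, pop.N, size=(config.R, config.n))
    y_s = pop.y[idx]
    if config.rescramble_each_rep:
        p = config.params
        S = rng.normal(0.0, np.sqrt(p.sigma2_S), size=idx.shape)
        T = 1.0 + rng.normal(0.0, np.sqrt(p.sigma2_T), size=idx.shape)
        z_s = scrambled_values(y_s, p, S, T)
    else:
        z_s = pop.z[idx]
    x1_s = pop.x1[idx]
    x2_s = pop.x2[idx]
    return SampleStats(
        n=config.n,
        zbar=z_s.mean(axis=1),
        s2_z=z_s.var(axis=1, ddof=1),
        s2_x1=x1_s.var(axis=1, ddof=1),
        s2_x2=x2_s.var(axis=1, ddof=1),
    )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Execute one Monte-Carlo study; deterministic given the config seed."""
    seed = config.seed
    pop = generate_population(config.spec, seed % _MOD)
    pop = scramble(pop, config.params, (seed + 1) % _MOD)
    pm = population_moments(pop)
    sigma2_y = pm.sigma2_y
    u0 = theory.target_value(config.params, pm)
    offset = u0 - sigma2_y
    aux = KnownAuxiliary(pm.sigma2_x1, pm.sigma2_x2, pm.N)

    rng = np.random.default_rng((seed + 2) % _MOD)
    stats = _sample_stats(pop, config, rng)
    chash = config.config_hash()

    records = []
    for spec in config.estimators:
        if config.constants_policy == "fixed" and spec.constants == "optimal":
            raise InvalidParameterError(
                "constants_policy='fixed' requires explicit constants"
            )
        rspec = resolve_constants(spec, config.params, pm, config.n)
        est = np.asarray(estimate(rspec, config.params, stats, aux), dtype=float)
        finite = np.isfinite(est)
        kept = est[finite]
        n_excluded = int(config.R - kept.size)
        err = kept - sigma2_y
        emp_bias = float(err.mean())
        emp_mse = float((err**2).mean())
        mc_se = float((err**2).std(ddof=1) / np.sqrt(kept.size))
        tr = theory.bias_mse(
            rspec.family, config.params, pm, config.n,
            rspec.constants if isinstance(rspec.constants, dict) else {},
            rspec.exponents, config.mode,
        )
        records.append({
            "estimator": estimator_label(rspec),
            "family": rspec.family,
            "exponents": dict(rspec.exponents),
            "constants_used": dict(tr.constants_used),
            "empirical_bias": emp_bias,
            "empirical_mse": emp_mse,
            "theory_bias": tr.bias + offset,
            "theory_mse": tr.mse + 2.0 * offset * tr.bias + offset**2,
            "theory_bias_model": tr.bias,
            "theory_mse_model": tr.mse,
            "mc_standard_error": mc_se,
            "n_excluded": n_excluded,
            "seed": seed,
            "config_hash": chash,
        })
    return SimulationResult(
        records=records,
        population_summary=population_summary(pop, config.params),
        sigma2_y=sigma2_y,
        u0=u0,
        offset=offset,
        seed=seed,
        config_hash=chash,
        n=config.n,
        R=config.R,
    )


def population_summary(pop: FinitePopulation, params: ScramblingParams) -> dict:
    """Realized population summaries (divisor N-1) in the standard layout."""
    mat = np.vstack([pop.y, pop.x1, pop.x2])
    cov = np.cov(mat, ddof=1)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    out = {
        "N": pop.N,
        "mu_y": float(pop.y.mean()),
        "mu_x1": float(pop.x1.mean()),
        "mu_x2": float(pop.x2.mean()),
        "sigma2_y": float(cov[0, 0]),
        "sigma2_x1": float(cov[1, 1]),
        "sigma2_x2": float(cov[2, 2]),
        "cov_yx1": float(cov[0, 1]),
        "cov_yx2": float(cov[0, 2]),
        "cov_x1x2": float(cov[1, 2]),
        "rho_yx1": float(corr[0, 1]),
        "rho_yx2": float(corr[0, 2]),
        "rho_x1x2": float(corr[1, 2]),
        "sigma2_S": params.sigma2_S,
        "sigma2_T": params.sigma2_T,
    }
    if pop.z is not None:
        out["Zbar"] = float(pop.z.mean())
        out["sigma2_z"] = float(np.var(pop.z, ddof=1))
    return out


def gupta_estimators() -> list[EstimatorSpec]:
    return [
        EstimatorSpec("usual"),
        EstimatorSpec("ratio"),
        EstimatorSpec("genratio", {"g": 1.0, "a": 1.0, "b": 0.0}, "optimal"),
        EstimatorSpec("diff1", {}, "optimal"),
        EstimatorSpec("diff2", {}, "optimal"),
    ]


def saleem_grid_estimators() -> list[EstimatorSpec]:
    return [
        EstimatorSpec("saleem_gen", {"lambda1": float(l1), "lambda2": float(l2)},
                      "optimal")
        for l1, l2 in SALEEM_GRID
    ]


def proposed_grid_estimators() -> list[EstimatorSpec]:
    return [
        EstimatorSpec(
            "proposed",
            {"pi1": float(p1), "pi2": float(p2), "pi3": float(p3)},
            "optimal",
        )
        for p1, p2, p3 in PROPOSED_GRID
    ]


def default_table_configs(
    n: int = 50,
    R: int = 5000,
    seed: int = 1,
    sigma2_S: float = FIXTURE_SIGMA2_S,
    sigma2_T: float = FIXTURE_SIGMA2_T,
    populations: list[PopulationSpec] | None = None,
) -> list[SimulationConfig]:
    """The standard four-table study over the built-in populations.

    All configs for one population share the same seed, hence the same
    realized population; the multiplicative-additive scramble (the mixture
    model at h = 0, i.e. Z = T*Y + S) is shared by the Gupta-family,
    three-constant and proposed-class tables, while the additive/
    multiplicative mixture table re-scrambles at each l in {0, 1}.
    """
    populations = populations if populations is not None else builtin_specs()
    diana = ScramblingParams("diana_perri", sigma2_S, sigma2_T)
    genh = ScramblingParams(
        "generalized_h", sigma2_S, sigma2_T, alpha=1.0, mix=0.0
    )
    configs = []
    for spec in populations:
        base = dict(spec=spec, n=n, R=R, seed=seed)
        configs.append(SimulationConfig(
            params=diana, estimators=gupta_estimators(), **base))
        configs.append(SimulationConfig(
            params=genh, estimators=saleem_grid_estimators(), **base))
        for l in (0.0, 1.0):
            azeem = ScramblingParams(
                "azeem_l", sigma2_S, sigma2_T, mix=l
            )
            configs.append(SimulationConfig(
                params=azeem,
                estimators=[EstimatorSpec("azeem_usual"),
                            EstimatorSpec("azeem_ratio")],
                **base))
        configs.append(SimulationConfig(
            params=genh, estimators=proposed_grid_estimators(), **base))
    return configs


_TABLE_OF_FAMILY = {
    "usual": "gupta", "ratio": "gupta", "genratio": "gupta",
    "diff1": "gupta", "diff2": "gupta",
    "saleem_gen": "saleem_grid",
    "proposed": "proposed_grid",
    "azeem_usual": "azeem", "azeem_ratio": "azeem",
}


def build_comparison_tables(
    configs: list[SimulationConfig],
) -> dict[str, pd.DataFrame]:
    """Run a set of configs and assemble the four comparison tables.

    Returns long-format frames keyed ``gupta``, ``saleem_grid``, ``azeem``,
    ``proposed_grid``, each row carrying the population, sample size and
    the empirical and theoretical MSE of one estimator.  An empty config
    list yields an empty table set.
    """
    rows: dict[str, list[dict]] = {}
    for config in configs:
        result = run_simulation(config)
        for rec in result.records:
            table = _TABLE_OF_FAMILY[rec["family"]]
            label = rec["estimator"]
            if rec["family"].startswith("azeem"):
                label = f"{rec['estimator']}(l={config.params.mix:g})"
            rows.setdefault(table, []).append({
                "estimator": label,
                "population": config.spec.name,
                "n": config.n,
                "R": config.R,
                "empirical_mse": rec["empirical_mse"],
                "theory_mse": rec["theory_mse"],
                "empirical_bias": rec["empirical_bias"],
                "theory_bias": rec["theory_bias"],
                "seed": rec["seed"],
                "config_hash": rec["config_hash"],
            })
    return {name: pd.DataFrame(data) for name, data in rows.items()}


def pivot_mse_table(table: pd.DataFrame, value: str = "empirical_mse") -> pd.DataFrame:
    """Wide display: one row per estimator, one column per population."""
    if table.empty:
        return table
    return table.pivot_table(
        index="estimator", columns="population", values=value, sort=False
    )
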