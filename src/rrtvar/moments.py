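"""Finite-population moment functionals driving the first-order theory.

All first-order (``theta = 1/n``) bias and mean-squared-error expressions
for the variance estimators are parameterized by standardized mixed central
moments of the triple ``(z, x1, x2)``,

    mu_rst   = (1/(N-1)) * sum (z_i - Zbar)^r (x1_i - X1bar)^s (x2_i - X2bar)^t
    gamma_rst = mu_rst / (mu_200^{r/2} * mu_020^{s/2} * mu_002^{t/2})
    gamma*_rst = gamma_rst - 1,

together with the coefficient of variation ``C_z = sigma_z / Zbar``.  Under
simple random sampling with replacement the relative errors

    zeta_z  = (s_z^2 - sigma_z^2)/sigma_z^2,   zeta_zbar = (zbar - Zbar)/Zbar,
    zeta_x1 = (s_x1^2 - sigma_x1^2)/sigma_x1^2, zeta_x2 likewise,

have mean zero and second moments ``theta`` times a fixed table of gamma
quantities; that table is the entire stochastic input to the first-order
calculus.

Divisor convention: ``N - 1`` throughout, matching the definitions of the
population variances.  Under with-replacement sampling the sample variance
is unbiased for the divisor-``N`` variance, an ``O(1/N)`` discrepancy
absorbed into Monte-Carlo tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegeneratePopulationError,
    InsufficientDataError,
    InvalidParameterError,
)
from .synthpop import FinitePopulation

#: Gamma triples required by every implemented bias/MSE formula.
REQUIRED_TRIPLES = (
    (4, 0, 0), (0, 4, 0), (0, 0, 4),
    (2, 2, 0), (2, 0, 2), (0, 2, 2),
    (3, 0, 0), (1, 2, 0), (1, 0, 2),
)

ZETA_SYMBOLS = ("zeta_z", "zeta_zbar", "zeta_x1", "zeta_x2")


@dataclass(frozen=True)
class PopulationMoments:
    """Moment summary of a scrambled finite population."""

    N: int
    Zbar: float
    Ybar: float
    sigma2_z: float
    sigma2_y: float
    sigma2_x1: float
    sigma2_x2: float
    Cz: float
    gamma: dict[tuple[int, int, int], float]

    def gamma_star(self, triple: tuple[int, int, int]) -> float:
        return self.gamma_at(triple) - 1.0

    def gamma_at(self, triple: tuple[int, int, int]) -> float:
        try:
            return self.gamma[triple]
        except KeyError as exc:  # pragma: no cover - defensive
            from .errors import IncompleteMomentsError

            raise IncompleteMomentsError(f"gamma{triple} not available") from exc

    def to_json(self) -> str:
        flat = {f"gamma_{r}{s}{t}": v for (r, s, t), v in self.gamma.items()}
        flat.update(
            N=self.N, Zbar=self.Zbar, Ybar=self.Ybar, Cz=self.Cz,
            sigma2_z=self.sigma2_z, sigma2_y=self.sigma2_y,
            sigma2_x1=self.sigma2_x1, sigma2_x2=self.sigma2_x2,
        )
        return json.dumps(flat)


@dataclass(frozen=True)
class ZetaMoments:
    """Second-moment table of the sampling relative errors."""

    theta: float
    table: dict[tuple[str, str], float]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return self.table[(a, b)] if (a, b) in self.table else self.table[(b, a)]

    def matrix(self) -> np.ndarray:
        """4x4 matrix of E[zeta_i zeta_j] in the order z, zbar, x1, x2."""
        m = np.empty((4, 4))
        for i, a in enumerate(ZETA_SYMBOLS):
            for j, b in enumerate(ZETA_SYMBOLS):
                m[i, j] = self[(a, b)]
        return m


def central_moment(pop: FinitePopulation, r: int, s: int, t: int) -> float:
    """Mixed central moment mu_rst of (z, x1, x2) with divisor N - 1."""
    if pop.z is None:
        raise InvalidParameterError("population has no scrambled responses")
    if min(r, s, t) < 0:
        raise InvalidParameterError("moment orders must be non-negative")
    N = pop.N
    if N < 2:
        raise InsufficientDataError("need at least 2 units")
    dz = pop.z - pop.z.mean()
    d1 = pop.x1 - pop.x1.mean()
    d2 = pop.x2 - pop.x2.mean()
    return float(np.sum(dz**r * d1**s * d2**t) / (N - 1))


def gamma_ratio(pop: FinitePopulation, r: int, s: int, t: int) -> float:
    """Standardized moment ratio gamma_rst = mu_rst / (mu_200^{r/2}
    mu_020^{s/2} mu_002^{t/2})."""
    mu200 = central_moment(pop, 2, 0, 0)
    mu020 = central_moment(pop, 0, 2, 0)
    mu002 = central_moment(pop, 0, 0, 2)
    for order, margin in ((r, mu200), (s, mu020), (t, mu002)):
        if order > 0 and margin <= 0:
            raise DegeneratePopulationError("zero variance in a used margin")
    denom = 1.0
    if r:
        denom *= mu200 ** (r / 2)
    if s:
        denom *= mu020 ** (s / 2)
    if t:
        denom *= mu002 ** (t / 2)
    return central_moment(pop, r, s, t) / denom


def population_moments(pop: FinitePopulation) -> PopulationMoments:
    """All moment functionals needed by the theory module, in one pass."""
    if pop.z is None:
        raise InvalidParameterError("population has no scrambled responses")
    sigma2_z = float(np.var(pop.z, ddof=1))
    if sigma2_z <= 0:
        raise DegeneratePopulationError("constant scrambled response")
    Zbar = float(np.mean(pop.z))
    if Zbar == 0.0:
        raise DegeneratePopulationError("Cz undefined: Zbar = 0")
    gamma = {triple: gamma_ratio(pop, *triple) for triple in REQUIRED_TRIPLES}
    return PopulationMoments(
        N=pop.N,
        Zbar=Zbar,
        Ybar=float(np.mean(pop.y)),
        sigma2_z=sigma2_z,
        sigma2_y=float(np.var(pop.y, ddof=1)),
        sigma2_x1=float(np.var(pop.x1, ddof=1)),
        sigma2_x2=float(np.var(pop.x2, ddof=1)),
        Cz=float(np.sqrt(sigma2_z) / Zbar),
        gamma=gamma,
    )


def zeta_second_moments(pm: PopulationMoments, n: int) -> ZetaMoments:
    """First-order second moments of the sampling relative errors.

    ``theta = 1/n``; each entry is theta times a gamma functional of the
    population, e.g. ``E[zeta_z^2] = theta * (gamma_400 - 1)``.
    """
    if n < 2:
        raise InvalidParameterError("sample size must be at least 2")
    th = 1.0 / n
    g, gs, Cz = pm.gamma_at, pm.gamma_star, pm.Cz
    table = {
        ("zeta_z", "zeta_z"): th * gs((4, 0, 0)),
        ("zeta_zbar", "zeta_zbar"): th * Cz**2,
        ("zeta_x1", "zeta_x1"): th * gs((0, 4, 0)),
        ("zeta_x2", "zeta_x2"): th * gs((0, 0, 4)),
        ("zeta_z", "zeta_zbar"): th * Cz * g((3, 0, 0)),
        ("zeta_z", "zeta_x1"): th * gs((2, 2, 0)),
        ("zeta_z", "zeta_x2"): th * gs((2, 0, 2)),
        ("zeta_x1", "zeta_x2"): th * gs((0, 2, 2)),
        ("zeta_x1", "zeta_zbar"): th * g((1, 2, 0)) * Cz,
        ("zeta_x2", "zeta_zbar"): th * g((1, 0, 2)) * Cz,
    }
    # symmetrize
    table.update({(b, a): v for (a, b), v in list(table.items())})
    return ZetaMoments(theta=th, table=table)
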