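"""Point estimators of the finite-population variance of a sensitive variable.

Every family starts from the unscrambled plug-in estimator
``sigma_y_hat^2 = (s_z^2 - c_S - c_M*zbar^2)/scale`` of
:func:`rrtvar.models.unscramble_variance_estimator` and sharpens it with
known auxiliary population variances ``sigma_x1^2``, ``sigma_x2^2``:

``usual``
    the plug-in estimator itself;
``ratio``
    plug-in times ``sigma_x1^2 / s_x1^2``;
``genratio``
    ``(plug-in + (sigma_x1^2 - s_x1^2))`` times a ``w``-mixed power bracket
    ``[(a*sigma_x1^2 + b) / (w*(a*s_x1^2 + b) + (1-w)*(a*sigma_x1^2 + b))]^g``;
``diff1``
    plug-in plus ``K*(sigma_x1^2 - s_x1^2)``;
``diff2``
    ``J1*plug-in + J2*(sigma_x1^2 - s_x1^2) + J3*(sigma_x2^2 - s_x2^2)``;
``saleem_gen``
    the ``diff2`` form (constants ``K1..K3``) multiplied by
    ``exp((sigma_x1^2 - s_x1^2)/(sigma_x1^2 + s_x1^2))^lambda1 *
    (sigma_x2^2/s_x2^2)^lambda2``;
``proposed``
    difference-in-exponential ratio-product class
    ``L1*plug-in*exp((sigma_x1^2 - s_x1^2)/(sigma_x1^2 + s_x1^2))^pi1
    + L2*exp((s_x1^2 - sigma_x1^2)/(s_x1^2 + sigma_x1^2))^pi2
    + L3*exp((s_x2^2 - sigma_x2^2)/(s_x2^2 + sigma_x2^2))^pi3``;
``azeem_usual`` / ``azeem_ratio``
    the plug-in under the additive/multiplicative mixture model, the ratio
    variant multiplying by ``s_x*^2 / sigma_x1^2`` with the complement
    variance ``s_x*^2 = ((N-1)*sigma_x^2 - (n-1)*s_x^2)/(N-n)``.

Estimators are pure functions of the sample summaries, the known auxiliary
variances and the model constants; array-valued sample summaries broadcast,
which is what the Monte-Carlo engine relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .models import ScramblingParams, unscramble_variance_estimator

FAMILIES = (
    "usual", "ratio", "genratio", "diff1", "diff2",
    "saleem_gen", "proposed", "azeem_usual", "azeem_ratio",
)

#: Exponent keys each family understands (beyond constants).
_EXPONENT_KEYS = {
    "genratio": ("g", "w", "a", "b"),
    "saleem_gen": ("lambda1", "lambda2"),
    "proposed": ("pi1", "pi2", "pi3"),
}

#: Constant keys per family, in canonical order.
CONSTANT_KEYS = {
    "usual": (), "ratio": (), "azeem_usual": (), "azeem_ratio": (),
    "genratio": (),  # the tunables g, w, a, b live in `exponents`
    "diff1": ("K",),
    "diff2": ("J1", "J2", "J3"),
    "saleem_gen": ("K1", "K2", "K3"),
    "proposed": ("L1", "L2", "L3"),
}


@dataclass(frozen=True)
class SampleStats:
    """Sample summaries (divisor n-1) consumed by every estimator."""

    n: int
    zbar: float
    s2_z: float
    s2_x1: float
    s2_x2: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("sample size must be at least 2")


@dataclass(frozen=True)
class KnownAuxiliary:
    """Known population variances of the auxiliary variables."""

    sigma2_x1: float
    sigma2_x2: float
    N: int

    def __post_init__(self) -> None:
        if self.sigma2_x1 <= 0 or self.sigma2_x2 <= 0:
            raise InvalidParameterError("auxiliary variances must be positive")


@dataclass(frozen=True)
class EstimatorSpec:
    """An estimator family with its exponents and constants.

    ``constants`` is either a mapping of explicit values or the token
    ``"optimal"``; resolving the optimum is the theory module's job
    (:func:`rrtvar.theory.optimal_constants`).
    """

    family: str
    exponents: dict = field(default_factory=dict)
    constants: dict | str = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(f"unknown family {self.family!r}")
        if isinstance(self.constants, str) and self.constants != "optimal":
            raise InvalidParameterError(
                "constants must be a mapping or the token 'optimal'"
            )
        if self.family == "genratio":
            a = self.exponents.get("a", 1.0)
            b = self.exponents.get("b", 0.0)
            # the bracket is undefined when a*sigma_x1^2 + b could vanish
            if a == 0.0 and b == 0.0:
                raise InvalidParameterError("genratio requires a or b nonzero")

    def with_constants(self, constants: dict) -> "EstimatorSpec":
        return EstimatorSpec(self.family, dict(self.exponents), dict(constants))

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "exponents": self.exponents,
             "constants": self.constants}
        )

    @classmethod
    def from_json(cls, text: str) -> "EstimatorSpec":
        d = json.loads(text)
        return cls(d["family"], d.get("exponents", {}), d.get("constants", {}))


def sx_star(s2_x, sigma2_x: float, N: int, n: int):
    """Complement sample variance ((N-1)*sigma_x^2 - (n-1)*s_x^2)/(N-n)."""
    if N == n:
        raise ZeroDivisionError("sx_star undefined at N = n")
    return ((N - 1) * sigma2_x - (n - 1) * s2_x) / (N - n)


def _require_constants(spec: EstimatorSpec) -> dict:
    if not isinstance(spec.constants, dict):
        raise InvalidParameterError(
            "estimate() needs explicit constants; resolve 'optimal' first"
        )
    missing = [k for k in CONSTANT_KEYS[spec.family] if k not in spec.constants]
    if missing:
        raise InvalidParameterError(
            f"{spec.family} requires constants {missing}"
        )
    return spec.constants


def estimate(
    spec: EstimatorSpec,
    params: ScramblingParams,
    stats: SampleStats,
    aux: KnownAuxiliary,
):
    """Evaluate an estimator on one sample (or broadcast over arrays).

    Division by a zero sample variance in the ratio-type families raises
    ``ZeroDivisionError`` for scalar inputs; array inputs propagate
    non-finite values, which the simulation engine records and excludes.
    """
    consts = _require_constants(spec)
    fam = spec.family
    u = unscramble_variance_estimator(params, stats)
    scalar = np.isscalar(stats.s2_z) or np.ndim(stats.s2_z) == 0

    def _checked_div(num, den):
        if scalar and den == 0:
            raise ZeroDivisionError(f"{fam} undefined at zero sample variance")
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / den

    if fam in ("usual", "azeem_usual"):
        return u
    if fam == "ratio":
        return u * _checked_div(aux.sigma2_x1, stats.s2_x1)
    if fam == "azeem_ratio":
        star = sx_star(stats.s2_x1, aux.sigma2_x1, aux.N, stats.n)
        return u * star / aux.sigma2_x1
    if fam == "genratio":
        e = spec.exponents
        g, w = e.get("g", 1.0), e.get("w", 1.0)
        a, b = e.get("a", 1.0), e.get("b", 0.0)
        known = a * aux.sigma2_x1 + b
        mixed = w * (a * stats.s2_x1 + b) + (1.0 - w) * known
        bracket = _checked_div(known, mixed)
        return (u + (aux.sigma2_x1 - stats.s2_x1)) * bracket**g
    if fam == "diff1":
        return u + consts["K"] * (aux.sigma2_x1 - stats.s2_x1)
    d1 = aux.sigma2_x1 - stats.s2_x1
    d2 = aux.sigma2_x2 - stats.s2_x2
    if fam == "diff2":
        return consts["J1"] * u + consts["J2"] * d1 + consts["J3"] * d2
    if fam == "saleem_gen":
        l1 = spec.exponents.get("lambda1", 0.0)
        l2 = spec.exponents.get("lambda2", 0.0)
        base = consts["K1"] * u + consts["K2"] * d1 + consts["K3"] * d2
        expo = np.exp(_checked_div(d1, aux.sigma2_x1 + stats.s2_x1)) ** l1
        ratio = _checked_div(aux.sigma2_x2, stats.s2_x2) ** l2
        return base * expo * ratio
    # proposed
    p1 = spec.exponents.get("pi1", 0.0)
    p2 = spec.exponents.get("pi2", 0.0)
    p3 = spec.exponents.get("pi3", 0.0)
    f1 = np.exp(_checked_div(d1, aux.sigma2_x1 + stats.s2_x1)) ** p1
    f2 = np.exp(_checked_div(-d1, stats.s2_x1 + aux.sigma2_x1)) ** p2
    f3 = np.exp(_checked_div(-d2, stats.s2_x2 + aux.sigma2_x2)) ** p3
    return consts["L1"] * u * f1 + consts["L2"] * f2 + consts["L3"] * f3
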