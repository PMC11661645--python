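"""Exact second-order expansions of the estimators in the sampling errors.

Every estimator in :mod:`rrtvar.estimators` is a smooth function of the
sample summaries ``(s_z^2, zbar, s_x1^2, s_x2^2)``.  Writing each summary as
its population value times ``1 + zeta`` and truncating products at second
order in the relative errors ``zeta = (zeta_z, zeta_zbar, zeta_x1,
zeta_x2)`` yields, for each family, an expansion

    f  =  a0  +  a1 . zeta  +  zeta' A2 zeta   (+ third order and beyond),

from which the first-order bias and MSE follow by taking expectations
against the second-moment table of :func:`rrtvar.moments.zeta_second_moments`:

    bias = (a0 - u0) + tr(A2 Sigma),
    mse  = (a0 - u0)^2 + 2 (a0 - u0) tr(A2 Sigma) + a1' Sigma a1,

where ``u0`` is the model-unscrambled population variance and ``Sigma =
E[zeta zeta']``.  The algebra here is carried out exactly (no numerical
differentiation), so it serves as the canonical closed form; the
finite-difference oracle in :mod:`rrtvar.theory` provides the independent
numerical route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .models import ModelConstants
from .moments import PopulationMoments

_DIM = 4  # zeta order: z, zbar, x1, x2
_IX1 = 2
_IX2 = 3


@dataclass(frozen=True)
class Expansion:
    """Second-order polynomial in the four sampling relative errors."""

    a0: float
    a1: np.ndarray  # shape (4,)
    a2: np.ndarray  # shape (4, 4), symmetric

    def __add__(self, other: "Expansion") -> "Expansion":
        return Expansion(self.a0 + other.a0, self.a1 + other.a1, self.a2 + other.a2)

    def __sub__(self, other: "Expansion") -> "Expansion":
        return Expansion(self.a0 - other.a0, self.a1 - other.a1, self.a2 - other.a2)

    def __mul__(self, other):
        if np.isscalar(other):
            return Expansion(self.a0 * other, self.a1 * other, self.a2 * other)
        # product of two expansions, truncated at second order
        outer = np.outer(self.a1, other.a1)
        return Expansion(
            self.a0 * other.a0,
            self.a0 * other.a1 + other.a0 * self.a1,
            self.a0 * other.a2 + other.a0 * self.a2 + 0.5 * (outer + outer.T),
        )

    __rmul__ = __mul__

    def shift(self, c: float) -> "Expansion":
        return Expansion(self.a0 + c, self.a1, self.a2)

    def mean(self, sigma: np.ndarray) -> float:
        """E[f] given Sigma = E[zeta zeta'] (zeroth plus curvature)."""
        return self.a0 + float(np.sum(self.a2 * sigma))

    def mse_about(self, target: float, sigma: np.ndarray) -> float:
        """First-order E[(f - target)^2]."""
        d0 = self.a0 - target
        quad = float(np.sum(self.a2 * sigma))
        return d0 * d0 + 2.0 * d0 * quad + float(self.a1 @ sigma @ self.a1)


def _const(c: float) -> Expansion:
    return Expansion(c, np.zeros(_DIM), np.zeros((_DIM, _DIM)))


def _factor(i: int, lin: float, quad: float) -> Expansion:
    """A scalar factor 1 + lin*zeta_i + quad*zeta_i^2."""
    a1 = np.zeros(_DIM)
    a1[i] = lin
    a2 = np.zeros((_DIM, _DIM))
    a2[i, i] = quad
    return Expansion(1.0, a1, a2)


def exp_known_minus_sample(i: int, lam: float) -> Expansion:
    """exp((sigma^2 - s^2)/(sigma^2 + s^2))^lam = exp(-zeta/(2+zeta))^lam."""
    return _factor(i, -0.5 * lam, lam * (lam + 2.0) / 8.0)


def exp_sample_minus_known(i: int, lam: float) -> Expansion:
    """exp((s^2 - sigma^2)/(s^2 + sigma^2))^lam."""
    return _factor(i, 0.5 * lam, lam * (lam - 2.0) / 8.0)


def pow_known_over_sample(i: int, lam: float) -> Expansion:
    """(sigma^2 / s^2)^lam = (1 + zeta)^(-lam)."""
    return _factor(i, -lam, lam * (lam + 1.0) / 2.0)


def mix_bracket(wpsi: float, g: float) -> Expansion:
    """(1 + w*psi*zeta_x1)^(-g), the generalized-ratio power bracket."""
    return _factor(_IX1, -g * wpsi, g * (g + 1.0) / 2.0 * wpsi**2)


def sigma_star2(mc: ModelConstants, pm: PopulationMoments) -> float:
    """sigma*^2 = sigma_z^2 - c_S - c_lin*Zbar - c_M*Zbar^2 (= scale*u0)."""
    return pm.sigma2_z - mc.c_S - mc.c_lin * pm.Zbar - mc.c_M * pm.Zbar**2


def u_expansion(mc: ModelConstants, pm: PopulationMoments) -> Expansion:
    """The unscrambled plug-in estimator; exact (it is quadratic in zeta)."""
    c, Z = mc.scale, pm.Zbar
    a1 = np.zeros(_DIM)
    a1[0] = pm.sigma2_z / c
    a1[1] = -(2.0 * mc.c_M * Z**2 + mc.c_lin * Z) / c
    a2 = np.zeros((_DIM, _DIM))
    a2[1, 1] = -mc.c_M * Z**2 / c
    return Expansion(sigma_star2(mc, pm) / c, a1, a2)


def _diff_term(i: int, sigma2_x: float) -> Expansion:
    """(sigma_x^2 - s_x^2) = -sigma_x^2 * zeta."""
    a1 = np.zeros(_DIM)
    a1[i] = -sigma2_x
    return Expansion(0.0, a1, np.zeros((_DIM, _DIM)))


def genratio_wpsi(exponents: dict, sigma2_x1: float) -> tuple[float, float]:
    """(w*psi, g) for the generalized-ratio bracket."""
    g = exponents.get("g", 1.0)
    w = exponents.get("w", 1.0)
    a = exponents.get("a", 1.0)
    b = exponents.get("b", 0.0)
    denom = a * sigma2_x1 + b
    if denom == 0.0:
        raise InvalidParameterError("genratio bracket undefined: a*sigma_x1^2 + b = 0")
    return w * a * sigma2_x1 / denom, g


def basis_expansions(
    family: str,
    exponents: dict,
    mc: ModelConstants,
    pm: PopulationMoments,
    n: int,
) -> tuple[Expansion, list[Expansion], tuple[str, ...]]:
    """Decompose an estimator as fixed + sum(constant_k * basis_k).

    Returns ``(fixed, basis, keys)`` where the estimator with constants
    ``c`` equals ``fixed + sum_k c[keys[k]] * basis[k]``.  Families without
    free constants return an empty basis.
    """
    u = u_expansion(mc, pm)
    d1 = _diff_term(_IX1, pm.sigma2_x1)
    d2 = _diff_term(_IX2, pm.sigma2_x2)
    zero = _const(0.0)

    if family in ("usual", "azeem_usual"):
        return u, [], ()
    if family == "ratio":
        return u * pow_known_over_sample(_IX1, 1.0), [], ()
    if family == "azeem_ratio":
        if pm.N <= n:
            raise InvalidParameterError("azeem_ratio requires N > n")
        D = (n - 1) / (pm.N - n)
        return u * _factor(_IX1, -D, 0.0), [], ()
    if family == "genratio":
        wpsi, g = genratio_wpsi(exponents, pm.sigma2_x1)
        return (u + d1) * mix_bracket(wpsi, g), [], ()
    if family == "diff1":
        return u, [d1], ("K",)
    if family == "diff2":
        return zero, [u, d1, d2], ("J1", "J2", "J3")
    if family == "saleem_gen":
        l1 = exponents.get("lambda1", 0.0)
        l2 = exponents.get("lambda2", 0.0)
        m = exp_known_minus_sample(_IX1, l1) * pow_known_over_sample(_IX2, l2)
        return zero, [u * m, d1 * m, d2 * m], ("K1", "K2", "K3")
    if family == "proposed":
        p1 = exponents.get("pi1", 0.0)
        p2 = exponents.get("pi2", 0.0)
        p3 = exponents.get("pi3", 0.0)
        return (
            zero,
            [
                u * exp_known_minus_sample(_IX1, p1),
                exp_sample_minus_known(_IX1, p2),
                exp_sample_minus_known(_IX2, p3),
            ],
            ("L1", "L2", "L3"),
        )
    raise InvalidParameterError(f"unknown family {family!r}")


def estimator_expansion(
    family: str,
    exponents: dict,
    constants: dict,
    mc: ModelConstants,
    pm: PopulationMoments,
    n: int,
) -> Expansion:
    """Full expansion of an estimator with explicit constants."""
    fixed, basis, keys = basis_expansions(family, exponents, mc, pm, n)
    f = fixed
    for key, term in zip(keys, basis):
        f = f + constants[key] * term
    return f


def mse_quadratic(
    family: str,
    exponents: dict,
    mc: ModelConstants,
    pm: PopulationMoments,
    n: int,
    sigma: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, tuple[str, ...]]:
    """First-order MSE as an exact quadratic in the free constants.

    Returns ``(const, b, Q, keys)`` with
    ``mse(c) = const + b . c + c' Q c`` about the model target ``u0``.
    """
    fixed, basis, keys = basis_expansions(family, exponents, mc, pm, n)
    if not keys:
        raise InvalidParameterError(f"{family} has no free constants")
    u0 = sigma_star2(mc, pm) / mc.scale
    e0 = fixed.shift(-u0)
    k = len(basis)
    A = np.array([e.a0 for e in basis])
    Qc = np.array([float(np.sum(e.a2 * sigma)) for e in basis])
    A0 = e0.a0
    Q0 = float(np.sum(e0.a2 * sigma))
    gram = np.empty((k, k))
    g0 = np.empty(k)
    for i in range(k):
        g0[i] = float(e0.a1 @ sigma @ basis[i].a1)
        for j in range(i, k):
            gram[i, j] = gram[j, i] = float(basis[i].a1 @ sigma @ basis[j].a1)
    const = A0 * A0 + 2.0 * A0 * Q0 + float(e0.a1 @ sigma @ e0.a1)
    b = 2.0 * (A0 * A + A0 * Qc + A * Q0 + g0)
    Q = np.outer(A, A) + np.outer(A, Qc) + np.outer(Qc, A) + gram
    return const, b, Q, keys
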