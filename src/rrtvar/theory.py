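"""First-order bias/MSE theory, closed-form optima and numerical oracles.

Two evaluation modes are available everywhere:

``"canonical"`` (default)
    exact second-order expansion algebra (:mod:`rrtvar._expansion`), the
    re-derived first-order theory.  This is what the simulation engine and
    the closed-form optima use.
``"published"``
    literal transcriptions of the reported closed forms
    (:mod:`rrtvar._published`), retained so the two can be audited against
    each other.  Where a reported display is internally incomplete the mode
    falls back to canonical with an explanatory note.

Independent of both closed-form routes, :func:`delta_oracle` differentiates
the actual estimator implementation numerically (Richardson-refined central
differences) and assembles bias and MSE from the sampling-error covariance,
providing the package's cross-check on every formula.  The audit helpers
emit machine-readable records of any published-vs-canonical discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _published as pub
from ._expansion import (
    estimator_expansion,
    genratio_wpsi,
    mse_quadratic,
    sigma_star2,
)
from .errors import (
    InvalidParameterError,
    OracleFailureError,
    SingularSystemError,
)
from .estimators import (
    CONSTANT_KEYS,
    EstimatorSpec,
    KnownAuxiliary,
    SampleStats,
    estimate,
)
from .models import ModelConstants, ScramblingParams, model_constants
from .moments import PopulationMoments, zeta_second_moments

MODES = ("canonical", "published")

#: Default exponent settings used when a family is audited or optimized
#: without explicit exponents.
DEFAULT_EXPONENTS = {
    "genratio": {"g": 1.0, "w": 1.0, "a": 1.0, "b": 0.0},
    "saleem_gen": {"lambda1": 1.0, "lambda2": 1.0},
    "proposed": {"pi1": 1.0, "pi2": 1.0, "pi3": 1.0},
}


@dataclass
class TheoryResult:
    """First-order bias and MSE with the named intermediate quantities."""

    family: str
    mode: str
    bias: float
    mse: float
    constants_used: dict
    intermediates: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _unpack(family, constants, exponents):
    if isinstance(family, EstimatorSpec):
        spec = family
        c = spec.constants if isinstance(spec.constants, dict) else (constants or {})
        return spec.family, dict(c), dict(spec.exponents)
    return str(family), dict(constants or {}), dict(exponents or {})


def _sigma_matrix(pm: PopulationMoments, n: int) -> np.ndarray:
    return zeta_second_moments(pm, n).matrix()


def target_value(params: ScramblingParams, pm: PopulationMoments) -> float:
    """The model-unscrambled population variance u0 = sigma*^2 / scale."""
    mc = model_constants(params)
    return sigma_star2(mc, pm) / mc.scale


def _canonical_intermediates(
    family: str, exponents: dict, mc: ModelConstants,
    pm: PopulationMoments, n: int, sigma: np.ndarray,
) -> dict:
    """Named quadratic-form coefficients recovered from the canonical MSE."""
    th, c = 1.0 / n, mc.scale
    out: dict = {}
    if family == "diff1":
        const, b, Q, _ = mse_quadratic(family, exponents, mc, pm, n, sigma)
        out["pi1"] = const * c**2 / th
        out["pi2"] = -b[0] * c / (2.0 * th * pm.sigma2_x1)
    elif family == "genratio":
        def at(a):
            f = estimator_expansion(
                "genratio", {"g": 1.0, "w": a, "a": 1.0, "b": 0.0}, {}, mc, pm, n
            )
            return f.mse_about(sigma_star2(mc, pm) / c, sigma)

        m0, mp, mm = at(0.0), at(1.0), at(-1.0)
        out["delta1"] = m0 * c**2 / th
        out["delta2"] = ((mp + mm) / 2.0 - m0) * c**2 / th
        out["delta3"] = (mm - mp) / 4.0 * c**2 / th
    elif family == "diff2":
        const, b, Q, _ = mse_quadratic(family, exponents, mc, pm, n, sigma)
        out.update(
            U1=c**2 * Q[0, 0], U2=c**2 * Q[1, 1], U3=c**2 * Q[2, 2],
            U4=-(c**2) * b[0] / 2.0,
            U5=-(c**2) * Q[0, 1], U6=-(c**2) * Q[0, 2], U7=c**2 * Q[1, 2],
        )
    elif family == "saleem_gen":
        const, b, Q, _ = mse_quadratic(family, exponents, mc, pm, n, sigma)
        out.update(
            alpha1=c**2 * Q[0, 0], alpha2=c**2 * Q[1, 1], alpha3=c**2 * Q[2, 2],
            alpha4=-(c**2) * b[0] / 2.0,
            alpha5=c**2 * b[1] / 2.0, alpha6=c**2 * b[2] / 2.0,
            alpha7=-(c**2) * Q[0, 1], alpha8=-(c**2) * Q[0, 2],
            alpha9=c**2 * Q[1, 2],
        )
    elif family == "proposed":
        const, b, Q, _ = mse_quadratic(family, exponents, mc, pm, n, sigma)
        out.update(
            eta1=c**2 * Q[0, 0], eta2=c**2 * Q[1, 1], eta3=c**2 * Q[2, 2],
            eta4=-(c**2) * b[0] / 2.0,
            eta5=-(c**2) * b[1] / 2.0, eta6=-(c**2) * b[2] / 2.0,
            eta7=c**2 * Q[0, 1], eta8=c**2 * Q[0, 2], eta9=c**2 * Q[1, 2],
        )
    return out


def bias_mse(
    family,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    constants: dict | None = None,
    exponents: dict | None = None,
    mode: str = "canonical",
) -> TheoryResult:
    """First-order bias and MSE of an estimator about the model target u0.

    ``family`` may be a family name or an :class:`EstimatorSpec` carrying
    explicit constants.  theta = 1/n throughout.
    """
    family, constants, exponents = _unpack(family, constants, exponents)
    if mode not in MODES:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    mc = model_constants(params)
    sigma = _sigma_matrix(pm, n)
    u0 = sigma_star2(mc, pm) / mc.scale
    notes: list[str] = []

    if mode == "canonical":
        f = estimator_expansion(family, exponents, constants, mc, pm, n)
        bias = f.mean(sigma) - u0
        mse = f.mse_about(u0, sigma)
        inter = _canonical_intermediates(family, exponents, mc, pm, n, sigma)
    else:
        x = pub._Ctx(mc, pm, n)
        inter = {}
        if family in ("usual",):
            bias, mse = pub.usual_bias(x), pub.usual_mse(x)
        elif family == "ratio":
            bias, mse = pub.ratio_bias(x), pub.ratio_mse(x)
        elif family == "genratio":
            wpsi, g = genratio_wpsi(exponents, pm.sigma2_x1)
            bias = pub.genratio_bias(x, wpsi, g)
            mse = pub.genratio_mse(x, wpsi, g)
            d1, d2, d3 = pub.genratio_deltas(x)
            inter = {"delta1": d1, "delta2": d2, "delta3": d3}
        elif family == "diff1":
            bias = pub.usual_bias(x)
            mse = pub.diff1_mse(x, constants["K"])
            inter = dict(zip(("pi1", "pi2"), pub.diff1_pi(x)))
        elif family == "diff2":
            bias = pub.diff2_bias(x, constants["J1"])
            mse = pub.diff2_mse(x, constants["J1"], constants["J2"], constants["J3"])
            inter = pub.diff2_U(x)
        elif family == "saleem_gen":
            l1 = exponents.get("lambda1", 0.0)
            l2 = exponents.get("lambda2", 0.0)
            bias = pub.saleem_bias(
                x, constants["K1"], constants["K2"], constants["K3"], l1, l2
            )
            # the reported coefficient list for this family's variance
            # quadratic is incomplete; fall back to the canonical value
            f = estimator_expansion(family, exponents, constants, mc, pm, n)
            mse = f.mse_about(u0, sigma)
            notes.append("incomplete_published_algebra:mse_evaluated_canonically")
        elif family == "proposed":
            p1 = exponents.get("pi1", 0.0)
            p2 = exponents.get("pi2", 0.0)
            p3 = exponents.get("pi3", 0.0)
            bias = pub.proposed_bias(
                x, constants["L1"], constants["L2"], constants["L3"], p1, p2, p3
            )
            mse = pub.proposed_mse(
                x, constants["L1"], constants["L2"], constants["L3"],
                p1, p2, p3, params.sigma2_T,
            )
            inter = pub.proposed_eta(x, p1, p2, p3, params.sigma2_T)
        elif family == "azeem_usual":
            bias, mse = pub.azeem_usual_bias(x), pub.azeem_usual_mse(x)
        elif family == "azeem_ratio":
            bias = pub.azeem_ratio_bias(x, pm.N, n)
            mse = pub.azeem_ratio_mse(x, pm.N, n, params.mix, params.sigma2_S)
        else:
            raise InvalidParameterError(f"unknown family {family!r}")

    if mse < 0.0:
        notes.append("formula_audit:negative_mse")
    return TheoryResult(
        family=family, mode=mode, bias=float(bias), mse=float(mse),
        constants_used=dict(constants), intermediates=inter, notes=notes,
    )


def _det3(a1, a2, a3, a7, a8, a9) -> float:
    """Determinant of [[a1,-a7,-a8],[-a7,a2,a9],[-a8,a9,a3]]."""
    return (
        a1 * a2 * a3 - a1 * a9**2 - a2 * a8**2 - a3 * a7**2
        + 2.0 * a7 * a8 * a9
    )


def optimal_constants(
    family,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    exponents: dict | None = None,
    mode: str = "canonical",
) -> dict:
    """Closed-form MSE-minimizing constants for a family.

    Evaluates the scalar cofactor forms (not a generic linear solver) on the
    mode-appropriate intermediate quantities; :func:`numeric_opt_oracle`
    provides the solver-style cross-check.
    """
    family, _, exponents = _unpack(family, None, exponents)
    mc = model_constants(params)
    sigma = _sigma_matrix(pm, n)
    c = mc.scale
    inter = _intermediates_for_mode(family, params, mc, pm, n, sigma, exponents, mode)

    if family == "diff1":
        denom = c * pm.sigma2_x1 * pm.gamma_star((0, 4, 0))
        _check_nonsingular(denom)
        return {"K": inter["pi2"] / denom}
    if family == "genratio":
        _check_nonsingular(inter["delta2"])
        return {"wpsig": inter["delta3"] / inter["delta2"]}
    if family == "diff2":
        U1, U2, U3 = inter["U1"], inter["U2"], inter["U3"]
        U4, U5, U6, U7 = inter["U4"], inter["U5"], inter["U6"], inter["U7"]
        det = _det3(U1, U2, U3, U5, U6, U7)
        _check_nonsingular(det)
        return {
            "J1": U4 * (U2 * U3 - U7**2) / det,
            "J2": U4 * (U3 * U5 - U6 * U7) / det,
            "J3": U4 * (U2 * U6 - U5 * U7) / det,
        }
    if family == "saleem_gen":
        a1, a2, a3 = inter["alpha1"], inter["alpha2"], inter["alpha3"]
        a4, a5, a6 = inter["alpha4"], inter["alpha5"], inter["alpha6"]
        a7, a8, a9 = inter["alpha7"], inter["alpha8"], inter["alpha9"]
        O1 = _det3(a1, a2, a3, a7, a8, a9)
        _check_nonsingular(O1)
        O2 = (a2 * a3 * a4 - a2 * a6 * a8 - a3 * a5 * a7 - a4 * a9**2
              + a5 * a8 * a9 + a6 * a7 * a9)
        O3 = (a1 * a3 * a5 - a1 * a6 * a9 - a3 * a4 * a7 + a4 * a8 * a9
              - a5 * a8**2 + a6 * a7 * a8)
        O4 = (a1 * a2 * a6 - a1 * a5 * a9 - a2 * a4 * a8 + a4 * a7 * a9
              + a5 * a7 * a8 - a6 * a7**2)
        return {"K1": O2 / O1, "K2": -O3 / O1, "K3": -O4 / O1}
    if family == "proposed":
        e1, e2, e3 = inter["eta1"], inter["eta2"], inter["eta3"]
        e4, e5, e6 = inter["eta4"], inter["eta5"], inter["eta6"]
        e7, e8, e9 = inter["eta7"], inter["eta8"], inter["eta9"]
        Q1 = (e1 * e2 * e3 - e1 * e9**2 - e2 * e8**2 - e3 * e7**2
              + 2.0 * e7 * e8 * e9)
        _check_nonsingular(Q1)
        Q2 = (e2 * e3 * e4 - e2 * e6 * e8 - e3 * e5 * e7 - e4 * e9**2
              + e5 * e8 * e9 + e6 * e7 * e9)
        Q3 = (e1 * e3 * e5 - e1 * e6 * e9 - e3 * e4 * e7 + e4 * e8 * e9
              - e5 * e8**2 + e6 * e7 * e8)
        Q4 = (e1 * e2 * e6 - e1 * e5 * e9 - e2 * e4 * e8 + e4 * e7 * e9
              + e5 * e7 * e8 - e6 * e7**2)
        return {"L1": Q2 / Q1, "L2": Q3 / Q1, "L3": Q4 / Q1}
    raise InvalidParameterError(f"{family} has no free constants to optimize")


def min_mse(
    family,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    exponents: dict | None = None,
    mode: str = "canonical",
) -> float:
    """Closed-form minimum first-order MSE of a family."""
    family, _, exponents = _unpack(family, None, exponents)
    mc = model_constants(params)
    sigma = _sigma_matrix(pm, n)
    th, c = 1.0 / n, mc.scale
    star2 = sigma_star2(mc, pm)
    if family not in CONSTANT_KEYS or not CONSTANT_KEYS.get(family, ()):
        if family == "genratio":
            inter = _intermediates_for_mode(
                family, params, mc, pm, n, sigma, exponents, mode
            )
            d1, d2, d3 = inter["delta1"], inter["delta2"], inter["delta3"]
            _check_nonsingular(d2)
            return th / c**2 * (d1 - d3**2 / d2)
        # no tunable constants: the minimum is the value itself
        return bias_mse(family, params, pm, n, {}, exponents, mode).mse

    inter = _intermediates_for_mode(family, params, mc, pm, n, sigma, exponents, mode)
    if family == "diff1":
        g040s = pm.gamma_star((0, 4, 0))
        _check_nonsingular(g040s)
        return th / c**2 * (inter["pi1"] - inter["pi2"] ** 2 / g040s)
    if family == "diff2":
        U1, U2, U3 = inter["U1"], inter["U2"], inter["U3"]
        U4, U5, U6, U7 = inter["U4"], inter["U5"], inter["U6"], inter["U7"]
        det = _det3(U1, U2, U3, U5, U6, U7)
        _check_nonsingular(det)
        return (star2**2 - U4**2 * (U2 * U3 - U7**2) / det) / c**2
    if family == "saleem_gen":
        a = inter
        O1 = _det3(a["alpha1"], a["alpha2"], a["alpha3"],
                   a["alpha7"], a["alpha8"], a["alpha9"])
        _check_nonsingular(O1)
        m1 = a["alpha9"] ** 2 - a["alpha2"] * a["alpha3"]
        m2 = 2.0 * a["alpha3"] * a["alpha7"] - 2.0 * a["alpha8"] * a["alpha9"]
        m3 = a["alpha2"] * a["alpha8"] - a["alpha7"] * a["alpha9"]
        m4 = a["alpha8"] ** 2 - a["alpha1"] * a["alpha3"]
        m5 = a["alpha1"] * a["alpha9"] - a["alpha7"] * a["alpha8"]
        m6 = a["alpha1"] * a["alpha2"] - a["alpha7"] ** 2
        O5 = (m1 * a["alpha4"] ** 2
              + (m2 * a["alpha5"] + 2.0 * m3 * a["alpha6"]) * a["alpha4"]
              + m4 * a["alpha5"] ** 2 + 2.0 * m5 * a["alpha5"] * a["alpha6"]
              - m6 * a["alpha6"] ** 2)
        return (star2**2 + O5 / O1) / c**2
    if family == "proposed":
        e = inter
        Q1 = (e["eta1"] * e["eta2"] * e["eta3"] - e["eta1"] * e["eta9"] ** 2
              - e["eta2"] * e["eta8"] ** 2 - e["eta3"] * e["eta7"] ** 2
              + 2.0 * e["eta7"] * e["eta8"] * e["eta9"])
        _check_nonsingular(Q1)
        t1 = e["eta9"] ** 2 - e["eta2"] * e["eta3"]
        t2 = 2.0 * e["eta3"] * e["eta7"] - 2.0 * e["eta8"] * e["eta9"]
        t3 = e["eta2"] * e["eta8"] - e["eta7"] * e["eta9"]
        t4 = e["eta8"] ** 2 - e["eta1"] * e["eta3"]
        t5 = e["eta1"] * e["eta9"] - e["eta7"] * e["eta8"]
        t6 = e["eta1"] * e["eta2"] - e["eta7"] ** 2
        Q5 = (t1 * e["eta4"] ** 2
              + (t2 * e["eta5"] + 2.0 * t3 * e["eta6"]) * e["eta4"]
              + t4 * e["eta5"] ** 2 + 2.0 * t5 * e["eta5"] * e["eta6"]
              - t6 * e["eta6"] ** 2)
        return (star2**2 + Q5 / Q1) / c**2
    raise InvalidParameterError(f"min_mse undefined for family {family!r}")


def _intermediates_for_mode(
    family, params, mc, pm, n, sigma, exponents, mode
) -> dict:
    if mode == "canonical" or family == "saleem_gen":
        # the published coefficient list for saleem_gen is incomplete
        return _canonical_intermediates(family, exponents, mc, pm, n, sigma)
    x = pub._Ctx(mc, pm, n)
    if family == "diff1":
        return dict(zip(("pi1", "pi2"), pub.diff1_pi(x)))
    if family == "genratio":
        return dict(zip(("delta1", "delta2", "delta3"), pub.genratio_deltas(x)))
    if family == "diff2":
        return pub.diff2_U(x)
    if family == "proposed":
        return pub.proposed_eta(
            x,
            exponents.get("pi1", 0.0), exponents.get("pi2", 0.0),
            exponents.get("pi3", 0.0), params.sigma2_T,
        )
    return _canonical_intermediates(family, exponents, mc, pm, n, sigma)


def _check_nonsingular(value: float, tol: float = 1e-300) -> None:
    if not np.isfinite(value) or abs(value) < tol:
        raise SingularSystemError("singular denominator in the optimum system")


# ---------------------------------------------------------------------------
# numerical oracles
# ---------------------------------------------------------------------------

def _grad_hess(F, p0: np.ndarray):
    """Gradient and Hessian by Richardson-refined central differences."""
    p0 = np.asarray(p0, dtype=float)
    k = p0.size
    f0 = F(p0)
    hg = 1e-5 * np.abs(p0)
    hh = 5e-4 * np.abs(p0)

    def step(i, h):
        e = np.zeros(k)
        e[i] = h
        return e

    def gcomp(i, h):
        return (F(p0 + step(i, h)) - F(p0 - step(i, h))) / (2.0 * h)

    def hdiag(i, h):
        return (F(p0 + step(i, h)) - 2.0 * f0 + F(p0 - step(i, h))) / h**2

    def hoff(i, j, hi, hj):
        ei, ej = step(i, hi), step(j, hj)
        return (
            F(p0 + ei + ej) - F(p0 + ei - ej) - F(p0 - ei + ej) + F(p0 - ei - ej)
        ) / (4.0 * hi * hj)

    grad = np.empty(k)
    hess = np.empty((k, k))
    for i in range(k):
        grad[i] = (4.0 * gcomp(i, hg[i] / 2.0) - gcomp(i, hg[i])) / 3.0
        hess[i, i] = (4.0 * hdiag(i, hh[i] / 2.0) - hdiag(i, hh[i])) / 3.0
        for j in range(i + 1, k):
            v = (4.0 * hoff(i, j, hh[i] / 2.0, hh[j] / 2.0)
                 - hoff(i, j, hh[i], hh[j])) / 3.0
            hess[i, j] = hess[j, i] = v
    if not (np.isfinite(f0) and np.all(np.isfinite(grad))
            and np.all(np.isfinite(hess))):
        raise OracleFailureError("non-finite derivatives at the population point")
    return f0, grad, hess


def delta_oracle(
    spec: EstimatorSpec,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    constants: dict | None = None,
) -> TheoryResult:
    """Numerical delta-method bias/MSE of the implemented estimator.

    Differentiates :func:`rrtvar.estimators.estimate` at the population
    point ``(sigma_z^2, Zbar, sigma_x1^2, sigma_x2^2)`` by central finite
    differences with Richardson refinement, then assembles

        bias = delta0 + tr(Hess Cov)/2,
        mse  = delta0^2 + delta0 tr(Hess Cov) + grad' Cov grad,

    where ``Cov`` comes from the zeta second-moment table and ``delta0`` is
    the zeroth-order offset from the model target.  Independent of the
    closed forms: it never sees the expansion algebra.
    """
    if constants is not None:
        spec = spec.with_constants(constants)
    if not isinstance(spec.constants, dict):
        raise InvalidParameterError("delta_oracle needs explicit constants")
    aux = KnownAuxiliary(pm.sigma2_x1, pm.sigma2_x2, pm.N)
    p0 = np.array([pm.sigma2_z, pm.Zbar, pm.sigma2_x1, pm.sigma2_x2])

    def F(v):
        stats = SampleStats(n=n, zbar=v[1], s2_z=v[0], s2_x1=v[2], s2_x2=v[3])
        return float(estimate(spec, params, stats, aux))

    cov_rel = _sigma_matrix(pm, n)
    D = np.diag(p0)
    cov = D @ cov_rel @ D
    f0, grad, hess = _grad_hess(F, p0)
    u0 = target_value(params, pm)
    delta0 = f0 - u0
    trc = float(np.sum(hess * cov))
    bias = delta0 + 0.5 * trc
    mse = delta0**2 + delta0 * trc + float(grad @ cov @ grad)
    return TheoryResult(
        family=spec.family, mode="oracle", bias=bias, mse=mse,
        constants_used=dict(spec.constants),
        intermediates={"delta0": delta0, "grad": grad, "hessian": hess},
    )


def numeric_opt_oracle(
    family,
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    exponents: dict | None = None,
) -> dict:
    """Derivative-free minimization of the canonical first-order MSE.

    Local search (Nelder-Mead) started from the best point of a coarse
    grid; returns the argmin keyed like :func:`optimal_constants`.  A
    non-converged search returns its best iterate with ``converged=False``.
    """
    family, _, exponents = _unpack(family, None, exponents)
    if family == "genratio":
        keys = ("wpsig",)

        def objective(v):
            exps = {"g": 1.0, "w": float(v[0]), "a": 1.0, "b": 0.0}
            return bias_mse("genratio", params, pm, n, {}, exps).mse
    else:
        keys = CONSTANT_KEYS.get(family, ())
        if not keys:
            raise InvalidParameterError(f"{family} has no free constants")

        def objective(v):
            consts = dict(zip(keys, map(float, v)))
            return bias_mse(family, params, pm, n, consts, exponents).mse

    grid_1d = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])
    if len(keys) == 1:
        starts = grid_1d[:, None]
    else:
        pts = np.array(np.meshgrid(*[[-1.0, 0.0, 1.0]] * len(keys)))
        starts = pts.reshape(len(keys), -1).T
    best = min(starts, key=lambda v: objective(v))
    x = np.asarray(best, dtype=float)
    iterates = []
    success = False
    for _ in range(2):  # restart once to polish
        res = optimize.minimize(
            objective, x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000,
                     "maxfev": 40000},
        )
        x = res.x
        success = bool(res.success)
        iterates.append(np.array(x))
    # converged if the polish run met its tolerances or changed nothing
    stable = bool(np.allclose(iterates[0], iterates[1], rtol=1e-7, atol=1e-10))
    converged = success or stable
    out = dict(zip(keys, map(float, x)))
    out["converged"] = converged
    out["min_mse"] = float(objective(x))
    return out


# ---------------------------------------------------------------------------
# published-vs-canonical audit
# ---------------------------------------------------------------------------

def _rel_diff(a: float, b: float) -> float:
    scale = max(abs(a), abs(b), 1e-300)
    return abs(a - b) / scale


def audit_formulas(
    params: ScramblingParams,
    pm: PopulationMoments,
    n: int,
    population: str = "",
    tol: float = 1e-6,
) -> list[dict]:
    """Machine-readable published-vs-canonical comparison for every family.

    Each record carries the family, the quantity, both values, their
    relative difference and a verdict (``agree`` / ``discrepant`` /
    ``incomplete_published_algebra``).  Families with free constants are
    audited at their canonical optimum.
    """
    records = []
    for family in ("usual", "ratio", "genratio", "diff1", "diff2",
                   "saleem_gen", "proposed", "azeem_usual", "azeem_ratio"):
        exponents = DEFAULT_EXPONENTS.get(family, {})
        keys = CONSTANT_KEYS.get(family, ())
        if family == "genratio":
            a_opt = optimal_constants(family, params, pm, n, exponents)["wpsig"]
            exponents = {"g": 1.0, "w": a_opt, "a": 1.0, "b": 0.0}
            constants = {}
        elif keys:
            constants = optimal_constants(family, params, pm, n, exponents)
        else:
            constants = {}
        can = bias_mse(family, params, pm, n, constants, exponents, "canonical")
        chk = bias_mse(family, params, pm, n, constants, exponents, "published")
        for quantity in ("bias", "mse"):
            a, b = getattr(chk, quantity), getattr(can, quantity)
            if quantity == "mse" and family == "saleem_gen":
                verdict = "incomplete_published_algebra"
            else:
                verdict = "agree" if _rel_diff(a, b) <= tol else "discrepant"
            records.append({
                "family": family,
                "population": population,
                "quantity": quantity,
                "published_value": float(a),
                "canonical_value": float(b),
                "rel_diff": float(_rel_diff(a, b)),
                "verdict": verdict,
            })
    return records
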