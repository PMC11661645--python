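"""Literal transcriptions of the published first-order bias/MSE displays.

These are the closed forms as commonly reported in the survey-sampling
literature for the randomized-response variance-estimation families, kept
symbol-for-symbol so that the package's canonical (re-derived) algebra can
be audited against them.  Known transcription choices, each flagged by the
audit machinery rather than silently corrected:

* the single-auxiliary difference family's cross quantity ``pi2`` carries
  coefficient 1 on the ``c_M*Zbar^2*gamma_120*C_z`` term as reported (the
  expansion gives 2);
* the mixture-model usual-estimator MSE is reported with a spurious leading
  minus sign, dropped here (a mean square cannot be negative);
* the mixture-model ratio-estimator MSE is transcribed per its most literal
  reading, including oddly-powered scrambling-variance terms, with the
  sampling fraction ``theta`` restored as a common factor;
* in the proposed-class variance quantity ``eta1`` an undefined pair of
  starred constants is read as ``H* H**``; the reported ``eta7`` lacks a
  1/8 on one term and the reported ``eta9`` lacks ``theta`` on two terms —
  ``eta7`` is kept literal, ``eta9`` takes the dimensionally forced
  ``theta``;
* the reported bias of the proposed class repeats the exponent ``pi2`` in
  the third-constant term where the structure calls for ``pi3``; kept
  literal.

The three-constant generalized class's variance quadratic is not fully
transcribable (its reported coefficient list is incomplete), so no
published-mode MSE exists for it; see :func:`rrtvar.theory.bias_mse`.
"""

from __future__ import annotations

from .models import ModelConstants
from .moments import PopulationMoments


class _Ctx:
    """Local aliases shared by every transcription."""

    def __init__(self, mc: ModelConstants, pm: PopulationMoments, n: int):
        self.th = 1.0 / n
        self.c = mc.scale
        self.cS = mc.c_S
        self.cM = mc.c_M
        self.sz2 = pm.sigma2_z
        self.Z = pm.Zbar
        self.Cz = pm.Cz
        self.sx12 = pm.sigma2_x1
        self.sx22 = pm.sigma2_x2
        self.star2 = pm.sigma2_z - mc.c_S - mc.c_lin * pm.Zbar - mc.c_M * pm.Zbar**2
        g, gs = pm.gamma_at, pm.gamma_star
        self.g400s = gs((4, 0, 0))
        self.g040s = gs((0, 4, 0))
        self.g004s = gs((0, 0, 4))
        self.g220s = gs((2, 2, 0))
        self.g202s = gs((2, 0, 2))
        self.g022s = gs((0, 2, 2))
        self.g300 = g((3, 0, 0))
        self.g120 = g((1, 2, 0))
        self.g102 = g((1, 0, 2))


def usual_bias(x: _Ctx) -> float:
    return -x.th * x.cM * x.Z**2 * x.Cz**2 / x.c


def usual_mse(x: _Ctx) -> float:
    return (x.th / x.c**2) * (
        x.sz2**2 * x.g400s
        + 4.0 * x.cM**2 * x.Z**4 * x.Cz**2
        - 4.0 * x.sz2 * x.cM * x.Z**2 * x.g300 * x.Cz
    )


def ratio_bias(x: _Ctx) -> float:
    return (x.th / x.c) * (
        x.sz2 * (x.g040s - x.g220s)
        - x.cS * x.g040s
        - x.cM * x.Z**2 * (x.Cz**2 + x.g040s - 2.0 * x.g120 * x.Cz)
    )


def ratio_mse(x: _Ctx) -> float:
    return (x.th / x.c**2) * (
        x.sz2**2 * (x.g040s + x.g400s - 2.0 * x.g220s)
        + x.cS**2 * x.g040s
        + x.cM**2 * x.Z**4 * (x.g040s + 4.0 * x.Cz**2 - 4.0 * x.g120 * x.Cz)
        - 2.0 * x.sz2 * x.cS * (x.g040s - x.g220s)
        - 2.0 * x.cM * x.sz2 * x.Z**2
        * (x.g040s - x.g220s - 2.0 * x.g120 * x.Cz + 2.0 * x.g300 * x.Cz)
        + 2.0 * x.cM * x.cS * x.Z**2 * (x.g040s - 2.0 * x.g120 * x.Cz)
    )


def genratio_bias(x: _Ctx, wpsi: float, g: float) -> float:
    a = g * wpsi
    q = g * (g + 1.0) / 2.0 * wpsi**2
    return (x.th / x.c) * (
        x.sz2 * (-a * x.g220s + q * x.g040s)
        - x.cS * q * x.g040s
        - x.cM * x.Z**2 * (x.Cz**2 + q * x.g040s - 2.0 * a * x.g120 * x.Cz)
        + x.sx12 * a * x.g040s * x.c
    )


def genratio_deltas(x: _Ctx) -> tuple[float, float, float]:
    d1 = (
        x.sz2**2 * x.g400s
        + 4.0 * x.cM**2 * x.Z**4 * x.Cz**2
        + x.sx12**2 * x.c**2 * x.g040s
        - 4.0 * x.sz2 * x.cM * x.Z**2 * x.g300 * x.Cz
        - 2.0 * x.sz2 * x.sx12 * x.c * x.g220s
        + 4.0 * x.cM * x.sx12 * x.Z**2 * x.g120 * x.Cz * x.c
    )
    d2 = x.g040s * (
        x.sz2**2 + x.cS**2 + x.cM**2 * x.Z**4
        - 2.0 * x.sz2 * x.cS - 2.0 * x.sz2 * x.cM * x.Z**2
        + 2.0 * x.cS * x.cM * x.Z**2
    )
    d3 = (
        x.g220s * (x.sz2**2 - x.sz2 * x.cS - x.sz2 * x.cM * x.Z**2)
        + 2.0 * x.g120 * x.Cz
        * (x.cM**2 * x.Z**4 - x.Z**2 * x.sz2 * x.cM + x.cS * x.cM * x.Z**2)
        + x.g040s * x.c * x.sx12 * (-x.sz2 + x.cS + x.cM * x.Z**2)
    )
    return d1, d2, d3


def genratio_mse(x: _Ctx, wpsi: float, g: float) -> float:
    a = g * wpsi
    d1, d2, d3 = genratio_deltas(x)
    return (x.th / x.c**2) * (d1 + a**2 * d2 - 2.0 * a * d3)


def diff1_pi(x: _Ctx) -> tuple[float, float]:
    pi1 = (
        x.sz2**2 * x.g400s
        + 4.0 * x.cM**2 * x.Z**4 * x.Cz**2
        - 4.0 * x.sz2 * x.cM * x.g300 * x.Cz * x.Z**2
    )
    # reported with coefficient 1 on the gamma_120 term (expansion gives 2)
    pi2 = x.sz2 * x.g220s - x.cM * x.Z**2 * x.g120 * x.Cz
    return pi1, pi2


def diff1_mse(x: _Ctx, K: float) -> float:
    pi1, pi2 = diff1_pi(x)
    return (x.th / x.c**2) * (
        pi1
        - 2.0 * K * x.c * x.sx12 * pi2
        + K**2 * x.sx12**2 * x.c**2 * x.g040s
    )


def diff2_bias(x: _Ctx, J1: float) -> float:
    return ((J1 - 1.0) * x.star2 - J1 * x.th * x.cM * x.Z**2 * x.Cz**2) / x.c


def diff2_U(x: _Ctx) -> dict[str, float]:
    pi1, _ = diff1_pi(x)
    return {
        "U1": x.star2**2
        + x.th * (pi1 - 2.0 * x.star2 * x.cM * x.Z**2 * x.Cz**2),
        "U2": x.th * x.sx12**2 * x.c**2 * x.g040s,
        "U3": x.th * x.sx22**2 * x.c**2 * x.g004s,
        "U4": x.star2**2 - x.th * x.star2 * x.cM * x.Z**2 * x.Cz**2,
        "U5": x.th * x.sx12 * x.c
        * (x.sz2 * x.g220s - 2.0 * x.cM * x.Z**2 * x.g120 * x.Cz),
        "U6": x.th * x.sx22 * x.c
        * (x.sz2 * x.g202s - 2.0 * x.cM * x.Z**2 * x.g102 * x.Cz),
        "U7": x.th * x.sx12 * x.sx22 * x.c**2 * x.g022s,
    }


def diff2_mse(x: _Ctx, J1: float, J2: float, J3: float) -> float:
    U = diff2_U(x)
    return (
        x.star2**2
        + J1**2 * U["U1"] + J2**2 * U["U2"] + J3**2 * U["U3"]
        - 2.0 * J1 * U["U4"] - 2.0 * J1 * J2 * U["U5"] - 2.0 * J1 * J3 * U["U6"]
        + 2.0 * J2 * J3 * U["U7"]
    ) / x.c**2


def saleem_bias(
    x: _Ctx, K1: float, K2: float, K3: float, l1: float, l2: float
) -> float:
    a1 = l1 * (l1 + 2.0) / 8.0
    a2 = l2 * (l2 + 1.0) / 2.0
    a3 = l1 * l2 / 2.0
    asum = a1 * x.g040s + a2 * x.g004s + a3 * x.g022s
    return (
        (K1 - 1.0) * x.star2
        + K1 * x.th * (
            x.sz2 * (-0.5 * l1 * x.g220s - l2 * x.g202s + asum)
            - x.cS * asum
            - x.Z**2 * x.cM
            * (x.Cz**2 - l1 * x.g120 * x.Cz - 2.0 * l2 * x.g102 * x.Cz + asum)
        )
        - K2 * x.c * x.sx12 * x.th * (-0.5 * l1 * x.g040s - l2 * x.g022s)
        - K3 * x.c * x.sx22 * x.th * (-0.5 * l1 * x.g022s - l2 * x.g004s)
    ) / x.c


def proposed_bias(
    x: _Ctx, L1: float, L2: float, L3: float,
    p1: float, p2: float, p3: float,
) -> float:
    q1 = p1 * (p1 + 2.0) / 8.0
    return (
        (L1 - 1.0) * x.star2
        + L1 * x.th * (
            x.sz2 * (-0.5 * p1 * x.g220s + q1 * x.g040s)
            - x.cS * q1 * x.g040s
            - x.Z**2 * x.cM * (x.Cz**2 - p1 * x.g120 * x.Cz + q1 * x.g040s)
        )
        # third-constant term reported with pi2 where the structure calls
        # for pi3; kept literal
        + L2 * x.c * (1.0 + x.th * p2 * (p2 - 2.0) / 8.0 * x.g040s)
        + L3 * x.c * (1.0 + x.th * p2 * (p2 - 2.0) / 8.0 * x.g004s)
    ) / x.c


def proposed_eta(
    x: _Ctx, p1: float, p2: float, p3: float, sigma2_T: float
) -> dict[str, float]:
    """The nine reported variance-quadratic coefficients of the proposed
    class, transcribed literally (H = scale, H* = cS/(alpha^2 sigma_S^2)
    folded into cS, H** = cM)."""
    th, sz2, Z, Cz = x.th, x.sz2, x.Z, x.Cz
    H, cS, cM = x.c, x.cS, x.cM
    g040s, g004s, g220s, g202s, g022s = x.g040s, x.g004s, x.g220s, x.g202s, x.g022s
    g400s, g300, g120, g102 = x.g400s, x.g300, x.g120, x.g102
    star2 = x.star2
    q1 = p1 * (p1 + 2.0) / 8.0

    eta1 = (
        star2**2
        + sz2**2 * th * (g400s + 0.25 * p1**2 * g040s - p1 * g220s)
        + 0.25 * cS**2 * th * p1**2 * g040s
        - 2.0 * cS * sz2 * th * (-0.5 * p1 * g220s + 0.25 * p1**2 * g040s)
        + Z**4 * cM**2 * th
        * (4.0 * Cz**2 + 0.25 * p1**2 * g040s - 2.0 * p1 * g120 * Cz)
        - 2.0 * Z**2 * sz2 * cM * th
        * (-0.5 * p1 * g220s + 2.0 * g300 * Cz + 0.25 * p1**2 * g040s
           - p1 * g120 * Cz)
        # undefined starred pair read as H* H**; note the reported extra
        # sigma_T^2 factor is kept
        + 2.0 * cS * sigma2_T * Z**2 * cM * th
        * (0.25 * p1**2 * g040s - p1 * g120 * Cz)
        + 2.0 * star2 * (
            sz2 * th * (-0.5 * p1 * g220s + q1 * g040s)
            - cS * th * q1 * g040s
            - Z**2 * cM * th * (Cz**2 - p1 * g120 * Cz + q1 * g040s)
        )
    )
    eta2 = H**2 * (1.0 + 0.5 * th * p2 * (p2 - 1.0) * g040s)
    eta3 = H**2 * (1.0 + 0.5 * th * p3 * (p3 - 1.0) * g004s)
    eta4 = star2**2 + star2 * th * (
        sz2 * (-0.5 * p1 * g220s + q1 * g040s)
        - cS * q1 * g040s
        - Z**2 * cM * (Cz**2 - p1 * g120 * Cz + q1 * g040s)
    )
    eta5 = star2 * H * (1.0 + th * p2 * (p2 - 2.0) / 8.0 * g040s)
    eta6 = star2 * H * (1.0 + th * p3 * (p3 - 2.0) / 8.0 * g004s)
    eta7 = H * (
        star2 * (1.0 + th * p2 * (p2 - 1.0) / 8.0 * g040s)
        # reported without the 1/8 on the second term; kept literal
        + sz2 * th * (0.5 * (p2 - p1) * g220s + p1 * (p1 - 2.0 * p2 + 2.0) * g040s)
        - cS * th * (p1 * (p1 - 2.0 * p2 + 2.0) / 8.0 * g040s)
        - Z**2 * cM * th
        * (Cz**2 + (p2 - p1) * g120 * Cz
           + p1 * (p1 - 2.0 * p2 + 2.0) / 8.0 * g040s)
    )
    eta8 = H * (
        star2 * (1.0 + th * p3 * (p3 - 1.0) / 8.0 * g004s)
        + sz2 * th * (0.5 * p3 * g202s - 0.25 * p1 * p3 * g022s
                      + q1 * g040s - 0.5 * p1 * g220s)
        - cS * th * (-0.25 * p1 * p3 * g022s + q1 * g040s)
        - Z**2 * cM * th
        * (-0.25 * p1 * p3 * g022s + p3 * g102 * Cz + Cz**2 + q1 * g040s)
    )
    eta9 = H**2 * (
        1.0
        + 0.25 * th * p2 * p3 * g022s
        + th * p2 * (p2 - 2.0) / 8.0 * g040s
        + th * p3 * (p3 - 2.0) / 8.0 * g004s
    )
    return {f"eta{i}": v for i, v in enumerate(
        (eta1, eta2, eta3, eta4, eta5, eta6, eta7, eta8, eta9), start=1
    )}


def proposed_mse(
    x: _Ctx, L1: float, L2: float, L3: float,
    p1: float, p2: float, p3: float, sigma2_T: float,
) -> float:
    e = proposed_eta(x, p1, p2, p3, sigma2_T)
    return (
        x.star2**2
        + L1**2 * e["eta1"] + L2**2 * e["eta2"] + L3**2 * e["eta3"]
        - 2.0 * L1 * e["eta4"] - 2.0 * L2 * e["eta5"] - 2.0 * L3 * e["eta6"]
        + 2.0 * L1 * L2 * e["eta7"] + 2.0 * L1 * L3 * e["eta8"]
        + 2.0 * L2 * L3 * e["eta9"]
    ) / x.c**2


def azeem_usual_bias(x: _Ctx) -> float:
    A = x.c
    return -x.th * x.Z**2 * x.Cz**2 * (A - 1.0) / A


def azeem_usual_mse(x: _Ctx) -> float:
    # reported with a spurious leading minus sign, dropped
    A = x.c
    return (x.th / A**2) * (
        x.sz2**2 * x.g400s
        + 4.0 * x.Z**4 * (A - 1.0) ** 2 * x.Cz**2
        - 4.0 * x.sz2 * x.Z**2 * (A - 1.0) * x.g300 * x.Cz
    )


def azeem_ratio_bias(x: _Ctx, N: int, n: int) -> float:
    A = x.c
    D = (n - 1) / (N - n)
    return -(x.th / A) * (
        D * x.sz2 * x.g220s
        + x.Z**2 * (A - 1.0) * (x.Cz**2 - 2.0 * D * x.g120 * x.Cz)
    )


def azeem_ratio_mse(
    x: _Ctx, N: int, n: int, mix: float, sigma2_S: float
) -> float:
    """Most literal reading of the reported display, with theta restored."""
    A = x.c
    D = (n - 1) / (N - n)
    l, sS2 = mix, sigma2_S
    return (x.th / A**2) * (
        x.sz2**2 * (x.g400s + D**2 * x.g040s - 2.0 * D * x.g220s)
        + x.Z**4 * (4.0 * x.Cz**2 + D**2 * x.g040s - 4.0 * D * x.g120 * x.Cz)
        + l**4 * sS2 * D**2 * x.g040s
        - 2.0 * x.sz2 * x.Z**2
        * (2.0 * x.g300 * x.Cz - D * x.g220s - 2.0 * D * x.g120 * x.Cz
           + D**2 * x.g040s)
        + 2.0 * x.sz2 * l**2 * D**2 * sS2 * D * (x.g220s - D * x.g040s)
        - 2.0 * sS2 * x.Z**2 * l**2 * D * (A - 1.0)
        * (2.0 * x.g120 * x.Cz - D**2 * x.g040s)
    )
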