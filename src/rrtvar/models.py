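"""Scrambled randomized-response models for a quantitative sensitive variable.

Four scrambling rules map the true value ``Y`` and independent scrambling
variables ``S`` (additive, ``E[S] = 0``, ``Var[S] = sigma2_S``) and ``T``
(multiplicative, ``E[T] = 1``, ``Var[T] = sigma2_T``) to a reported value
``Z``:

====================  =====================================================
model                 reported response
====================  =====================================================
``diana_perri``       ``Z = T*Y + S``
``generalized_h``     ``Z = h*(Y + a*S) + (1 - h)*(T*Y + a*S)``
``saleem_g``          ``Z = g*(Y + a*S) + (1 - g)*T*(Y + a*S)``
``azeem_l``           ``Z = l*(Y + S) + (1 - l)*(Y + Y*S)``
====================  =====================================================

Each model implies a variance identity linking the variance of the reported
response to the variance of the sensitive variable,

    sigma_z^2 = scale * sigma_y^2 + c_S + c_lin * mu_Y + c_M * mu_Y^2,

and hence an unscrambled plug-in estimator of the finite-population variance

    sigma_y_hat^2 = (s_z^2 - c_S - c_lin * zbar - c_M * zbar^2) / scale.

Two coefficient conventions are supported for the mixing models.  The
``"published"`` convention uses the commonly reported constants in which the
mixing weight enters through ``1 - h^2`` (e.g. ``H = h^2 +
(1 - h^2)*(sigma_T^2 + 1)``).  The ``"literal"`` convention expands the
mixing equation as written, which yields ``(1 - h)^2`` instead: the mixing
coefficient ``h + (1 - h)*T`` has variance ``(1 - h)^2 * sigma_T^2``.  The
two agree at ``h`` in ``{0, 1}`` and the package never silently prefers one;
:func:`rrtvar.synthpop.audit_scramble_variance` adjudicates them by
Monte-Carlo.  For the ``azeem_l`` model the published identity uses ``A =
l^2 + (1 - l^2)*(1 + sigma_S^2)``, while the literal expansion carries a
term linear in ``mu_Y`` (the ``c_lin`` slot); they also agree at the
endpoints ``l`` in ``{0, 1}``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .errors import DegenerateModelError, InvalidParameterError

MODEL_NAMES = ("diana_perri", "saleem_g", "generalized_h", "azeem_l")
CONVENTIONS = ("published", "literal")


@dataclass(frozen=True)
class ScramblingParams:
    """Parameters of a scrambling model.

    Parameters
    ----------
    model : str
        One of ``diana_perri``, ``saleem_g``, ``generalized_h``, ``azeem_l``.
    sigma2_S, sigma2_T : float
        Variances of the additive (mean-0) and multiplicative (mean-1)
        scrambling variables.  ``sigma2_T`` is unused by ``azeem_l``.
    alpha : float
        Weight on the additive scrambler in the ``generalized_h`` and
        ``saleem_g`` models; unused by ``diana_perri`` and ``azeem_l``.
    mix : float
        Mixing constant in ``[0, 1]`` (``h``, ``g`` or ``l`` depending on
        the model); unused by ``diana_perri``.
    coeff_convention : str
        ``"published"`` (default) or ``"literal"``; see the module docstring.
    """

    model: str
    sigma2_S: float = 1.0
    sigma2_T: float = 1.0
    alpha: float = 1.0
    mix: float = 0.0
    coeff_convention: str = "published"

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.sigma2_S < 0 or self.sigma2_T < 0:
            raise InvalidParameterError("scrambling variances must be >= 0")
        if not 0.0 <= self.mix <= 1.0:
            raise InvalidParameterError("mix must lie in [0, 1]")
        if self.coeff_convention not in CONVENTIONS:
            raise InvalidParameterError(
                f"unknown coefficient convention {self.coeff_convention!r}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ScramblingParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ModelConstants:
    """Derived constants of a scrambling model.

    ``scale``, ``c_S``, ``c_lin`` and ``c_M`` form the common unscrambling
    tuple; the named constants (``H``, ``H_star``, ``H_dstar``, ``G``, ``A``)
    are retained so formulas can be read symbol-for-symbol against the
    survey-sampling literature.  ``H_star`` simplifies to 1 identically but
    is kept as a named quantity.
    """

    scale: float
    c_S: float
    c_M: float
    c_lin: float = 0.0
    H: float | None = None
    H_star: float | None = None
    H_dstar: float | None = None
    G: float | None = None
    A: float | None = None


def model_constants(params: ScramblingParams) -> ModelConstants:
    """Reduce a scrambling model to its unscrambling constants.

    Raises
    ------
    DegenerateModelError
        If the unscrambling scale is not strictly positive.
    """
    s2S, s2T, a, m = params.sigma2_S, params.sigma2_T, params.alpha, params.mix
    published = params.coeff_convention == "published"

    if params.model == "diana_perri":
        mc = ModelConstants(scale=s2T + 1.0, c_S=s2S, c_M=s2T)
    elif params.model == "generalized_h":
        one_minus = (1.0 - m**2) if published else (1.0 - m) ** 2
        # H = m^2 + (1 - m^2) + one_minus*s2T; the mixing weights sum to 1
        H_dstar = one_minus * s2T  # = H - 1 exactly
        H = 1.0 + H_dstar
        H_star = m**2 + (1.0 - m**2)  # identically 1
        mc = ModelConstants(
            scale=H, c_S=a**2 * s2S * H_star, c_M=H_dstar,
            H=H, H_star=H_star, H_dstar=H_dstar,
        )
    elif params.model == "saleem_g":
        one_minus = (1.0 - m**2) if published else (1.0 - m) ** 2
        G = 1.0 + one_minus * s2T
        mc = ModelConstants(scale=G, c_S=a**2 * s2S * G, c_M=one_minus * s2T, G=G)
    else:  # azeem_l
        A = m**2 + (1.0 - m**2) * (1.0 + s2S)  # = 1 + (1 - l^2)*s2S
        if published:
            mc = ModelConstants(scale=A, c_S=m**2 * s2S, c_M=A - 1.0, A=A)
        else:
            # Direct expansion of Z = Y + l*S + (1-l)*Y*S: the cross term
            # 2*l*(1-l)*sigma_S^2*mu_Y is linear in the mean.
            mc = ModelConstants(
                scale=1.0 + (1.0 - m) ** 2 * s2S,
                c_S=m**2 * s2S,
                c_M=(1.0 - m) ** 2 * s2S,
                c_lin=2.0 * m * (1.0 - m) * s2S,
                A=A,
            )
    if mc.scale <= 0.0:
        raise DegenerateModelError(f"non-positive unscrambling scale {mc.scale}")
    return mc


def variance_identity(
    params: ScramblingParams, sigma2_y: float, mu_Y: float
) -> float:
    """Variance of the reported response implied by the model.

    Returns ``scale*sigma2_y + c_S + c_lin*mu_Y + c_M*mu_Y**2``.
    """
    mc = model_constants(params)
    return mc.scale * sigma2_y + mc.c_S + mc.c_lin * mu_Y + mc.c_M * mu_Y**2


def unscramble_variance_estimator(
    params: ScramblingParams,
    stats,
    *,
    floor_at_zero: bool = False,
):
    """Unscrambled plug-in estimator of the population variance of Y.

    Parameters
    ----------
    params : ScramblingParams
    stats : SampleStats or any object with ``s2_z`` and ``zbar`` attributes
        (array-valued fields are broadcast).
    floor_at_zero : bool
        Clip negative estimates at zero.  Off by default: the first-order
        theory assumes no truncation, so negative values are reported as-is.
    """
    mc = model_constants(params)
    est = (stats.s2_z - mc.c_S - mc.c_lin * stats.zbar - mc.c_M * stats.zbar**2) / mc.scale
    if floor_at_zero:
        import numpy as np

        est = np.maximum(est, 0.0)
    return est
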