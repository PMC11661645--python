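import numpy as np
import pytest

from rrtvar import (
    EstimatorSpec,
    InvalidParameterError,
    KnownAuxiliary,
    SampleStats,
    ScramblingParams,
    estimate,
    sx_star,
)
from rrtvar.simulate import PROPOSED_GRID, SALEEM_GRID
from conftest import S2S, S2T

PARAMS = ScramblingParams("generalized_h", S2S, S2T, alpha=1.0, mix=0.0)
AUX = KnownAuxiliary(sigma2_x1=2.0, sigma2_x2=2.0, N=500)
STATS = SampleStats(n=50, zbar=5.2, s2_z=17.1, s2_x1=1.7, s2_x2=2.4)


def _est(family, exponents=None, constants=None):
    return estimate(
        EstimatorSpec(family, exponents or {}, constants or {}),
        PARAMS, STATS, AUX,
    )


class TestSxStar:
    def test_fixed_point(self):
        assert sx_star(2.0, 2.0, 500, 50) == pytest.approx(2.0)

    def test_hand_value(self):
        assert sx_star(0.0, 2.0, 500, 50) == pytest.approx(499 * 2 / 450)

    def test_equal_sizes_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sx_star(1.0, 2.0, 50, 50)


class TestReductions:
    def test_diff1_at_zero_K_is_usual(self):
        assert _est("diff1", constants={"K": 0.0}) == pytest.approx(
            _est("usual"), rel=1e-14
        )

    def test_diff2_nests_diff1(self):
        K = 0.7312
        d2 = _est("diff2", constants={"J1": 1.0, "J2": K, "J3": 0.0})
        assert d2 == pytest.approx(_est("diff1", constants={"K": K}), rel=1e-14)

    def test_proposed_collapses_to_usual(self):
        val = _est("proposed", {"pi1": 0.0, "pi2": 0.0, "pi3": 0.0},
                   {"L1": 1.0, "L2": 0.0, "L3": 0.0})
        assert val == pytest.approx(_est("usual"), rel=1e-14)

    def test_saleem_collapses_to_usual(self):
        val = _est("saleem_gen", {"lambda1": 0.0, "lambda2": 0.0},
                   {"K1": 1.0, "K2": 0.0, "K3": 0.0})
        assert val == pytest.approx(_est("usual"), rel=1e-14)

    def test_population_level_direct_response_is_exact(self, pop1):
        # the whole population as the sample, no scrambling: the usual
        # estimator returns sigma_y^2 exactly
        direct = ScramblingParams("generalized_h", 0.4, 0.4, alpha=0.0, mix=1.0)
        stats = SampleStats(
            n=pop1.N,
            zbar=float(pop1.y.mean()),
            s2_z=float(np.var(pop1.y, ddof=1)),
            s2_x1=float(np.var(pop1.x1, ddof=1)),
            s2_x2=float(np.var(pop1.x2, ddof=1)),
        )
        aux = KnownAuxiliary(stats.s2_x1, stats.s2_x2, pop1.N)
        val = estimate(EstimatorSpec("usual"), direct, stats, aux)
        assert val == pytest.approx(np.var(pop1.y, ddof=1), rel=1e-14)


class TestGridNesting:
    @pytest.mark.parametrize("l1,l2", SALEEM_GRID)
    def test_saleem_grid_matches_hand_formula(self, l1, l2):
        consts = {"K1": 0.93, "K2": 0.21, "K3": -0.35}
        got = _est("saleem_gen", {"lambda1": float(l1), "lambda2": float(l2)},
                   consts)
        base = (consts["K1"] * _est("usual")
                + consts["K2"] * (AUX.sigma2_x1 - STATS.s2_x1)
                + consts["K3"] * (AUX.sigma2_x2 - STATS.s2_x2))
        factor = (
            np.exp((AUX.sigma2_x1 - STATS.s2_x1)
                   / (AUX.sigma2_x1 + STATS.s2_x1)) ** l1
            * (AUX.sigma2_x2 / STATS.s2_x2) ** l2
        )
        assert got == pytest.approx(base * factor, rel=1e-13)

    @pytest.mark.parametrize("p1,p2,p3", PROPOSED_GRID)
    def test_proposed_grid_matches_hand_formula(self, p1, p2, p3):
        consts = {"L1": 0.88, "L2": 1.4, "L3": -0.6}
        got = _est("proposed", {"pi1": float(p1), "pi2": float(p2),
                                "pi3": float(p3)}, consts)
        e1 = np.exp((AUX.sigma2_x1 - STATS.s2_x1)
                    / (AUX.sigma2_x1 + STATS.s2_x1))
        e2 = np.exp((STATS.s2_x1 - AUX.sigma2_x1)
                    / (STATS.s2_x1 + AUX.sigma2_x1))
        e3 = np.exp((STATS.s2_x2 - AUX.sigma2_x2)
                    / (STATS.s2_x2 + AUX.sigma2_x2))
        expected = (consts["L1"] * _est("usual") * e1**p1
                    + consts["L2"] * e2**p2 + consts["L3"] * e3**p3)
        assert got == pytest.approx(expected, rel=1e-13)


class TestScaleEquivariance:
    def test_ratio_type_families_invariant_to_auxiliary_rescaling(self):
        c = 3.7
        aux_s = KnownAuxiliary(AUX.sigma2_x1 * c**2, AUX.sigma2_x2, AUX.N)
        stats_s = SampleStats(n=STATS.n, zbar=STATS.zbar, s2_z=STATS.s2_z,
                              s2_x1=STATS.s2_x1 * c**2, s2_x2=STATS.s2_x2)
        # genratio is excluded: its un-coefficiented additive difference
        # term (sigma_x1^2 - s_x1^2) scales with the auxiliary, so the
        # family as defined is not scale-equivariant
        for family, exps, consts, consts_s in [
            ("ratio", {}, {}, {}),
            ("diff1", {}, {"K": 0.4}, {"K": 0.4 / c**2}),
            ("saleem_gen", {"lambda1": 1.0, "lambda2": -1.0},
             {"K1": 0.9, "K2": 0.3, "K3": 0.2},
             {"K1": 0.9, "K2": 0.3 / c**2, "K3": 0.2}),
            ("proposed", {"pi1": 1.0, "pi2": -1.0, "pi3": 0.5},
             {"L1": 0.9, "L2": 1.0, "L3": 1.0},
             {"L1": 0.9, "L2": 1.0, "L3": 1.0}),
        ]:
            a = estimate(EstimatorSpec(family, exps, consts), PARAMS, STATS, AUX)
            b = estimate(EstimatorSpec(family, exps, consts_s), PARAMS,
                         stats_s, aux_s)
            assert a == pytest.approx(b, rel=1e-12), family


def test_estimator_spec_json_round_trip():
    spec = EstimatorSpec("proposed", {"pi1": 1.0, "pi2": -1.0, "pi3": 0.0},
                         {"L1": 0.9, "L2": 1.0, "L3": 0.5})
    assert EstimatorSpec.from_json(spec.to_json()) == spec
    opt = EstimatorSpec("diff2", {}, "optimal")
    assert EstimatorSpec.from_json(opt.to_json()).constants == "optimal"


class TestErrors:
    def test_zero_sample_variance_raises_for_ratio(self):
        stats = SampleStats(n=50, zbar=5.0, s2_z=17.0, s2_x1=0.0, s2_x2=1.0)
        with pytest.raises(ZeroDivisionError):
            estimate(EstimatorSpec("ratio"), PARAMS, stats, AUX)

    def test_missing_constants_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate(EstimatorSpec("diff1"), PARAMS, STATS, AUX)
        with pytest.raises(InvalidParameterError):
            estimate(EstimatorSpec("diff2", {}, "optimal"), PARAMS, STATS, AUX)

    def test_array_broadcasting_matches_scalar(self):
        stats = SampleStats(
            n=50,
            zbar=np.array([5.2, 4.8]),
            s2_z=np.array([17.1, 16.0]),
            s2_x1=np.array([1.7, 2.1]),
            s2_x2=np.array([2.4, 1.9]),
        )
        vec = estimate(EstimatorSpec("diff1", {}, {"K": 0.5}), PARAMS, stats, AUX)
        scalar0 = estimate(
            EstimatorSpec("diff1", {}, {"K": 0.5}), PARAMS,
            SampleStats(n=50, zbar=5.2, s2_z=17.1, s2_x1=1.7, s2_x2=2.4), AUX,
        )
        assert vec.shape == (2,)
        assert vec[0] == pytest.approx(scalar0, rel=1e-14)
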