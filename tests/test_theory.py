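import numpy as np
import pytest

from rrtvar import (
    EstimatorSpec,
    PopulationMoments,
    ScramblingParams,
    bias_mse,
    builtin_specs,
    delta_oracle,
    generate_population,
    min_mse,
    numeric_opt_oracle,
    optimal_constants,
    population_moments,
    scramble,
    audit_formulas,
)
from conftest import random_admissible, rel_diff

N_SAMPLE = 60

FAMILY_SETTINGS = [
    ("usual", {}, {}),
    ("ratio", {}, {}),
    ("diff1", {}, {"K": 0.8}),
    ("diff2", {}, {"J1": 0.95, "J2": 0.5, "J3": 0.3}),
    ("genratio", {"g": 1.2, "w": 0.7, "a": 1.0, "b": 0.5}, {}),
    ("saleem_gen", {"lambda1": 1.0, "lambda2": -1.0},
     {"K1": 0.9, "K2": 0.4, "K3": -0.2}),
    ("proposed", {"pi1": 1.0, "pi2": -1.0, "pi3": 0.5},
     {"L1": 0.9, "L2": 1.1, "L3": -0.4}),
    ("azeem_usual", {}, {}),
    ("azeem_ratio", {}, {}),
]

OPT_FAMILIES = [
    ("diff1", {}),
    ("diff2", {}),
    ("genratio", {"g": 1.0, "w": 1.0, "a": 1.0, "b": 0.0}),
    ("saleem_gen", {"lambda1": 1.0, "lambda2": 1.0}),
    ("proposed", {"pi1": 1.0, "pi2": 1.0, "pi3": 1.0}),
]


def _zero_scramble_pm(seed=13):
    """A 'scrambled' population with z = y (no privacy noise)."""
    spec = builtin_specs()[0]
    params = ScramblingParams("diana_perri", 0.0, 0.0)
    pop = scramble(generate_population(spec, seed), params, seed + 1)
    return params, population_moments(pop)


class TestOracleAgreement:
    @pytest.mark.parametrize("family,exps,consts", FAMILY_SETTINGS)
    def test_canonical_matches_delta_oracle(self, family, exps, consts, pm1):
        model = "azeem_l" if family.startswith("azeem") else "generalized_h"
        rng = np.random.default_rng(3)
        for _ in range(5):
            params, pm = random_admissible(rng, model=model)
            tr = bias_mse(family, params, pm, N_SAMPLE, consts, exps)
            orc = delta_oracle(
                EstimatorSpec(family, exps, consts), params, pm, N_SAMPLE
            )
            assert rel_diff(tr.bias, orc.bias) < 1e-6, family
            assert rel_diff(tr.mse, orc.mse) < 1e-6, family

    def test_linear_statistic_has_zero_oracle_bias(self, genh_params, pm1):
        # the usual estimator under direct response is linear in s_z^2
        direct = ScramblingParams("generalized_h", 0.0, 0.5, alpha=0.0, mix=1.0)
        orc = delta_oracle(EstimatorSpec("usual"), direct, pm1, N_SAMPLE)
        assert abs(orc.bias) < 1e-8 * pm1.sigma2_z


class TestTrivialReductions:
    def test_usual_bias_vanishes_without_multiplicative_noise(self, pm1):
        params = ScramblingParams("diana_perri", 0.4, 0.0)
        tr = bias_mse("usual", params, pm1, N_SAMPLE)
        assert tr.bias == pytest.approx(0.0, abs=1e-14)
        expected_mse = (pm1.sigma2_z**2 * pm1.gamma_star((4, 0, 0))) / N_SAMPLE
        assert tr.mse == pytest.approx(expected_mse, rel=1e-12)

    def test_azeem_bias_vanishes_at_l_one(self, pm1):
        params = ScramblingParams("azeem_l", 0.4, 0.0, mix=1.0)
        for mode in ("canonical", "published"):
            tr = bias_mse("azeem_usual", params, pm1, N_SAMPLE, mode=mode)
            assert tr.bias == pytest.approx(0.0, abs=1e-14), mode

    def test_diff1_mse_reduces_at_zero_scrambling(self):
        # theta*[sigma_y^4 g*400 - 2K sx1^2 sigma_y^2 g*220 + K^2 sx1^4 g*040]
        params, pm = _zero_scramble_pm()
        K = 0.6
        tr = bias_mse("diff1", params, pm, N_SAMPLE, {"K": K})
        th = 1.0 / N_SAMPLE
        expected = th * (
            pm.sigma2_y**2 * pm.gamma_star((4, 0, 0))
            - 2 * K * pm.sigma2_x1 * pm.sigma2_y * pm.gamma_star((2, 2, 0))
            + K**2 * pm.sigma2_x1**2 * pm.gamma_star((0, 4, 0))
        )
        assert tr.mse == pytest.approx(expected, rel=1e-12)

    def test_diff1_kopt_is_regression_coefficient_at_zero_scrambling(self):
        params, pm = _zero_scramble_pm()
        K = optimal_constants("diff1", params, pm, N_SAMPLE)["K"]
        expected = (pm.sigma2_y * pm.gamma_star((2, 2, 0))
                    / (pm.sigma2_x1 * pm.gamma_star((0, 4, 0))))
        assert K == pytest.approx(expected, rel=1e-12)


class TestOptima:
    @pytest.mark.parametrize("family,exps", OPT_FAMILIES)
    def test_numeric_oracle_matches_closed_form(self, family, exps,
                                                genh_params, pm1):
        closed = optimal_constants(family, genh_params, pm1, N_SAMPLE, exps)
        numeric = numeric_opt_oracle(family, genh_params, pm1, N_SAMPLE, exps)
        assert numeric["converged"]
        for key, val in closed.items():
            assert rel_diff(val, numeric[key]) < 1e-5, (family, key)

    @pytest.mark.parametrize("family,exps", OPT_FAMILIES)
    def test_optimum_beats_random_perturbations(self, family, exps,
                                                genh_params, pm1):
        closed = optimal_constants(family, genh_params, pm1, N_SAMPLE, exps)
        if family == "genratio":
            def mse_at(c):
                e = {"g": 1.0, "w": c["wpsig"], "a": 1.0, "b": 0.0}
                return bias_mse("genratio", genh_params, pm1, N_SAMPLE, {}, e).mse
        else:
            def mse_at(c):
                return bias_mse(family, genh_params, pm1, N_SAMPLE, c, exps).mse
        at_opt = mse_at(closed)
        rng = np.random.default_rng(17)
        for _ in range(25):
            pert = {k: v * (1.0 + rng.uniform(-0.1, 0.1))
                    for k, v in closed.items()}
            assert mse_at(pert) >= at_opt - 1e-12 * abs(at_opt), family

    @pytest.mark.parametrize("family,exps", OPT_FAMILIES)
    def test_min_mse_self_consistent(self, family, exps, genh_params, pm1):
        closed = optimal_constants(family, genh_params, pm1, N_SAMPLE, exps)
        mm = min_mse(family, genh_params, pm1, N_SAMPLE, exps)
        if family == "genratio":
            e = {"g": 1.0, "w": closed["wpsig"], "a": 1.0, "b": 0.0}
            at_opt = bias_mse("genratio", genh_params, pm1, N_SAMPLE, {}, e).mse
        else:
            at_opt = bias_mse(family, genh_params, pm1, N_SAMPLE, closed, exps).mse
        assert rel_diff(mm, at_opt) < 1e-8, family

    def test_published_mode_self_consistency_diff1(self, diana_params, pm1):
        closed = optimal_constants("diff1", diana_params, pm1, N_SAMPLE,
                                   mode="published")
        mm = min_mse("diff1", diana_params, pm1, N_SAMPLE, mode="published")
        at_opt = bias_mse("diff1", diana_params, pm1, N_SAMPLE, closed,
                          mode="published").mse
        assert rel_diff(mm, at_opt) < 1e-10

    def test_monotone_information_ordering(self, genh_params):
        # min MSE(two auxiliaries) <= min MSE(one) <= MSE(usual)
        for i, spec in enumerate(builtin_specs()):
            pop = scramble(generate_population(spec, 300 + i),
                           genh_params, 400 + i)
            pm = population_moments(pop)
            usual = bias_mse("usual", genh_params, pm, N_SAMPLE).mse
            m1 = min_mse("diff1", genh_params, pm, N_SAMPLE)
            m2 = min_mse("diff2", genh_params, pm, N_SAMPLE)
            assert m2 <= m1 + 1e-12 <= usual + 1e-12
            # nesting cross-check via the derivative-free oracle
            n1 = numeric_opt_oracle("diff1", genh_params, pm, N_SAMPLE)
            n2 = numeric_opt_oracle("diff2", genh_params, pm, N_SAMPLE)
            assert n2["min_mse"] <= n1["min_mse"] + 1e-9

    def test_uncorrelated_second_auxiliary_collapses_diff2_to_diff1(
        self, genh_params, pm1
    ):
        gamma = dict(pm1.gamma)
        gamma[(0, 2, 2)] = 1.0   # g*022 = 0
        gamma[(2, 0, 2)] = 1.0   # g*202 = 0
        gamma[(1, 0, 2)] = 0.0   # g102 = 0
        pm = PopulationMoments(
            N=pm1.N, Zbar=pm1.Zbar, Ybar=pm1.Ybar, sigma2_z=pm1.sigma2_z,
            sigma2_y=pm1.sigma2_y, sigma2_x1=pm1.sigma2_x1,
            sigma2_x2=pm1.sigma2_x2, Cz=pm1.Cz, gamma=gamma,
        )
        # the collapse forces J3 -> 0 and makes the second auxiliary inert:
        # the minimum is attained within the (J1, J2) subfamily.  (diff2
        # does NOT reduce to diff1 here — its J1 shrinkage freedom remains.)
        opt = optimal_constants("diff2", genh_params, pm, N_SAMPLE)
        assert opt["J3"] == pytest.approx(0.0, abs=1e-12)
        m2 = min_mse("diff2", genh_params, pm, N_SAMPLE)
        at_no_x2 = bias_mse("diff2", genh_params, pm, N_SAMPLE,
                            {"J1": opt["J1"], "J2": opt["J2"], "J3": 0.0}).mse
        assert m2 == pytest.approx(at_no_x2, rel=1e-12)
        inter = bias_mse("diff2", genh_params, pm, N_SAMPLE,
                         opt).intermediates
        assert inter["U6"] == pytest.approx(0.0, abs=1e-12)
        assert inter["U7"] == pytest.approx(0.0, abs=1e-12)


class TestAudit:
    def test_audit_verdicts(self, genh_params, pm1):
        records = {(r["family"], r["quantity"]): r
                   for r in audit_formulas(genh_params, pm1, N_SAMPLE, "Pop I")}
        for fam in ("usual", "ratio", "diff2", "azeem_usual"):
            assert records[(fam, "mse")]["verdict"] == "agree", fam
            assert records[(fam, "bias")]["verdict"] == "agree", fam
        # the reported single-auxiliary difference MSE carries a halved
        # cross-moment coefficient; the audit must flag it
        assert records[("diff1", "mse")]["verdict"] == "discrepant"
        assert records[("saleem_gen", "mse")]["verdict"] == (
            "incomplete_published_algebra")
        assert records[("azeem_ratio", "mse")]["verdict"] == "discrepant"
        for rec in records.values():
            assert set(rec) >= {"family", "population", "quantity",
                                "published_value", "canonical_value",
                                "rel_diff", "verdict"}
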