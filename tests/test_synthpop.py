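import numpy as np
import pytest

from rrtvar import (
    FinitePopulation,
    InvalidParameterError,
    InvalidSpecError,
    PopulationSpec,
    ScramblingParams,
    audit_scramble_variance,
    builtin_specs,
    generate_population,
    scramble,
)
from conftest import S2S, S2T


class TestBuiltinSpecs:
    def test_three_populations_with_printed_structure(self):
        specs = builtin_specs()
        assert len(specs) == 3
        for spec in specs:
            assert spec.N == 500
            assert spec.mean == (5.0, 5.0, 5.0)
        cov1, cov2, cov3 = (s.cov_array for s in specs)
        assert cov1[0, 0] == 10.0
        assert cov1[1, 2] == 1.1
        assert cov2[0, 0] == 6.0
        # Population II differs from I only in the sensitive-variable variance
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        assert np.array_equal(cov1[mask], cov2[mask])
        assert cov3[0, 0] == 9.0 and cov3[1, 1] == 4.0

    def test_covariances_symmetric_positive_definite(self):
        for spec in builtin_specs():
            cov = spec.cov_array
            assert np.array_equal(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_json_round_trip(self):
        spec = builtin_specs()[1]
        assert PopulationSpec.from_json(spec.to_json()) == spec

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            PopulationSpec("bad", (0, 0, 0),
                           ((1, 2, 0), (2, 1, 0), (0, 0, 1)), 100)
        with pytest.raises(InvalidSpecError):
            PopulationSpec("tiny", (0, 0, 0),
                           ((1, 0, 0), (0, 1, 0), (0, 0, 1)), 3)


class TestGeneratePopulation:
    def test_sample_variance_near_superpopulation_variance(self):
        spec = builtin_specs()[0]
        pop = generate_population(spec, seed=42)
        # normal-theory SE of a sample variance: sigma^2 * sqrt(2/N)
        assert abs(np.var(pop.y, ddof=1) - 10.0) < 4 * np.sqrt(2 / 500) * 10.0

    def test_independent_coordinates_uncorrelated(self):
        spec = PopulationSpec(
            "diag", (5, 5, 5), ((4, 0, 0), (0, 2, 0), (0, 0, 2)), 500
        )
        pop = generate_population(spec, seed=7)
        r = np.corrcoef(pop.y, pop.x1)[0, 1]
        assert abs(r) < 4 / np.sqrt(500)

    def test_deterministic_given_seed(self):
        spec = builtin_specs()[1]
        a = generate_population(spec, seed=99)
        b = generate_population(spec, seed=99)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.x1, b.x1)
        assert np.array_equal(a.x2, b.x2)

    def test_csv_round_trip(self, tmp_path, pop1_scrambled):
        path = tmp_path / "pop.csv"
        pop1_scrambled.to_csv(path)
        back = FinitePopulation.from_csv(path)
        np.testing.assert_allclose(back.z, pop1_scrambled.z)
        np.testing.assert_allclose(back.y, pop1_scrambled.y)


class TestScramble:
    def test_degenerate_models_return_y_exactly(self, pop1):
        direct = ScramblingParams("generalized_h", 0.5, 0.5, alpha=0.0, mix=1.0)
        assert np.array_equal(scramble(pop1, direct, 3).z, pop1.y)
        silent = ScramblingParams("diana_perri", 0.0, 0.0)
        assert np.array_equal(scramble(pop1, silent, 3).z, pop1.y)

    def test_scramble_deterministic(self, pop1, diana_params):
        a = scramble(pop1, diana_params, 5)
        b = scramble(pop1, diana_params, 5)
        assert np.array_equal(a.z, b.z)

    def test_negative_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScramblingParams("diana_perri", -0.1, 0.2)

    @pytest.mark.parametrize("model,mix", [
        ("diana_perri", 0.0), ("generalized_h", 0.5),
        ("saleem_g", 0.3), ("azeem_l", 0.7),
    ])
    def test_scrambled_mean_unbiased_for_population_mean(self, pop1, model, mix):
        # E(T)=1, E(S)=0 imply E(Z | y) = mean(y); check over many scrambles
        params = ScramblingParams(model, 1.0, 1.0, alpha=1.0, mix=mix)
        reps = 400
        means = np.array([
            scramble(pop1, params, 1000 + r).z.mean() for r in range(reps)
        ])
        se = means.std(ddof=1) / np.sqrt(reps)
        assert abs(means.mean() - pop1.y.mean()) < 4 * se


class TestAuditScrambleVariance:
    def test_endpoint_conventions_coincide_and_match(self):
        spec = builtin_specs()[0]
        for params in (
            ScramblingParams("generalized_h", 0.3, 0.3, alpha=1.0, mix=0.0),
            ScramblingParams("generalized_h", 0.0, 0.3, alpha=0.0, mix=1.0),
            ScramblingParams("azeem_l", 0.3, 0.0, mix=1.0),
        ):
            rep = audit_scramble_variance(spec, params, reps=150, seed=21)
            assert rep["published_value"] == pytest.approx(rep["literal_value"])
            assert rep["literal_matches"]

    def test_interior_mixing_flags_exactly_one_convention(self):
        # brute-force Monte-Carlo adjudication of the mixing coefficient
        spec = builtin_specs()[0]
        params = ScramblingParams("generalized_h", 1.0, 1.0, alpha=1.0, mix=0.5)
        rep = audit_scramble_variance(spec, params, reps=400, seed=22)
        assert rep["literal_matches"] and not rep["published_matches"]

    def test_azeem_interior_literal_identity_within_3se(self):
        # the literal expansion of the additive/multiplicative mixture carries
        # a cross term linear in the mean; it, not the published identity,
        # matches Monte-Carlo at interior l
        spec = builtin_specs()[0]
        for l in (0.25, 0.5, 0.75):
            params = ScramblingParams("azeem_l", S2S, S2T, mix=l)
            rep = audit_scramble_variance(spec, params, reps=300, seed=23)
            assert rep["literal_matches"]

    def test_reps_floor(self):
        spec = builtin_specs()[0]
        params = ScramblingParams("diana_perri", 0.2, 0.2)
        with pytest.raises(InvalidParameterError):
            audit_scramble_variance(spec, params, reps=50, seed=1)
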