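# Methods

## Setting

A finite population of `N` units carries a sensitive quantitative variable
`Y` and two non-sensitive auxiliary variables `X1`, `X2` whose population
variances are known.  Because respondents will not report `Y` directly,
each unit reports a scrambled value `Z` built from `Y` and independent
scrambling variables `S` (additive, `E[S] = 0`, `Var[S] = σ_S²`) and `T`
(multiplicative, `E[T] = 1`, `Var[T] = σ_T²`).  Four scrambling rules are
implemented:

| model           | reported response                        |
|-----------------|------------------------------------------|
| `diana_perri`   | `Z = T·Y + S`                            |
| `generalized_h` | `Z = h(Y + αS) + (1−h)(T·Y + αS)`        |
| `saleem_g`      | `Z = g(Y + αS) + (1−g)·T·(Y + αS)`       |
| `azeem_l`       | `Z = l(Y + S) + (1−l)(Y + Y·S)`          |

Each rule implies a variance identity
`σ_z² = scale·σ_y² + c_S + c_lin·μ_Y + c_M·μ_Y²` and therefore an
unscrambled plug-in estimator of the finite-population variance
`σ̂_y² = (s_z² − c_S − c_lin·z̄ − c_M·z̄²)/scale`, where `s_z²` and `z̄` are
the sample variance (divisor `n−1`) and mean of a simple random sample
drawn with replacement (SRSWR).  The estimator families (`usual`, `ratio`,
`genratio`, `diff1`, `diff2`, `saleem_gen`, `proposed`, `azeem_usual`,
`azeem_ratio`) sharpen the plug-in with the known auxiliary variances; see
the `rrtvar.estimators` docstring for the exact forms.

## Coefficient conventions

For the mixture models the literature's constants use `1 − h²` weights
(e.g. `H = h² + (1−h²)(σ_T²+1)`), whereas expanding the mixing equation as
written gives `(1−h)²`: the coefficient `h + (1−h)T` has variance
`(1−h)²σ_T²`.  The two coincide at `h ∈ {0, 1}`.  Both are implemented
(`coeff_convention = "published" | "literal"`, default published so the
symbolic theory matches the reported constants), and
`synthpop.audit_scramble_variance` adjudicates them by Monte-Carlo: it
repeatedly generates fresh populations and scrambles, estimates `Var(Z)`,
and flags which convention's identity lies within 3 Monte-Carlo standard
errors.  For the simulated populations here the literal convention is the
one that matches at interior mixing values.

The `azeem_l` model is a sharper case: expanding `Z = Y + lS + (1−l)YS`
yields `Var(Z) = σ_y²(1 + (1−l)²σ_S²) + l²σ_S² + σ_S²[2l(1−l)μ_Y +
(1−l)²μ_Y²]`, which contains a term *linear* in `μ_Y`.  The commonly
reported identity `σ_z² = Aσ_y² + l²σ_S² + (A−1)μ_Y²` with
`A = l² + (1−l²)(1+σ_S²)` matches only at `l ∈ {0, 1}` (the difference is
`2l(1−l)σ_S²(σ_y² + μ_Y² − μ_Y)`).  The published convention evaluates the
reported identity; the literal convention carries the linear term through
the `c_lin` slot of the unscrambling tuple.  The comparison tables use
only the endpoints `l ∈ {0, 1}`, where the conventions agree.

## First-order theory

Writing each sample summary as its population value times `1 + ζ`, the
relative errors `ζ = (ζ_z, ζ_z̄, ζ_x1, ζ_x2)` have mean zero and second
moments `θ = 1/n` times a fixed table of standardized mixed central
moments `γ_rst = μ_rst/(μ₂₀₀^{r/2} μ₀₂₀^{s/2} μ₀₀₂^{t/2})` (divisor `N−1`
throughout; under SRSWR `E[s²] = ((N−1)/N)·σ²_{N−1}`, a 0.2% discrepancy
at `N = 500` absorbed into Monte-Carlo tolerances).  Every estimator is
expanded exactly to second order in `ζ` (`rrtvar._expansion`), giving

    bias = (a0 − u0) + tr(A₂ Σ),
    mse  = (a0 − u0)² + 2(a0 − u0)·tr(A₂ Σ) + a₁ᵀ Σ a₁,

about the model-unscrambled target `u0 = σ*²/scale`.  Because the free
constants of the difference and generalized classes enter linearly, the
MSE is an exact quadratic in them; the closed-form optima are evaluated
with the scalar cofactor formulas of the 3×3 normal equations (preserving
symbol-level traceability to the reported `U`/`O,m`/`Q,t` systems) and
cross-checked by a derivative-free Nelder-Mead search.

Two closed-form routes are kept deliberately separate:

* **canonical** — the expansion algebra above, used by default everywhere;
* **published** — literal transcriptions of the reported displays.

They are compared by `theory.audit_formulas`, which emits JSON-line records
`{family, population, quantity, published_value, canonical_value, rel_diff,
verdict}`.  Known divergences (all flagged, none silently corrected): the
single-auxiliary difference family's cross quantity carries a halved
`γ₁₂₀C_z` coefficient in the reported form; the three-constant generalized
class's reported variance-coefficient list is incomplete (one coefficient
garbled, one absent), so its published-mode MSE falls back to canonical
with an `incomplete_published_algebra` verdict; the proposed class's
reported `η₁`/`η₇` contain transcription oddities (an undefined starred
constant pair, read as `H*H**`; a missing 1/8); and the
mixture-model ratio estimator's reported MSE display is garbled.  A
spurious leading minus sign on one reported mean-square is dropped (a mean
square cannot be negative), and one evident exponent typo
(`σ_x1²+s_x2²` for `σ_x1²+s_x1²` in an exponential-ratio denominator) is
corrected in the estimator definition.

Independently of both routes, `theory.delta_oracle` numerically
differentiates the *implemented* estimator at the population point
(central differences, relative steps `1e-5` for the gradient and `5e-4`
for the Hessian, each Richardson-refined from step pairs `(h, h/2)`) and
assembles bias and MSE from the ζ covariance.  Canonical closed forms and
the oracle agree to better than `1e-6` relative for every family; the
finite-difference step sizes balance truncation against round-off so the
Hessian trace retains ~9 significant digits.

## Synthetic data

Populations are drawn from trivariate normal superpopulations.  The three
built-in specifications share mean `(5, 5, 5)` and `N = 500` and differ in
covariance structure: Population I (moderate auxiliary correlation,
`σ_y² = 10`), Population II (strong correlation, `σ_y² = 6`), Population
III (weak correlation, `σ_y² = 9`).  The scrambling variances default to
the fixture values `σ_S² = 0.2636628`, `σ_T² = 0.2198689` in table-style
runs (unit variances are available by flag — the study conditions state
both, so the choice is exposed rather than hidden).  Scrambling is applied
once per population by default (`z_i` are fixed unit characteristics);
per-replication re-scrambling is an option.

What the generator does **not** emulate: non-normal superpopulations,
without-replacement or stratified designs, nonresponse, or measurement
error beyond the scrambling itself.  Passing tests therefore demonstrate
the internal consistency of the theory and its Monte-Carlo behaviour under
normal populations, not robustness on real survey data.

## Simulation engine and reference points

`simulate.run_simulation` draws `R` SRSWR samples (vectorized; `R = 20000`
at `n = 100` takes well under a second), resolves `"optimal"` constants
once per population from the realized moments (the known-moments
idealization of the optimum plug-ins; a per-sample-estimated mode is out
of scope), and reports empirical bias/MSE against the realized
finite-population `σ_y²` (divisor `N−1`) — the estimand of every formula.

With a single fixed scramble the realized `σ_z²` differs from its model
value, so the theory target `u0` differs from `σ_y²` by a fixed offset of
order `1/√N`.  The theory columns are therefore re-referenced exactly:
`bias_vs_y = bias + offset`, `mse_vs_y = mse + 2·offset·bias + offset²`.
This is an identity, not an extra approximation; the model-referenced
values are kept alongside.  At `n = 100`, `R = 20000` the empirical MSE of
the usual and difference estimators agrees with the re-referenced
first-order theory within a few percent on all built-in populations.

The same offset is why the *class-ordering* comparison (proposed class
< three-constant grid < classical family, and diff2 < diff1 < usual) is
run in the re-scrambling design: estimators that trade bias for variance
optimize MSE about `u0`, and a fixed scramble shifts their empirical MSE
about `σ_y²` by `2·offset·bias`, with a sign that depends on the scramble
realization alone.  Re-scrambling each replication makes the estimand and
the optimization target coincide, and the ordering is then stable across
seeds.  Sample size is not part of the study conditions and is a visible
configuration field; the default `n = 50` gives MSE magnitudes consistent
with moderate-sample practice, with `R = 5000` (tables) and `R = 20000`
(convergence and ordering checks) replications.

## Numerical choices and degenerate inputs

* Negative unscrambled variance estimates are reported as-is (the theory
  assumes no truncation); `floor_at_zero` is available but off by default.
* Ratio-type families raise on a zero sample variance for scalar input;
  array input propagates non-finite values, which the engine records,
  excludes, and counts per estimator.
* Optimum systems raise `SingularSystemError` on singular denominators;
  degenerate populations (zero variance margin, `Z̄ = 0`) raise dedicated
  errors rather than returning NaN.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every simulation record carries its seed and a configuration
  hash.

## Known limitations

* First order only: no `θ²` corrections, so theory-vs-simulation agreement
  degrades for small `n` or heavy scrambling.
* The genratio family is not auxiliary-scale-equivariant (its additive
  difference term carries an implicit unit coefficient); this is a
  property of the family as defined, preserved deliberately.
* The two-auxiliary difference family does not reduce to the
  single-auxiliary one when `X2` is uninformative — its leading-constant
  shrinkage freedom remains; only the `X2` coefficient is forced to zero.
* Published-mode evaluation reproduces reported displays including their
  typos (flagged by the audit); it is retained for traceability, not for
  inference.
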