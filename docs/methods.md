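# Methods

This note records the statistical model, the estimators, the numerical
choices and the simulation design implemented in `lrrmeta`, and what the
synthetic test conditions do and do not establish about real data.

## Study-level model

For a two-arm study with arm sample sizes n_T, n_C, sample means X̄_T,
X̄_C (> 0 required) and SDs s_T, s_C, the effect is λ̂ = log(X̄_T/X̄_C)
with delta-method variance v̂² = s_T²/(n_T X̄_T²) + s_C²/(n_C X̄_C²) —
the sum of squared sample coefficients of variation over arm sizes. The
optional second-order correction adds ½[s_T²/(n_T X̄_T²) − s_C²/(n_C X̄_C²)]
to the point estimate and ½[s_T⁴/(n_T² X̄_T⁴) − s_C⁴/(n_C² X̄_C⁴)] to the
variance. The correction helps under lognormal data and harms under
normal data, so it is off by default and never applied implicitly.

Non-positive sample means raise a typed error (`UndefinedLRRError`)
rather than yielding NaN; the simulation engine catches it to implement
explicit truncation accounting. The √n·X̄/s ≥ 3 precision rule (a study
passes if at least one arm passes) is advisory only: `analyze` warns per
failing study but never filters, since the rule is widely ignored in
applied work and silent filtering would change the estimand.
Coefficients of variation are always computed on demand from the stored
(n, mean, sd), never cached.

Under normal arm means, P(LRR undefined) = 1 − [1 − Φ(−√n_C μ_C/σ_C)]
[1 − Φ(−√n_T μ_T/σ_T)]; this closed form is exposed directly and used as
the analytic oracle for the engine's discard bookkeeping.

## Heterogeneity estimation

**Generalized moment (DL, J).** For fixed positive weights a_i, the
generalized Q statistic Q_a = Σa_i(λ̂_i − λ̄_a)² has expectation
Σa_i(v_i² + τ²) − Σa_i²(v_i² + τ²)/Σa_i under the random-effects model.
Matching the observed Q_a gives τ̂² = max(0, (Q_a − c₁)/c₂) with
c₁ = Σa_i v̂_i² − Σa_i² v̂_i²/Σa_i, c₂ = Σa_i − Σa_i²/Σa_i. DL is the
a_i = 1/v̂_i² case, J the a_i = 1/v̂_i case; there is deliberately a
single code path so the generalization is the single source of truth.
Truncation at zero is flagged.

**Mandel–Paule.** τ̂²_MP solves F(τ²) = K − 1 where F is the Q statistic
with inverse-variance weights evaluated at τ². F is strictly decreasing,
so the root is unique; it is bracketed by doubling from 1 and found by
Brent's method to 1e−10 in τ². F(0) < K − 1 gives a truncated zero.

**REML.** The profile restricted log-likelihood
l_R(τ²) = −½[Σlog(v̂_i²+τ²) + log Σŵ_i(τ²) + Σŵ_i(τ²)(λ̂_i − λ̂(τ²))²]
(λ profiled out in closed form, avoiding 2-D optimization) is maximized
by bounded scalar search on [0, τ²_max], τ²_max = max(10, 100·S²_λ̂),
tolerance 1e−10. A solution at the upper bound raises instead of
returning silently.

## Interval estimation for τ²

**Q-profile.** Bounds solve F(τ²) = χ²_{K−1} quantiles (same monotone F
as MP). Bounds that do not exist are truncated at 0; when the observed Q
is below the α/2 quantile already at τ² = 0 the interval is reported as
[0, 0] with both truncation flags — the Q-profile convention adopted
here, since the reference analyses do not state one.

**Biggerstaff–Jackson and Jackson.** For candidate τ², Q_a is a quadratic
form in the effects, distributed as Σ μ_j χ²(1) with μ_j the eigenvalues
of S(τ²)^{1/2} M S(τ²)^{1/2}, S = diag(v̂_i²+τ²), M = diag(a) − aaᵀ/Σa_i.
P(Q_a ≤ Q_a^obs | τ²) decreases in τ²; the bounds are where it crosses
1 − α/2 and α/2. Eigenvalues are recomputed at every candidate (K is at
most a few hundred; the symmetric eigensolve is negligible), clipped at
zero when within −1e−10 of it (the form is positive semidefinite; one
null eigenvalue is structural). Root searches use bracket doubling plus
Brent to 1e−10, with an upper cap of 1e4 beyond which the bound is
reported open-ended (infinite) rather than fabricated.

**Weighted-χ² CDF.** No installed Python library provides the CDF of a
positive linear combination of independent χ²(1) variables, so it is
implemented here two ways: Ruben's mixture-of-central-χ² series with
β = μ_min (a proper mixture — non-negative weights summing to one — so
the truncation error is bounded by the unaccumulated mass; the χ² CDF
terms use a log-space downward recursion to survive underflow at large
x/β), with Imhof characteristic-function inversion via adaptive
quadrature as the fallback when extreme eigenvalue spread makes the
series slow. Coefficients below 1e−9 of the total are dropped; they
perturb the CDF by less than the target accuracy but destroy the series'
convergence rate. Accuracy is ~1e−9 against χ² closed forms and within
Monte-Carlo error of a 10⁶-draw oracle.

**Profile likelihood.** The interval is {τ²: 2[l_R(τ̂²_REML) − l_R(τ²)]
≤ χ²₁,0.95}, anchored at the REML objective (the residual rather than
full likelihood) so that the point and interval pair consistently.
Endpoints are found by outward bracketing from the REML estimate; a flat
likelihood yields an open-ended upper bound with a warning.

## Overall effect

Inverse-variance means use ŵ_i(τ̂²) = (v̂_i²+τ̂²)⁻¹ and the customary
SE (Σŵ_i)^{−1/2}; the fixed-effect estimate is the τ² = 0 case. SSW uses
w_i = ñ_i = n_iT n_iC/(n_iT+n_iC) — equivalent to setting both CVs to 1
in the variance formula — and needs arm-level sample sizes.

HKSJ intervals use the weighted residual variance
q = Σŵ_i(λ̂_i − λ̂_RE)²/[(K−1)Σŵ_i] and t(K−1) critical values, with the
variance **unmodified** (no truncation at the inverse-variance value).
This is a deliberate choice: the unmodified form is what allows HKSJ to
be *narrower* than the Wald interval on homogeneous-looking data, the
behavior seen in the reference analyses. The SSW companion interval
plugs τ̂²_MP into Var̂(λ̂_SSW) = Σñ_i²(v̂_i²+τ̂²)/(Σñ_i)² and also uses
t(K−1).

The exponentiated scale (RoM = exp λ̂ with exponentiated bounds) is pure
output formatting; no back-transformation bias adjustment is applied.

I² = 100τ²/(τ²+s²) is provided as a descriptive utility with s² the
Higgins–Thompson typical within-study variance
s² = (K−1)Σŵ_i/[(Σŵ_i)² − Σŵ_i²]; the reference work does not pin down
its s² convention, so this standard choice is documented here and I² is
kept out of any validation target. Its λ-dependence for LRR is one
reason to prefer reporting τ² directly.

## Simulation design

The engine reproduces the two-distribution factorial design: λ ∈
{0, 0.2, 0.5, 1, 2}; τ² from 0 to 1 in steps of 0.1; μ_C ∈ {1, 4} for
normal data (proximity to zero matters) and 1 for lognormal (it does
not); K ∈ {5, 10, 30, 50, 100, 125}; total n ∈ {4, 10, 20, 40, 100, 250,
640, 1000} with equal arms; σ² = 1 in both arms; 10,000 replications per
cell at full scale. Study effects are λ_i ~ N(λ, τ²), μ_iT = μ_C e^{λ_i}.

Normal path: sufficient statistics are generated directly — X̄_ij ~
N(μ_ij, 2σ²/n), s²_ij ~ σ²χ²_{n/2−1}/(n/2−1) — which is exact, not an
approximation (validated by moment matching against subject-level
generation). Studies with a non-positive sample mean are discarded and K
reduced; replications retaining fewer than 2 studies are dropped and
counted (the edge case is vanishingly rare at the design's settings, and
no estimator is defined below K = 2). Retained-K quartiles are reported
so truncation is visible. Lognormal path: n/2 subject-level draws per arm
with log-scale mean log(μ) − ½log(1+σ²/μ²) and variance log(1+σ²/μ²),
matching raw-scale mean μ and variance σ²; nothing is discarded.

Coverage is judged against the generating λ for effect intervals and the
generating τ² for heterogeneity intervals. One root seed spawns
independent substreams per cell, so cells are reproducible in isolation
and under parallel execution. Every summary (bias, MSE, coverage, width)
carries its Monte-Carlo SE, so runs at reduced replication counts remain
interpretable; the runner accepts estimator subsets because the full
interval battery (eigendecompositions inside root searches) dominates
runtime at large K.

Problem sizes used by the bundled checks: the normal τ²-bias cell runs
5,000 replications and the lognormal cell 1,000 (≈5×10⁷ subject-level
draws), the Q-profile coverage check 2,000; each reports its Monte-Carlo
SE alongside.

### What the generator does and does not emulate

It generates exactly the stylized conditions above: equal arm sizes,
equal unit variances, a shared μ_C across studies, normal random
effects. Real meta-analyses have unequal and correlated sample sizes,
unequal arm variances, non-normal random effects and selection effects;
none of these are modeled, so a method performing well here may still
fail on such features — the simulations bound optimism, they do not
confer it. The two bundled example CSVs are synthetic stand-ins generated
from this same model (seeded), shaped like two published meta-analyses;
they exercise the full pipeline but do not reproduce the published
estimates, which require the original arm-level data.

## Degenerate inputs and tie-breaks

K < 2 is rejected at construction; K = 2 is allowed (all formulas are
valid). Zero SD in one arm is allowed (with an infinite-precision
warning); zero SD in both arms is a degenerate-variance error. All-equal
effects give Q = 0, truncated τ̂² = 0 and zero-width HKSJ intervals.
Missing SD cells in CSVs are errors; nothing is imputed.
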