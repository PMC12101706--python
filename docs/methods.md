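# Methods

## The problem

Two-arm time-to-event comparisons in biomedicine are overwhelmingly analyzed
with Cox proportional-hazards regression,

λ(t | x) = λ₀(t) · exp(x β),   HR = e^β,

with x a dummy-coded arm indicator. Testing H₀: β = 0 against H₁: β ~ f(φ)
with a Bayes factor

BF₁₀ = ∫_{Ω₁} L(β) f(β) dβ / L(0)

lets evidence be quantified for either hypothesis and legitimizes optional
stopping, but requires a prior f on the log hazard ratio. `coxprior`
implements a data-driven construction of that prior from large corpora of
published hazard ratios, and the Bayes-factor engine that consumes it.

## Likelihood

The likelihood inside BF₁₀ is instantiated as the Cox *partial* likelihood
with Efron's correction for tied event times. This eliminates the baseline
hazard, so no prior on λ₀ is needed and the marginal likelihood is a
one-dimensional integral over β. For a single binary covariate each
(event-time, Efron-index) pair contributes a term
log(a₀ + a₁ e^β) with risk-set counts a₀, a₁; the implementation flattens all
terms into two coefficient arrays so that one likelihood evaluation is a
single vectorized `logaddexp`, which is what makes sequential re-computation
cheap. A dataset with no events has a constant likelihood and BF₁₀ = 1
exactly. lifelines (also Efron) is used in the test suite as an independent
cross-check of the MLE and standard error, never as the implementation.

Monotone likelihoods (e.g. all events in one arm of a tiny dataset) have no
finite MLE; `cox_mle` detects this from the sign of the score at ±30 and
raises rather than returning a boundary estimate.

## Marginal-likelihood quadrature

The numerator integral is computed with adaptive quadrature
(`scipy.integrate.quad`) after two stabilizations: the likelihood at β = 0 is
factored out, and the integrand's log-maximum m (located with bounded scalar
minimization) is subtracted before exponentiation, so arbitrarily large
samples cannot overflow. The window is μ ± 12σ of the prior (the prior
density at the edge is below e⁻⁷⁰), intersected with the half-line for
one-sided priors; if the mode presses against the window it is widened up to
three times. The quadrature must reach a relative error of 1e-8 or the call
fails with diagnostics rather than returning a doubtful number. One-sided
hypotheses use the prior truncated at 0 and renormalized (a half-Normal for
μ = 0).

Internal correctness is guarded by two oracles: the two-subject single-event
dataset, whose partial-likelihood ratio is the logistic sigmoid so any
symmetric prior gives BF₁₀ = 1 analytically; and a 10⁶-draw Monte-Carlo prior
average of the likelihood ratio, which the quadrature must match within
3 Monte-Carlo standard errors on random small datasets.

## Prior construction from literature corpora

Each mined study i contributes b_i = log HR_i and, from its reported
100(1−α)% interval,

SE(b_i) = (log HR_u − log HR_l) / (2 z*),  z* = Q(1 − α/2).

Because the sign of b_i is an artifact of arm coding, every study enters
sign-symmetrized (+b_i and −b_i), which forces the pooled mean to 0 exactly.
The prior scale is the pooled standard deviation of the merged per-study
samples under an assumed common per-study size n:

σ_p = sqrt( ((n−1) Σ SE_i² + n Σ b_i²) / (N n − 1) ).

Inverse-variance weighting is deliberately *not* used: it would shrink the
prior without bound as the corpus grows and down-weight uncertain studies,
whereas the prior is meant to reflect the spread of plausible effects
including their uncertainty. The default n = 200 is an assumption, not an
estimate — abstracts do not report per-study sizes — and the sensitivity
analysis quantifies its influence by redrawing each n_i from the discrete
uniform on [10, 10000] (sizes are counts, so the integer reading is used) and
recomputing σ_p, by default 100,000 times (tests and the acceptance script
use 1,000, which bounds the Monte-Carlo summaries well enough for the
qualitative conclusion). The estimator depends on the corpus only through
(N, Σb², ΣSE²), so a surrogate corpus with constant b = √(mean b²),
SE = √(mean SE²) reproduces any corpus's σ_p exactly from its summary table —
this is how the bundled per-subfield summaries in `reference.py` determine
the nine default priors, whose scales fall between 0.915 and 1.079.

Degenerate corpora (σ_p = 0) are rejected at prior construction; a Normal
prior needs a strictly positive scale.

## Text mining and screening

Journal names are canonicalized (ampersands → "AND", strip non-alphabetic
non-whitespace, move a trailing "The" to the front, collapse whitespace,
uppercase) before matching articles to per-subfield top-journal lists; an
article whose journal sits in several lists contributes its effect to each.

Extraction takes the *first complete* (HR, level, lower, upper) tuple in
reading order. The grammar accepts the head tokens "hazard(s) ratio(s)"
(optionally followed by a bracketed HR abbreviation), "HR" and "H.R.", "=" or
":" separators with optional spaces, "95% CI" or "CI 95%" orderings
(including "confidence interval" spelled out), and bounds separated by
hyphen/dash, "to", or comma; decimal points only. Completeness is required —
an HR followed by a p-value, or an "HR" abbreviation with no interval, never
matches, and a partial leading mention cannot veto a valid later tuple
because the pattern must match all four numbers contiguously. The grammar is
a reconstruction of the documented reporting variants, not a character-level
copy of any particular production regex.

Screened tuples must satisfy four checks, each with its own reason code:
confidence level strictly inside (0, 100); HR and both bounds strictly
positive; log HR within rounding tolerance of the midpoint of the log
bounds; and no printed collision between HR and a bound. The midpoint
tolerance is the first-order propagation of half-ULP rounding of each
printed number through the log:

tol = 0.5·10^(−d_hr)/HR + 0.25·(10^(−d_l)/HR_l + 10^(−d_u)/HR_u),

with d the recorded printed decimals — scale-aware, so coarsely printed small
ratios get proportionally more slack. Two local decisions: collision is
judged on the parsed printed values (the parse *is* the printed precision),
and an inverted interval (lower > upper) fails the midpoint check, which
keeps the post-screening invariant lower ≤ upper without inventing a fifth
reason code.

## Synthetic data

The generators define the conditions under which the pipeline is tested.

* **Abstracts** embed one ground-truth tuple rendered in a uniformly sampled
  reporting variant, rounded at 1–2 decimals (escalating to more decimals on
  the rare rounding collision, so every embedded tuple passes screening by
  construction), with decoy sentences ("heart rate (HR)", HR-with-p-value)
  mixed in. Defaults: p_complete = 0.6 — mirroring the ≈60% extraction
  success observed on real corpora — and p_decoy = 0.3; 95% intervals carry
  90% of the level mass. What this does *not* emulate: journal-specific
  abstract styles, OCR noise, non-English text, or comma decimals; a perfect
  round-trip on synthetic abstracts therefore shows grammar correctness, not
  real-world recall.
* **Effect corpora** draw b_i = s_i |z_i| τ (folded Normal with random sign:
  heavy mass near zero, occasional large effects, matching the shape of
  mined corpora; a lognormal magnitude was rejected for having no mass at 0)
  and SE_i = c/√n_i with n_i uniform on [30, 3000], linking precision to
  study size. Defaults τ = 0.933, c = 2.2 put E[b²] ≈ 0.87 and E[SE²] ≈ 0.1,
  the typical mined magnitudes.
* **Trials** are exponential proportional-hazards data: baseline rate 0.1,
  treated rate 0.1·e^β, independent exponential censoring (rate 0.02 ≈ 9–17%
  censored) and/or an administrative cutoff, with a seeded random accrual
  order. Default n = 500 per arm, β = 0.7.

## Sequential monitoring

`sequential_bf` recomputes BF₁₀ on growing accrual prefixes — every 10
subjects by default (the granularity of real interim looks is a design
choice; it is configurable) — and stops at the first interim whose BF₁₀
exits the open interval (lower, upper), default (1/20, 20). Thresholds are
configurable because the certainty/efficiency trade-off is study-specific.
A prefix with no events has BF₁₀ = 1 and never stops. `sensitivity_grid`
runs the same monitor across a grid of prior scales (e.g. σ ∈ {0.3, …, 1.7})
with one shared accrual order so trajectories differ only in the prior.

Under these defaults (β = 0.7, n = 1,000, positive-sided N(0,1) prior) all
100 seeded replicates in the acceptance suite stop above 20 well before
sample exhaustion (median ≈ 70 subjects), and under β = 0 the median
full-sample BF₁₀ is ≈ 0.07 — evidence correctly accumulating toward the null.

## Numerical and design notes

* Natural logarithms throughout; z* from `scipy.stats.norm.ppf`.
* σ_p's N-form denominator (N n − 1) is used literally; the 2N-symmetrized
  variant agrees to 3 decimals at realistic corpus sizes.
* Retention diagnostics S1 = matched/allocated, S2 = considered/matched drop
  rows with a zero denominator rather than propagating divisions by zero.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and Monte-Carlo routine is reproducible bit-for-bit given its
  seed.
* Pipeline artifacts embed a config hash (analysis inputs and parameters,
  excluding the output directory) and the seed, so re-runs are byte-identical.

## Known limitations

* Single binary predictor only: no covariate adjustment, stratification, or
  interval nulls; the scalar parameter is why quadrature suffices and MCMC is
  avoided.
* The priors summarize entire subfields; they are starting points, not
  substitutes for problem-specific elicitation.
* The mining grammar targets the documented reporting variants; abstracts
  using other conventions (comma decimals, "CI" omitted) are not captured,
  and an "HR" abbreviation followed by a syntactically complete interval is
  taken at face value even if it abbreviates something else.
* The exponential trial generator satisfies proportional hazards by
  construction; it cannot probe robustness to non-proportionality.
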