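# Methods

## Model

Each arm's outcome is a Bernoulli attendance indicator; with a
Beta(α₀, β₀) prior on the attendance probability the posterior after
observing *s* attendances in *n* outcomes is Beta(α₀ + s, β₀ + n − s).
Updating is exact conjugate arithmetic throughout — sampling plays no role
in the posterior itself, only in the *comparison* functionals evaluated at
each interim analysis:

- p_best(k) = P(θ_k > θ_j for all j ≠ k | data)
- p_equiv  = P(max_k θ_k − min_k θ_k < δ | data)

The default prior Beta(100, 100) encodes 200 pseudo-observations at 50%
attendance. It is regularising rather than informative: at the first interim
(100 outcomes) the data carry a third of the posterior weight, so a lucky
early run cannot trigger a stop by itself; by a few thousand outcomes the
prior is immaterial.

## Comparison computation

Two routes compute the same functionals:

- **Monte Carlo** (any number of arms): joint independent draws from each
  posterior; p_best(k) is the fraction of draws in which arm *k* is strictly
  largest (exact ties — measure-zero for continuous posteriors — are broken
  uniformly at random so the probabilities sum to exactly 1), p_equiv the
  fraction in which the sampled range is below δ. Default 100 000 draws,
  giving standard error ≈ 0.0016 at p = 0.5 — negligible against the 0.95
  thresholds. Every comparison records its seed; seeds advance
  deterministically per interim from the trial's master seed.
- **Deterministic quadrature** (two arms): P(X > Y) = ∫ f_Y(y) (1 − F_X(y)) dy
  and P(|X − Y| < δ) = ∫ f_Y(y) (F_X(y+δ) − F_X(y−δ)) dy, evaluated with the
  regularised incomplete beta function on a 401-point uniform grid spanning
  mean ± 12 sd of both posteriors. Agreement with a 2001-point reference is
  ~10⁻⁶ even for posteriors concentrated on a sliver of (0, 1), far below
  Monte-Carlo resolution. The test suite cross-checks both routes against an
  independent brute-force 2-D quadrature oracle.

Trial runs resolve `comparison_method="auto"` to the quadrature for two-arm
trials and Monte Carlo otherwise. The operating-characteristics module uses
the quadrature, which removes comparison noise and is ~100× faster.

## Stopping rules

Checked in fixed priority order — superiority, practical equivalence,
ceiling — with strict inequalities for the probabilistic rules (> x, > y)
and an inclusive ceiling. Priority matters only when several rules are
satisfied at the same interim; superiority wins because it is the actionable
finding, and a ceiling stop is reported as indeterminate (no winner, but
posterior summaries are still emitted). The platform-closure rule (every
group at or above 80% attendance) is inclusive at the boundary.

`superiority_scope` selects which arms can end a trial by rule 1:

- `"any"` (default for single trials) — the symmetric reading: any arm,
  control included, can be declared best.
- `"non_control"` (default in the operating-characteristics study) — only an
  intervention arm can be declared best; evidence favouring standard care
  leaves the trial running until equivalence (or a ceiling). This one-sided
  form is the design whose simulated error rates and power the package
  reproduces: under the null it declares a false winner in roughly a third
  of trials, and at a 1-point effect it finds the intervention in roughly
  nine trials in ten, with the remainder stopping for equivalence. The
  symmetric form stops null trials about twice as often (either arm may
  cross) and loses several points of power at small effects to wrong-sign
  crossings.

No arm-dropping is implemented: whole trials stop, arms do not leave
mid-trial, because the protocol defines no dropping mechanism.

## Allocation

Permuted blocks: each block's size is drawn uniformly from the permitted set
(defaults: multiples of the ratio total within 4–12), filled with arms in
the ratio proportions and uniformly permuted. Within every completed block
the ratio is exact, so the imbalance at any cut point is bounded by one
incomplete block (≤ 11 for 1:1 with blocks up to 12). Stratification, off by
default, gives each stratum an independent block sequence whose seed derives
deterministically from the master seed and the stratum label, so a stratum's
assignments are invariant to how arrivals interleave.

## Synthetic referral stream

`PopulationSpec` models the referred population only (the upstream screening
cascade is out of scope): a fixed number of referrals per interim window
(default 100 per 72 h, the programme's observed rate), subgroup labels drawn
i.i.d. from stated prevalences, and attendance probability = subgroup
baseline + additive arm effect (absolute percentage points, optionally
subgroup-specific, clipped to [0, 1]). Additive-on-probability effects match
how the design's effect sizes are specified; odds-scale effects are not
modelled.

Outcomes are observed immediately at the end of each window, collapsing the
real-world 1–2 week appointment lag; interims are triggered by outcome count
rather than wall-clock time, which coincides with the 72-hour cadence at the
stated referral rate. Randomness lives on named counter-based (Philox)
streams keyed by the population seed, and the latent outcome uniform of the
*i*-th referred participant depends only on (seed, *i*): replaying one
stream under different designs reuses identical draws (common random
numbers), which sharpens design comparisons.

What the generator does **not** emulate: calendar-time arrival fluctuation
and slow-referral window extensions, outcome delay, correlation within
households or sites, non-attendance that converts to late attendance, and
drift in baseline rates over a trial. Passing operating-characteristic tests
therefore demonstrate the *statistical* behaviour of the stopping rules
under the stated generative model, not robustness to those real-data
features.

## Operating characteristics

A scenario runs `n_sims` independent two-arm trials (control rate 0.50,
effect *d*, defaults as above, no ceiling) on seed streams `base_seed + i`
and reports: power (fraction stopping by superiority with the intervention
declared best; meaningful for d > 0), false-positive rate (fraction stopping
by superiority at d = 0, where any declared winner is false), expected total
enrolment, mean interim count, winner-estimate bias, and binomial Monte-Carlo
standard errors. Null trials terminate via equivalence as the posteriors
concentrate (at ~30–45 k enrolments with the default margin); a guard at 10⁶
outcomes flags pathological configurations instead of looping. Grid rows are
cached to disk keyed by a scenario content hash, so re-running an identical
grid is free. A threshold sweep varies x at fixed *d* to display the
error/sample-size trade-off.

Problem sizes used by the shipped acceptance checks: 1000 replicates at
d = 0.03, 200 at d = 0.01 and 300 at d = 0 (the latter two scaled down
because those trials run to ~10⁴–4×10⁴ outcomes each), with bounds widened
by two binomial standard errors at the replicate count used.

## Winner-estimate bias

Stopping at the first crossing of a posterior threshold selects favourable
fluctuations, so the declared winner's posterior mean overestimates its true
rate when effects are small; each simulated trial therefore carries its
generative rates, and scenarios report mean(winner posterior mean − true
winner rate). The bias is positive at d = 0.01 and negligible at d ≥ 0.03,
where trials stop on signal rather than noise.

## Equity analysis

Disaggregation is direct: per-group referral and attendance counts within
one declared domain (e.g. sex, or a composite label), with population
fractions defaulting to observed referral shares and overridable by external
(census/baseline-survey) shares. The left-behind set accumulates groups in
ascending attendance order until their population fractions reach the 10%
floor; attendance ties favour the larger group (reaching the floor with
fewer groups), then label order, making the selection invariant to row
order. The primary outcome is attendance within the left-behind set, the
secondary outcome overall attendance, and the gap is reported in absolute
percentage points. The same operations serve baseline identification and
within-trial evaluation. No regression adjustment or inequality-slope
indices are computed.

## Numerical and degenerate-input choices

- Probabilistic thresholds live in [0.5, 1); margins must be positive;
  prevalences must sum to 1 within 10⁻⁹.
- The equivalence margin "1%" is 1 absolute percentage point (0.01 on the
  probability scale).
- Replay of a recorded participant table applies the identical interim loop
  to recorded outcomes in row order; if the records end before any rule
  fires, the result is returned unstopped rather than inventing a decision.
- Configuration validation is all-at-once: every defect is reported with its
  field path in a single error.
- All randomness flows from explicit seeds; no code path reads ambient
  entropy.

## Known limitations

- The immediate-outcome assumption makes "enrolled = outcomes observed" at
  every interim; with a real appointment lag, interim posteriors would trail
  enrolment and stops would come later in calendar time.
- Cluster-randomised designs, response-adaptive allocation, covariate
  adjustment and non-conjugate or hierarchical priors are out of scope.
- Operating characteristics are exact only for the two-arm case the study
  design specifies; multi-arm scenarios run through the same engine but
  their error rates have no printed reference values.
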