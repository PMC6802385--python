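# Methods

`divehmm` implements a complete analysis chain for inferring behavioral
states from biologging records of diving animals, built around the study
design used for Southern Resident killer whales (SRKW): suction-cup tag
deployments recording depth, triaxial acceleration, heading and roll at
50 Hz together with echolocation click events assigned to the tagged
animal.

## Units of analysis: dive segmentation

Pressure-derived depth is block-averaged down to 5 Hz. A dive is a maximal
excursion of the depth trace beyond 0.5 m that reaches at least 1 m; start
and end are placed at the 0.5 m crossings by linear interpolation between
adjacent samples, giving sub-sample duration accuracy at 5 Hz. The same
0.5 m threshold defines the return to the surface (only the departure
threshold is conventionally quoted; using one threshold for both keeps
dives and surface intervals tiling the record). Duration is measured
threshold-to-threshold. The bottom phase is the interval from the first to
the last sample at ≥ 70% of the dive's maximum depth; at least the
maximum-depth sample always qualifies. Dives beginning within the first
300 s of tag attachment are excluded (strictly: a dive starting exactly at
300 s is retained) to guard against short-term tagging responses. Manual
review of detections is supported as an overrides table of start/end edits
applied after detection. All thresholds live in the versioned YAML config
with these values as defaults.

## Per-dive response variables

Six variables per dive, four continuous and two binary:

- **Maximum depth** (m), over the whole dive.
- **Jerk peak**: `fs · ‖a(t+Δ) − a(t)‖₂` maximized over the bottom phase.
  The differentiator is the first difference of the triaxial acceleration;
  no additional filtering is applied (the estimator is otherwise
  unconstrained by convention, and only relative state separation matters
  after the log transform). Units follow the input acceleration units.
- **Roll**: median absolute roll (degrees); even-length medians average
  the middle pair.
- **Heading variance**: circular variance, 1 minus the mean resultant
  length of the heading unit vectors, in [0, 1].
- **Buzz presence** and **slow-click presence**: click events are
  partitioned into bouts at gaps > 2 s (a configurable choice — intervals
  across multi-second silences are not echolocation inter-click
  intervals). Within a bout, any inter-click interval ≤ 10 ms flags a
  buzz; any interval > 100 ms flags slow clicking; intervals between the
  two thresholds (regular fast clicking) set neither flag. Burst-pulse
  exclusion and assignment of clicks to the tagged animal are input-table
  responsibilities (an `assigned` column), not audio processing.

All variables except jerk peak are computed over the whole dive.
Continuous features are floored at 1e-6 before the natural-log transform
so every log is finite.

## The covariate hidden Markov model

Each deployment is an independent first-order Markov chain over N ∈ {3, 4, 5}
latent states sharing one parameter set. Conditional on the state, the six
channels are independent: the four continuous variables are Gaussian on
the ln scale with mean `α_jv + β_jv·sex` and per-state-channel standard
deviation σ_jv; the two binary variables are Bernoulli with logit
`α_jb + β_jb·sex`. Sex is encoded F = 0, M = 1; age class juvenile = 0,
adult = 1; year as treatment dummies against the earliest year.
Transition rows follow a baseline-category multinomial logit with
destination state 1 as baseline (the choice of baseline does not affect
probabilities) and at most one deployment-level covariate (none, sex, age
class, or year); all transitions are possible (no structural zeros). The
free-parameter count is

    k = 16N + N(N−1)(1+p) + (N−1)

with p transition-covariate columns — 12 emission parameters plus 4
binary-channel parameters per state, the transition logits, and the
initial distribution. This structure (one σ per state-channel, sex on
every response mean) is the one whose counts reproduce the published
AIC-difference arithmetic exactly; the triple of cross-checks in the test
suite is sensitive to any single-parameter miscount.

**Fitting.** EM with the scaled forward-backward recursion as the E-step.
Because the response covariate is a single binary indicator and transition
covariates have at most three levels, every M-step regression is
saturated, so the weighted least-squares / logistic / multinomial-logit
updates have exact closed forms (weighted group means and proportions,
inverted to coefficients); EM monotonicity then holds exactly, and the
test suite asserts it on every fixture. Convergence is an absolute
log-likelihood change below 1e-6 with an iteration cap of 2000. Each model
is restarted from random initializations (default 200; the restart count
and the iteration cap are separate configurable knobs, reflecting two
plausible readings of "maximum starting values" in common usage);
restart r derives its seed deterministically from the master seed, so
restarts are order-independent and parallelizable by contract. Each
restart initializes responsibilities from a randomized nearest-center
split of the standardized ln-continuous channels plus Dirichlet noise. A
restart in which any state's total responsibility falls below 1e-3 is
discarded as degenerate; the best surviving restart by AIC is retained.
Bernoulli rates are clamped to [1e-6, 1−1e-6] and transition/initial
probabilities floored at 1e-10 (numerical guards only; the clamps are
inactive on well-scaled data).

**Decoding and labeling.** Viterbi runs in log space with ties broken
toward the lower state index. Fitted states are relabeled canonically:
the deepest state (posterior-weighted mean ln maximum depth) first, the
remaining states by descending slow-click rate then ascending depth. The
relabeling is idempotent, invariant to the permutation the optimizer
happened to find, and leaves the likelihood unchanged.

**Selection.** The 12-cell grid (3–5 states × 4 covariate choices) is
compared by AIC with per-cell seeds derived from the master seed; ties
break toward fewer states, then fewer covariate columns. All cells share
one feature table and encoding.

## Downstream analyses

- **Transition report**: the fitted matrix evaluated at each sex.
- **Allocation table**: dive counts and summed seconds per (sex, state);
  percentages are of each sex's total sampled time.
- **Chi-square**: Pearson test of independence applied to the
  cumulative-seconds table exactly as counts, no continuity correction —
  the convention that reproduces the published statistic. Recomputing the
  statistic from the published whole-second table gives 7883.47 against
  the printed 7883.1; the gap is consistent with the table's rounding to
  whole seconds, and the test tolerance (±0.5) reflects exactly that.
- **Duration model**: ln(duration) ~ state + sex + (1 | deployment) via
  statsmodels MixedLM; Wald F tests per fixed-effect term (denominator
  degrees of freedom approximated by n − p − n_deployments); Tukey
  (studentized-range) adjusted pairwise comparisons of the additive
  state × sex cell means, summarized as a compact letter display with
  letters assigned in ascending-mean order. A singular random-effect fit
  falls back to OLS with a warning.
- **Hierarchical multinomial allocation model**: decoded state (reference
  state 1) on sex with per-deployment random intercepts per non-reference
  category, priors N(0, 5) on coefficients, half-Normal(1) on random-effect
  scales, non-centered parameterization. The posterior is sampled by a
  Hamiltonian Monte Carlo sampler implemented in this package:
  dual-averaging step-size adaptation to 0.8 acceptance, a diagonal mass
  matrix estimated from the middle half of warmup, and a jittered number
  of leapfrog steps (8–24). Defaults follow the study protocol: 4 chains,
  2000 warmup, 1000 retained draws. Split-R̂ is computed directly from the
  definition (half-chains; cross-checked against arviz in tests) and any
  max R̂ > 1.05 is flagged, never silently accepted. PSIS-LOO (arviz) on
  the per-dive pointwise log-likelihoods supports the comparison of the
  base model against variants with ln(deployment duration) as a linear
  effect or offset; "no strong support" is operationalized as a LOOIC
  difference within two standard errors of the paired pointwise
  differences.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
with truth labels, at two levels.

**Dive level.** A Markov chain per deployment from sex-matched transition
matrices; continuous variables drawn log-normal per state × sex, binary
variables Bernoulli. The reference parameterization encodes the published
per-sex state summaries: log-normal parameters come from the
quartile-matching map `mu = ln(median)`, `sigma = ln(q3/q1)/(2z)` with z
the standard-normal upper quartile — chosen because all four variables
are positive, right-skewed, and ln-transformed in the HMM. A
two-parameter log-normal matches the median and the quartile ratio; where
a published summary is asymmetric on the log scale (a few
heading-variance cells whose medians print at the table's resolution
limit) the implied quartiles deviate from the printed ones by exactly
that asymmetry, and the tests distinguish the two comparisons. Heading
variance draws are clipped just below 1 (the log-normal has unbounded
support; clipping above the third quartile leaves all matched quartiles
untouched). Probabilities printed as 0 or <0.01 are encoded 0.002 and
0.005, and a printed 1 as 0.995, since the fitted logit parameterization
requires interior probabilities. The default design mirrors the study:
13 deployments (7 F, 6 M, three field seasons), 180–400 dives each
(~3700 total). The per-sex transition matrices encode every directional
statement in the published analysis (persistence dominant in states 2, 4
and 5 with state 5 most persistent; no female state-1 persistence and
rare male persistence; state-3 persistence modal for males only; rare
switches into states 1 and 5; males switching into state 4 more readily),
with exact values chosen once here since the published values are
graphical. Per-state dive-duration log-normals (state 1 by far the
longest at ~4 min median, state 2 the shortest at ~18 s) are likewise
package defaults on physiological grounds.

**Signal level.** Each deployment is rendered as 50 Hz streams: dives are
trapezoids with descent/ascent at 2 m/s (configurable) and the drawn
maximum depth held with a ±1% wobble for the drawn duration; surface
intervals are exponential with mean 20 s and a 2 s floor (unreported by
any source; configurable stand-ins). A jerk transient of the dive's
target amplitude is injected at a random bottom-phase sample over a
0.004 g noise floor; roll is the target magnitude with random sign;
heading is wrapped-Gaussian with dispersion `sqrt(−2 ln(1−V))` matched to
the target circular variance and negligible autocorrelation (a
mean-reverting walk with persistence 0 — short dives then estimate V
without the upward bias that correlated headings would add). Slow-click
trains (inter-click intervals 150–400 ms) and buzz bursts (5 ms) are
placed in separate bouts more than 3 s apart. Maximum depths are floored
at 1.05 m in the signal path so every constructed dive is detectable.
Round-trip tests segment and re-extract these signals: dive recovery is
complete and per-state feature medians land within a few percent of
their targets (the tolerance asserted is 15%).

The generator does **not** emulate: sensor drift or depth noise (the
segmentation noise-invariance test injects its own), tag-orientation
artifacts, acoustic waveforms (click events are timestamps), prey-field
or tidal structure, within-dive behavioral phases beyond the trapezoid,
or dive-shape diversity. Passing round-trip tests therefore demonstrates
correctness of the pipeline's computations under the model's own
assumptions, not robustness to real-sensor pathologies.

## Problem sizes and numerical choices

Test fixtures use 3-state well-separated designs (~3000 dives) for
EM-recovery oracles, 20 replicates at n = 5000 for the transition-bias
invariant, and the full 13-deployment reference design for the
state-count selection check, which runs the 12-model grid at 3 restarts
per cell with tolerance 1e-4 and an iteration cap of 300 — the selection
margin between state counts (hundreds of AIC units) dwarfs restart
variability, so the reduced grid is a faithful scaled-down protocol. The
allocation-model convergence check runs at the full 4 × (2000 + 1000)
protocol on ~3000 synthetic dives. Brute-force path enumeration backs the
forward and Viterbi recursions on 200 random fixtures (N ≤ 3, T ≤ 6,
tolerance 1e-8); transition rows normalize to 1 within 1e-12.

## Known limitations

- The duration mixed model's denominator degrees of freedom are a simple
  approximation, not Satterthwaite/Kenward-Roger; p-values on small
  designs are approximate.
- The HMC sampler is a fixed-length leapfrog sampler with dual averaging,
  not NUTS; heavily imbalanced allocation tables may need longer warmup.
- Emission variances are state-specific but not covariate-dependent, and
  the initial distribution carries no covariates, matching the selected
  model structure.
- Canonical state labels are a deterministic convention (deepest first,
  then by slow-click rate); they coincide with ecological naming only as
  far as the fitted states separate.
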