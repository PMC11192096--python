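# Methods

## Discrete hazard model

Trial time is discrete at 1-second resolution, 0-based: timepoint `t`
means "during second `t`". A threat schedule is a proper probability
mass function `P(t)` of shock time over trial seconds (every trial ends
in a shock; normalization enforced to 1e-9 absolute). From it we derive

* survival `S(t) = Σ_{s≥t} P(s)` — the probability the shock has not yet
  occurred entering second `t` (computed as a tail sum, which makes the
  hazard at the last support point exactly 1 in floating point);
* hazard `h(t) = P(t)/S(t)`, clipped to [0, 1] against rounding;
* cumulative hazard `H(t) = Σ_{s≤t} h(s)`.

The profile is truncated at the last support point: beyond it survival
is zero and the hazard is left undefined rather than set to 0, avoiding
a 0/0 convention. Two display conventions coexist: full precision
everywhere internally, and a two-decimal "printed" rounding helper so
that the uniform-4 worked example reads `.25, .33, .5, 1` with
cumulative `2.08` (the full-precision value is 25/12 = 2.0833…; the
difference is rounding of the addends before summation).

Identities used as test oracles: `P(t) = S(t)·h(t)` exactly; `H = 1`
iff the schedule is a point mass, `H > 1` for any spread schedule; and
empirical conditional shock frequencies from Monte-Carlo draws match
`h(t)` within sampling error.

## Matched-pair design

`design_matched_pair` realizes the probability-matched,
hazard-dissociated condition pair on a 30-s trial with matched window
seconds 6–25 (chosen to span the four analyzed epochs 6–10 … 21–25 s).
Both conditions share `window_mass` of probability inside the window
with an identical shape; the early condition spends `early_pre_mass`
uniformly on seconds 0–5, the late condition places its off-window mass
uniformly on seconds 26–29. Strict hazard dominance of early over late
at every matched second follows algebraically from any positive
pre-window mass and is property-tested over randomized designs.

The window shape is uniform with an optional shared linear tilt.  The
tilt exists because a purely uniform family cannot simultaneously put
the early mean shock time near 9.5 s and the late mean near 19 s; with
defaults `window_mass = 0.62`, `early_pre_mass = 0.38`,
`window_tilt = −0.05142` the expected shock times are 9.50 s and
19.00 s. These are config values, not claims about any particular human
study's exact schedules.

Whole-trial cumulative-hazard dominance of the early condition holds at
the default design (4.61 vs 3.03) and is verified there, but it is *not*
a theorem of the constructor family: a short matched window followed by
a long post-window region can give the late schedule a larger
conditional tail cumulative hazard. `verify_pair` therefore reports
`matched_ok`, `dominance_ok` (window hazard) and `cumulative_ok`
separately.

## Synthetic cohort

The generator emulates the study design: N = 42 participants, 50
unavoidable learning shocks per condition in pseudo-randomized order, 25
testing trials per condition (interleaved), an in-trial rating on every
5th testing trial of each condition, one final unavoidable trial per
condition with a post-trial rating, and a forced choice.

**Learning.** Agents estimate each condition's schedule as a count
histogram of experienced shock times plus 0.5 pseudo-counts per bin
(additive smoothing); nothing else about the true schedule is available
to them.

**Escape policy.** Per second, escape probability
`logistic(α + β·signal(t))`, with the signal read off the *learned*
schedule as its hazard (hazard tracker) or its pmf (probability
tracker). The logistic form is the minimal monotone stochastic choice
rule; `β` is the recoverable sensitivity parameter. Within a second the
escape decision is evaluated before the shock resolves — escape is
anticipatory — so a flat policy with per-second probability `p` on a
certain `T`-second countdown escapes with probability `1 − (1−p)^T`
(used as a closed-form test oracle). If neither event occurs by the last
second (impossible under a proper true schedule, a numerical backstop
otherwise) the trial records a shock at the final second. Testing
earnings are 1¢ per second survived, i.e. `event_time_s` cents.

**Ratings.** `clip(gain·signal + ε, 0, 10)` with Gaussian ε; in-trial
ratings are prompted at a uniformly drawn second of the rated trial (the
prompt second is recorded, since the analysis regresses on the hazard at
that second); the final-trial rating reads out the mean tracked signal
over the seconds lived in that trial.

**Forced choice.** The condition with the higher mean experienced
tracked signal (signal summed over all seconds lived across learning
and testing trials, divided by seconds lived), plus judgment noise. The
end-of-study judgment aggregates over every trial experienced, so its
noise is one rating's noise divided by √(trials per condition). Note
that for *any* proper schedule the expected summed hazard experienced
per unavoidable trial is exactly 1 (since `Σ S·h = Σ P = 1`), so the
mean per-second experienced hazard is ≈ 1/E[shock time] — about twice as
high in the early condition, which is what the choice picks up.

**Population defaults** (one draw per agent): α ~ N(−5.8, 0.3), β ~
N(22, 1.5) truncated at 0, gain ~ N(10, 1.5) truncated at 0, rating
noise SD 1.0, smoothing 0.5. These were set so that the cohort expresses
the paradigm's intended behavior at magnitudes comparable to published
human countdown studies — escape reserved for genuinely threatening
seconds (per-second escape probability ~0.3% at hazard 0.1, ~50% at
hazard 0.26), epoch t-statistics in the 2–8 range, roughly 90% of
participants choosing the early condition, and strong but not degenerate
rating–hazard slopes. One master seed fixes the entire cohort
byte-for-byte.

**What the generator does not emulate.** Real participants drift,
habituate, and generalize across conditions; ratings are collected on
ordinal scales with anchors; shock intensity is individually calibrated;
condition order effects and session breaks exist. Passing tests
therefore show that the *pipeline* recovers the behavior its generative
model encodes, not that human data would yield the same numbers. The
published human-data statistics (e.g. a log-rank χ² of 259.30 or a
17.8% earnings loss) are properties of the real cohort and are out of
scope; in this generator the earnings gap (~50%) also reflects the
schedules' timing difference itself, not avoidance alone.

## Analysis battery

Escape behavior is a survival problem: the event is the escape decision,
and a delivered shock censors the escape time at the shock's second.

* **Kaplan–Meier** product-limit curves per condition (events before
  censorings at ties); with no censoring the curve equals the empirical
  survival function exactly (tested).
* **Log-rank** (df = 1) over pooled escape times with hypergeometric
  variance; exactly 0 for identical groups, symmetric in labels;
  cross-checked against lifelines.
* **Epoch avoidance**: for each epoch (6–10, 11–15, 16–20, 21–25 s), the
  per-participant fraction of trials entering the epoch that end in an
  escape inside it, compared across conditions with an
  independent-samples t-test (the test matching the design's published
  treatment, although a paired test was available). Degenerate identical
  groups return t = 0, p = 1.
* **Earnings**: per-participant mean testing earnings per condition,
  paired t; percent difference is `100·(late − early)/late`.
* **Rating association**: two-stage summary statistics — per-subject OLS
  of rating on the *true* schedule's hazard (or pmf) at the rated
  second, plus shocks received so far in that condition (optionally an
  early-condition indicator), then a one-sample t of subject slopes.
  Chosen over a mixed model to keep every step explicit and
  library-free; for balanced designs the two are asymptotically
  comparable. Subjects with < 3 rated trials are dropped with a warning.
* **Forced choice**: exact two-sided binomial against 0.5, convention
  `min(1, 2·smaller tail)`.
* **Final-trial ratings**: Wilcoxon rank-sum with midranks; exact
  permutation p when total n ≤ 12, tie-corrected normal approximation
  otherwise; repeated on ratings residualized (pooled OLS) for the
  cumulative number of shocks received in that condition.

## Calibration and dissociation checks

**Type-I error.** The acceptance suite simulates 1,000 null studies and
checks every test's rejection rate at α = .05 against the 99% binomial
band. The null must make the two conditions exchangeable: a
condition-blind policy (β = 0) alone is not enough, because with
different schedules the shock-censoring differs by condition — earnings
then differ structurally, and within-epoch escape is differentially
preempted by shocks. Calibration studies therefore use an
identical-schedule pair (all mass in a shared window) with β = 0, gain =
0, and *homogeneous* agents: between-subject variability in the escape
intercept correlates a participant's early and late proportions, which
the independent-samples epoch test (per the published treatment) treats
as independent, making it conservative — a limitation of that test, not
a bug in it. Null cohorts use 20 participants × 20 testing trials per
condition, sizes at which the asymptotic approximations the tests rely
on are in their working range while 1,000 replicates stay fast. The
exact binomial's achievable size at n = 20 (.041) happens to lie inside
the band; being an exact test it can only be conservative.

**Dissociation.** 100 default hazard-tracker cohorts must show the full
qualitative pattern (log-rank p < .005; higher early escape proportions
in all four matched epochs; lower early earnings; positive, significant
hazard-rating slope; early-majority forced choice) in ≥ 95 replicates.
Probability-tracker cohorts are checked for the *absence* of the
positive pattern: the rate of significantly-greater-early epoch tests
stays at chance. (Two-sided epoch rejections are not the right null
check there: the early condition's higher within-window shock hazard
differentially censors escapes, a structural, direction-reversed
artifact of the escape-given-entry statistic.)

## Numerical choices and degenerate inputs

pmf normalization tolerance 1e-9 absolute; negative mass, improper
sums, unsorted timepoints and length mismatches each raise a distinct
error. Hazard division uses tail-sum survival, so `h = 1` at the last
support point exactly. Rank-sum ties get midranks; two-sided exact p is
`P(|U − μ| ≥ |u − μ|)` with a 1e-12 slack for float ranks. Zero-variance
inputs short-circuit to t = 0, p = 1 rather than NaN. Schedule JSON/CSV
IO round-trips at full float precision (`repr`).

## Known limitations

* The two-stage rating model is not a mixed model; with strongly
  unbalanced rated-trial counts its weighting differs.
* The epoch statistic conditions on epoch entry, so it inherits the
  censoring asymmetry discussed above; interpret probability-tracker
  epoch effects only through the directional check.
* The agent has no memory dynamics within the testing phase (estimates
  are frozen after learning), and no time-discounting in the escape
  policy.
* Normal-approximation rank-sum p-values are used above total n = 12;
  at moderate sizes with heavy ties they are approximate.
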