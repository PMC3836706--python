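# Methods

`dreadchoice` implements a family of value models for intertemporal choice
over painful outcomes, together with the simulation, estimation, comparison
and classification machinery needed to study them end to end.  This note
documents the models, the synthetic study designs, the numerical choices,
and what the shipped tests do and do not establish.

## The value model family

A prospective option is a pain magnitude `x` (expected shocks per 5-s train,
or % of worst imaginable dental pain) delivered at integer delay `T`.  Its
total aversive value is

    V(x, T) = -( gamma_P^T * u(x) + D(x, T) )

with `u` the disutility of the pain itself, `gamma_P` in [0, 1] an
exponential discount factor on pain, and `D` the accumulated dread over the
waiting period.  Instantaneous dread at prospective moment `t` (0 ≤ t < T)
is modelled as the discounted expectation of the pain, `gamma_P^(T-t) u(x)`,
itself discounted back to the present by `gamma_D^t` and weighted by
`alpha` in [0, 1]:

    D(x, T) = alpha * u(x) * sum_{t=0}^{T-1} gamma_D^t * gamma_P^(T-t).

Special cases give the nested family: `null` (no delay sensitivity),
`exp_discount` (D = 0), `fixed_delay_cost` (D = 0 plus a constant cost A on
the later option), `constant_dread` (D = alpha·T·u(x)), `undiscounted_dread`
(gamma_D = 1; dread saturates, so aversion grows with delay at a decreasing
rate), `restricted_dread` (gamma_D = gamma_P, giving the closed form
D = alpha·T·gamma_P^T·u(x); aversion peaks at an intermediate delay near
-1/ln(gamma_P) - 1/alpha) and the 4-parameter `general_dread`.  All closed
forms are verified in the test suite against explicit term-by-term sums to
1e-9 or better, and the qualitative shapes (saturation; interior maximum
within one unit of the continuous stationary point) are property-tested by
brute-force scans.

The fixed delay cost A is attached, by default, to the strictly later
option of each pair ("relative" convention).  A per-option constant would
cancel from the binary-choice likelihood whenever both options are delayed,
as they always are in the shock task, leaving the parameter unidentifiable;
the relative convention is identifiable and produces the intended
step-shaped preference.  An "absolute" convention (A applied iff T > 0) is
available and is the natural choice for the dental task, where the sooner
option is always today.

Utility is linear in magnitude by default.  A concave alternative is
estimated from visual-analogue ratings by least-squares fitting of a
three-parameter Weibull, `u(x) = r_max (1 - exp(-(x/scale)^shape))`,
multistarted from a coarse grid; constant ratings yield a degenerate flat
fit with a warning.

Choices follow a softmax (logistic) rule in the value difference with
inverse temperature `beta`: p(i over j) = 1/(1 + exp(-beta (v_i - v_j))).
Only value differences matter, so dread pending from earlier interleaved
choices cancels; and the likelihood is invariant to rescaling beta by c and
all values by 1/c, so beta is interpretable only relative to the utility
scale.

## Synthetic study designs

**Shock task (Experiment-1 shape).**  95 choice pairs per run; magnitudes
3-12 expected shocks; delays 4-51 trials; pain and relief frames are
presentation-level relabelings of objectively identical outcomes (extra
shocks above a 2-shock baseline vs shocks relieved from a 14-shock
maximum), so models always consume the objective magnitude.  Magnitude
ordering is counterbalanced by construction: pairs are generated as
mirrored twins sharing the same two delays with swapped magnitudes, plus a
single equal-magnitude tie pair when the count is odd.  Mirroring makes two
design constants exact rather than approximate: a delay-blind
(magnitude-monotone) decision-maker chooses the later option with expected
probability exactly 0.5 over the whole set, and any model in the family
does so on the zero-delay-difference subset.  Delay differences populate
zero / short (1-10) / medium (11-20) / long (>20) bins; 13 zero-difference
trials are included by default.

The sooner option's delay is drawn from the near end of the range
([4, 12] by default; `sooner_delay_max=None` restores unrestricted
sampling).  This matters: with sooner delays uniform over the whole window,
most pairs straddle or sit beyond the restricted-dread aversiveness peak
and no parameterization of any model in the family produces the
down-then-up binned choice curve that defines reversing time preference —
the generator could then not express one of the four phenotypes the
pipeline is meant to recover.  Near-term sooner options are also the
natural reading of "sooner" in an intertemporal design.

Schedules interleave the 95 choice trials with no-choice trials in a
200-trial run (a choice at trial t with delays d1, d2 books outcome trials
t+d1 and t+d2; unreferenced trials deliver the baseline episode).  All
booked outcome slots must be pairwise distinct and inside the run — at 95%
slot load pure rejection sampling essentially never succeeds, so the
constructor uses randomized greedy assignment with min-conflicts repair
under a 10,000-attempt cap, raising a design-infeasibility error on
exhaustion.  No-choice trials necessarily thicken toward the end of the
run, as in the task.

**Dental task (Experiment-2 shape).**  Sooner appointment always "today";
later delays {1, 5, 13, 32, 89, 237} days; magnitudes {16, 37, 46, 51, 55,
60}% of worst imaginable dental pain.  Each non-60 magnitude is paired with
60% at every delay in both orderings, plus one 60-vs-60 tie per delay: 66
pairs.  The grid size is configurable since the full factorial is the only
reconstructible composition.

**Agents.**  Simulated subjects choose through the same softmax/value code
path used for fitting, so empirical choice frequencies converge to the
model probabilities by construction (property-tested with binomial
envelopes).  Shock counts in a delivered episode are conceptually Poisson
around the stated mean, but agents decide on the stated mean, which is the
modelling assumption throughout.  The phenotype presets are: zero = `null`
(beta 2); positive = `exp_discount` (beta 1, gamma_P 0.92); negative =
`undiscounted_dread` (beta 2, gamma_P 0.9, alpha 0.5); reversing =
`restricted_dread` with concave Weibull utility (r_max 10, scale 4, shape
1.5; beta 1, gamma_P 0.945, alpha 1.0).  The reversing preset needs the
concave utility: with linear utility the magnitude channel dominates the
dread channel and the binned reversal never reaches exact-test significance
at 190 choices per agent; concavity compresses magnitude differences
exactly as rating-derived utilities do, and the preset's aversiveness peak
(delay ≈ 17 trials) sits inside the design range.  Ratings are simulated
as a symmetric up-then-down staircase over 2-14 shocks with Gaussian noise
(sd 0.5 by default) clamped to the 0-10 scale; the noise model is a
generator choice, not an empirical claim.

## Estimation

Per-subject maximum likelihood by Nelder-Mead simplex in an unconstrained
space: each parameter is mapped to its box through a logistic bijection
(bounds: beta [0, 1000]; gamma_P, gamma_D, alpha [0, 1]; A [-50, 0]).
Parameters landing within 1e-6 of a bound (relative) are reported at the
bound and flagged, never silently clamped; separation cases (e.g. subjects
who always choose sooner) surface this way.

The multistart overlay: candidate points are sampled between the bounds
(uniformly, except beta log-uniformly over [0.01, 1000] — uniform draws on
a four-decade box almost never land in the behaviorally plausible decade),
a cheap screened presample (40x the start count, one likelihood evaluation
each) ranks them, and Nelder-Mead launches from the best half plus an
equal number of unscreened random points to preserve basin diversity.
Screening was added because plain random starts at desk scale repeatedly
stranded the 4-parameter general model in local optima, violating the
nesting hierarchy.  Desk-scale defaults are 20 starts and 1 restart;
`FitConfig.exhaustive()` restores 100 starts x 1000 whole-procedure
repeats.  Simplex tolerances default to 1e-6 on parameters and function
value.

Verification: an exhaustive log-scale grid search (default resolution 25
per axis, chunked evaluation, local refinement at 10x resolution around
both the grid and simplex optima; zero bound endpoints replaced by 1e-5 of
the bound magnitude) is available for the three-parameter models, and the
acceptance suite requires grid/simplex agreement within 0.1 log-units.
Central-difference second partials of the negative log-likelihood provide
a curvature check at interior optima (flagged inapplicable on a bound).

Joint two-frame fits in the framing battery add structural safeguards:
the fully free variant is fitted as two independent per-frame fits (an
exact decomposition) and floored at the likelihood attained by every
restricted variant's solution; the fully shared variant is refitted through
the same joint machinery with warm starts; restricted variants warm-start
from the shared and per-frame solutions.  Without these, search-effort
asymmetries at desk scale could invert the nesting hierarchy.

## Model comparison and framing

BIC = -2L + k ln(n) with n the number of choices entering the likelihood
being scored; group comparison is fixed-effects (per-subject BICs summed).
Nested models also get likelihood-ratio tests; at the group level
per-subject chi-squares and degrees of freedom are summed (one freed
parameter across N subjects gives df = N), and per-subject likelihood
ratios are summarized by their geometric mean.  The framing battery fits
the general dread model jointly to pain and relief frames under six
sharing maps (k = 8 / 5 / 5 / 5 / 5 / 4) and ranks by summed BIC.

An identifiability caveat belongs here because it shaped the validation
conditions.  Writing f(T) for the bracketed temporal weight in V, every
general-dread curve is a constrained two-exponential mixture, which makes
the gammaP-framing and gammaD-framing restrictions nearly observationally
equivalent on these designs: across a broad scan of base parameters the
best gammaD-split mimic of a gamma_P split (0.95 vs 0.85) lies within
~0.05-0.35 expected log-units per 190-choice subject of the truth.
Discrimination is best when choices remain stochastic; at beta around 1 on
the near-term-sooner design, choices become almost deterministic and the
restrictions are indistinguishable in practice.  The battery consistency
test therefore runs at beta = 0.25 (the representative softmax value used
throughout the examples), gamma_D = 1, alpha = 1, with 25 subjects — the
study scale — where the generating restriction wins reliably.  Users
fitting real data should expect gammaP- vs gammaD-framing comparisons to
need cohort-scale evidence, not single subjects.

Model-selection consistency has an analogous caveat: restricted dread can
mimic undiscounted dread to ~0.06 log-units per 190 choices at
(beta 0.25, gamma_P 0.9, alpha 0.5), so the consistency harness uses
well-separated generating points instead — null (beta 1), exp_discount
(beta 1, gamma_P 0.95), undiscounted (beta 0.5, gamma_P 0.85, alpha 1.0;
analytic gap to the best restricted mimic ≈ 1.9 log-units per 190 choices)
and restricted (beta 1, gamma_P 0.93, alpha 0.5, whose non-monotone
signature cannot be mimicked) — at 3 agents x 190 choices x 50 seeds with
desk-scale fits (4 screened starts, 1e-5 tolerances).  Parameter recovery
is validated separately at the representative point (beta 0.25, gamma_P
0.9, alpha 0.5; 20 agents x 190 choices; median |error| in gamma_P ≤ 0.1).

## Behavioral analysis

Choice curves bin the later-option choice proportion by delay-difference
tertile (zero / short / medium / long; trials for the shock task, days for
the dental task).  Phenotype classification: a subject is *zero* if no
bin's exact binomial test against 0.5 is significant (alpha = 0.05);
otherwise significant increases and decreases are collected from two-sided
Fisher exact tests between populated bin pairs — all pairs by default,
because a reversing subject's recovery typically spreads over two bin
steps and adjacent-only testing under-detects it (an adjacent-only mode is
available) — plus the first binomial-significant bin counted as a change
from the theoretical 0.5 anchor at zero delay difference (this anchors a
subject sitting uniformly below 0.5 with no between-bin trend as
*negative*).  Increases only → *positive*; decreases only → *negative*;
both → *reversing*.  The four labels are mutually exclusive and exhaustive
on any curve with at least two populated bins (property-tested).

Per-subject framing effects use a Fisher exact test on the 2x2 table of
sooner/later counts by frame, with a direction flag positive when sooner
pain is chosen more often in the pain frame.  Exclusions: end-of-session
rating of the maximum shock rate below 4/10 ("adaptation"), or 100% sooner
choices in at least one frame ("maximum dreader", whose indifference point
lies outside the offered choice set).  Group repeated-measures ANOVA is
delegated to statsmodels as clearly labelled convenience output.

## Problem sizes and determinism

Every generator and fit is deterministic given its seed; hypothesis-based
property tests run derandomized.  The shipped validation uses desk-scale
sizes chosen as the package's own defaults: recovery at 20 agents x 190
choices; selection consistency at 3 agents x 190 choices x 50 seeds per
generating model; the framing battery at 25 subjects (split frames) and 10
subjects (identical frames); classification at the published 25-agent
phenotype mix (7/4/12/2).  The exhaustive multistart scale
(`FitConfig.exhaustive()`: 100 starts x 1000 repeats) remains one
constructor call away but is unnecessary for these problem sizes.

## Known limitations

- Synthetic agents are stationary softmax choosers: no learning, lapses,
  response-time structure, or sequential dependencies between interleaved
  choices (additive independence of dread is assumed, as in the softmax
  differencing argument).
- The gammaP/gammaD near-equivalence above means battery results on small
  cohorts should be read as evidence about *whether* frames differ (the
  likelihood-ratio tests against no-framing are well powered), not *which*
  discount parameter carries the difference.
- Passing recovery and consistency tests show the pipeline is correct and
  well-calibrated under its own generative assumptions; they cannot certify
  behavior on real subjects, whose choices may violate the value-family
  assumptions in ways the synthetic cohorts do not emulate.
- The exact composition of the published 70-choice dental set is not
  reconstructible from its stated factors; the generator's 66-pair full
  factorial is the closest canonical set and the count is configurable.
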