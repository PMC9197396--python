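# Methods

This note documents the models implemented in `circlequest`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not establish about real data.

## Task model

A circle of radius r = 130 px is hidden inside a circular search field.
The field radius defaults to 540 px so that the hidden circle covers
(130/540)² ≈ 5.80 % of the search area. Touching the field at σ yields a
purple dot if |λ₀ − σ| ≤ r (λ₀ the hidden centre, boundary inclusive) and
a white dot otherwise. A free purple dot is shown at trial onset; every
further touch costs ηs ∈ {1, 5} credits from an initial reserve
R₀ ∈ {95, 130}. After an 18 s sampling window the participant places a
disc at λ̂ and receives

    score = R₀ − s·ηs − e·ηe ,

with s the number of *paid* touches, e = |λ̂ − λ₀| in pixels, and
ηe = 1.2 credits/px. The four (R₀, ηs) combinations are presented as four
blocks of 15 trials each. Coordinates are continuous, origin at the field
centre; the dot radius (4 px) is cosmetic and classification uses the
touch point only.

## Ideal observer

Uncertainty is quantified by a sequential Bayesian observer over candidate
centres λ on a square lattice of spacing `grid_stride` (default 4 px;
cohort-scale analyses use 8 px, see *Problem sizes*). The prior is uniform
over lattice points with |λ| ≤ field_radius − r, i.e. centres whose circle
lies fully inside the field — the hidden circle is always findable, so
centres that would clip the boundary are excluded. Each dot contributes a
0/1 likelihood (inclusive disc for purple, strict complement for white);
with a uniform prior the posterior is therefore always uniform over the
*feasible set* of centres consistent with every dot. Observations commute,
and a batch feasible-set construction is kept alongside the sequential
update as an independent test oracle. A dot sequence with an empty
feasible set raises an error rather than returning a degenerate
posterior: in this generative model it can only mean corrupt input.

The expected error of a candidate placement c is

    EE(c) = Σᵢ p(λᵢ) · |c − λᵢ| ,

and the trial's uncertainty is EE_opt = min_c EE(c), attained at the
ideal placement λ* (a Weber point of the posterior). Candidates are the
lattice points in the bounding box of the posterior support: EE is a
nonnegative-weighted sum of convex distance functions, hence convex, so
its minimiser lies in the support's convex hull. Exact ties are broken to
the lexicographically smallest candidate.

Numerics. For a single purple dot away from the field boundary the
posterior is a uniform disc of radius r and EE_opt has the closed form
2r/3 ≈ 86.67 px; the lattice value converges to it within 1 % at strides
≤ 2 px, which is the documented accuracy check for the discretisation.
On hot paths (trajectories, simulated placements) EE_opt is found by
coarse-to-fine multigrid descent over the same lattice instead of dense
evaluation; convexity makes the two agree (property-tested), with the
caveat that on exact plateaus the descent may return a different —
equally optimal — tie point than the lexicographic rule.

## Sampling efficiency

Across a participant's trials the EE at the ideal placement decays
roughly exponentially with the number of dots on screen. With s counting
dots (the free dot is s = 1) and the baseline EE₁ fixed at the
participant's mean first-dot EE, the two-parameter model

    EE(s) = (EE₁ − EE∞) · (1 − α)^(s−1) + EE∞ ,  0 < α < 1, EE∞ > 0

is fitted by least squares pooling all trials and dot indices. α is the
information extraction rate — the per-sample proportional reduction of
excess uncertainty and the participant's efficiency index — and EE∞ the
asymptote imposed by task geometry. One fit per participant pools all
four conditions, since the baseline is defined as an average over the
participant's full trial set; the average is taken over available trials
if some are missing. The SSE surface is only two-dimensional but can be
locally flat, so fitting uses a coarse α × EE∞ multistart grid followed
by bounded local refinement (tolerances 1e-12); bounds are
α ∈ (1e-6, 1−1e-6), EE∞ ∈ (1e-6, EE₁). Decay-free data resolves to the
smallest-α corner of the grid, i.e. a flat prediction.

## Optimal stopping

The expected value of stopping after s paid samples replaces the realised
error by the model-predicted EE:

    EV(s) = R₀ − s·ηs − ηe · EE(s + 1) ,

where the indexing reconciles two conventions: costs are charged per paid
touch, while the decay model counts on-screen dots, so s paid touches put
s + 1 dots on screen. EV is evaluated for s = 0…s_max with s_max the
smallest count whose predicted EE is within 0.1 % of EE∞ (capped at 60);
the tail beyond carries negligible probability mass because EV decreases
linearly in s there. A softmax over EV values — raw credit units, unit
temperature, computed with max-subtraction for overflow safety — gives
the stopping distribution of a rational agent; in raw credits this is
nearly deterministic around the optimum, which is intended: it is the
rational benchmark, not a behavioural model. The optimal count s* is the
smallest argmax of EV (equivalently the mode of the softmax), and
deviation from optimality is the participant's mean paid samples minus
s* for that condition; positive values are over-sampling.

Two structural properties follow and are verified empirically: s* is
invariant to R₀ (an additive shift of EV), and s* is weakly decreasing in
ηs. Sweeps also show s* weakly *decreasing* in α at fixed costs: faster
extraction reaches the EE asymptote sooner, so the marginal sample stops
paying for itself earlier.

## Behavioural markers and statistics

* **ISI** — mean interval between consecutive paid touches, averaged over
  a participant's trials; trials with fewer than two paid touches have no
  interval and are excluded. Shorter ISI = faster sampling.
* **Subjective uncertainty** — confidence ratings z-scored within
  participant (sample SD) and sign-flipped; constant ratings produce
  zeros with a warning. Within-participant scoring removes individual
  scale use before comparing across people.
* **Affective burden** — both questionnaire scores are standardised and
  the first principal component taken, oriented positively with
  depression (and with both scores when they correlate positively). For
  two standardised variables PC1 explains (1 + |r|)/2 of the variance —
  at r = 0.68 the familiar 84 % — so the composite is a symmetric
  weighting of depression and anxiety.
* **Partial Spearman correlation** — all variables rank-transformed,
  x and y residualised on the covariates by least squares, Pearson
  correlation of residuals; two-sided p from 10,000 seeded permutations
  of the residual pairing (add-one correction). On ranks with a single
  covariate this reproduces the first-order recursive partial-correlation
  formula to machine precision.
* **Group contrasts** — difference of group means with a two-sided
  permutation p (10,000 seeded label shuffles). Families of correlations
  reported together are Bonferroni-corrected (threshold 0.05/k).
  Complete-case handling throughout.

## Synthetic cohorts

The generator stands in for participant data and encodes the structure
the analysis is meant to detect. Each agent touches at lognormal
inter-touch intervals (positivity and right skew of human inter-response
times). With probability q the touch is *informative*: from a coarse
proposal set (points within one circle radius of the posterior bulk plus
a few support points) the agent picks the touch minimising the expected
one-step-ahead EE, averaging the purple/white outcomes; otherwise the
touch is uniform over the field. Inside this lookahead each outcome
branch is scored by the EE at its centroid — an O(n) surrogate for the
Weber point, exact for symmetric supports and an upper bound in general —
while all analysis-path EE values use the lattice optimum. Sampling stops
when the 18 s budget runs out or the myopic expected gain
ηe·(EE_now − EE_next) − ηs of the greedy candidate falls below the
agent's stopping threshold (ignored with a small lapse probability);
placement is the exact posterior optimum. The hidden centre is drawn
uniformly from the prior lattice, which guarantees the feasible set never
empties.

Cohort defaults are the study conditions: 27 controls + 27 SCI; median
inter-touch interval 1.7 s (between-participant SD 0.15 log units,
within-trial scale 0.35); stopping threshold 2.0 ± 0.5 credits;
q = 0.7 ± 0.1 in *both* groups; lapse 0.05. The SCI group's shifts are
−0.30 log-seconds on the interval (2 SD faster) and −1.0 credits on the
threshold (2 SD lower, hence more samples), so the generated dissociation
is faster and more extensive but equally efficient sampling.
Questionnaires draw age, cognitive score, BDI-II, HADS-depression and
HADS-anxiety from group-specific Gaussians matching the cohort
demographics table, with within-group correlation ρ = 0.55 between the
affective scores (chosen so the pooled correlation, inflated by the group
shift, lands near the 0.68 that puts 84 % of variance on PC1), rounded
and clipped to instrument ranges.

Passive offers: for each of five experimental uncertainty bands
(16.3–24.4, 27.1–38.9, 57.5–58.9, 73.33–74.18, 91.9–93.3 px) and five
repetitions, a 4-purple/4-white configuration is rejection-sampled until
its ideal-observer EE_opt lands in the band; each accepted configuration
is offered at all four reward levels (40, 65, 90, 115), giving 20 offer
types × 5 = 100 trials. Proposals realise a hidden circle, scatter purple
dots within a spread fraction u of its radius and white dots just outside
it; u is annealed per band (clumped purples with tightly carving whites
produce ring-like feasible sets whose EE exceeds the single-dot 86.7 px,
which is how the top band is reachable). Simulated responses share one
model across groups — confidence decreasing in band with rating noise,
acceptance logistic in reward minus an uncertainty penalty — matching
intact passive performance in both groups.

What the generator does not emulate: motor noise in touches and
placement, learning or fatigue across blocks, non-stationary policies,
heavy-tailed questionnaire distributions, and any dependence of passive
responses on active-task behaviour. Passing recovery tests therefore
shows the *pipeline* recovers effects it was designed for under its own
generative assumptions, not that those assumptions describe people.

A known interaction: because the true EE decay is not exactly
exponential (survivorship flattens its tail), participants with longer
trajectories — lower stopping thresholds, faster sampling — weight the
slower tail more, which biases their fitted α slightly downward (on the
order of 0.2 between-participant SD at the default q dispersion). Equal
q therefore yields *nearly*, not exactly, equal fitted α between groups,
and the recovery study's equal-efficiency null is occasionally rejected
for this reason rather than by chance alone.

## Problem sizes

Dense per-pixel evaluation is replaced by the lattice observer; stride
4 px is the package default, and all cohort-scale runs (the analysis
scripts and the recovery studies) use stride 8 px, where the single-dot
EE is within 0.03 px of the stride-4 value. The end-to-end recovery study
runs 100 replicate 27+27 cohorts with one 5-trial run of each condition
block per participant — at 2-SD between-participant effects the group
contrasts are powered far beyond the 95 % requirement at 20 trials per
participant, and the reduced trial count keeps the study at minutes of
CPU. Parameter-recovery suites for the efficiency model use 60-trial
datasets matching the full design.

## Known limitations

* The observer grid makes EE_opt an upper approximation of the continuous
  optimum; all comparisons are grid-consistent (the same stride is used
  within any analysis), and stride convergence is tested rather than
  assumed.
* The softmax stopping distribution in raw credits is effectively a
  delta at s* for realistic credit gaps; it is reported for completeness
  and the analysis relies on s*.
* Whether centres whose circle clips the field edge should be admitted is
  a modelling choice; this package excludes them. The top passive band
  (91.9–93.3 px) exceeds the unclipped single-purple-dot value 2r/3,
  which the generator reaches through white-dot carving.
* The efficiency model is deliberately simple (two parameters, shared
  across conditions); systematic departures from exponential decay fold
  into EE∞ and the α bias noted above.
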