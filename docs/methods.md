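# Methods

`probreason` analyzes the *probabilized conditional inference task*: for each
everyday conditional "if p then q" a participant estimates, on a 0–100 scale,
the probability of the conditional, of the minor premise, of the conclusion of
one inference form (MP, MT, AC or DA), and of five auxiliary quantities
(P(q|p), P(p∧q), P(¬p∨q), P(q|¬p), and the bare conclusion event).  A second,
*deductive* task elicits endorsements of all four forms for two abstract
conditionals under strict logical instructions.  This note records the models,
the numerical choices, and what the synthetic generator does and does not
emulate.

## Normative scoring

**Coherence intervals.**  With c = P(if p then q) read as P(q|p) and m the
minor-premise probability, the conclusion probability consistent with *some*
coherent joint distribution over {p,q} × {¬p,¬q} forms a closed interval,
derived from the law of total probability with the unknown quantities swept
over [0, 1]:

| form | minor m | conclusion | interval |
|------|---------|------------|----------|
| MP | P(p)  | P(q)  | [cm, cm + (1−m)] |
| MT | P(¬q) | P(¬p) | [max((1−c−m)/(1−c), (c+m−1)/c), 1] |
| AC | P(q)  | P(p)  | [0, min(m/c, (1−m)/(1−c))] |
| DA | P(¬p) | P(¬q) | [1−m−c(1−m), 1−c(1−m)] |

Terms with a vanishing denominator (c = 0 or c = 1) are dropped from the
max/min; if no term survives the bound defaults to the vacuous 0 or 1.  All
bounds are clipped to [0, 1].  `oracle_interval` re-derives every interval by
brute force — sweeping P(q|¬p) (MP/DA) or the conclusion marginal itself under
a feasibility test (MT/AC) over a grid — and the test suite holds the closed
forms to the oracle within one grid step on random premises.  Membership is
tested on the closed interval with tolerance 1e-9; interval widths are never
rounded before comparison.  Intervals may be extended by 0.05 or 0.1 on both
sides (clipped) to tolerate near-miss responses.  The chance-corrected
coherence score is `inside − width`: the interval width is exactly the
probability that a uniform random response lands inside.

**p-validity.**  Uncertainty is U = 1 − P.  A response is p-valid when the
conclusion uncertainty does not exceed the summed premise uncertainties,
truncated at 1; the truncated sum is simultaneously the chance level, because
a uniform response's conclusion uncertainty is itself uniform.  The score is
`valid − chance`.  Slack variants (0.05, 0.1) relax the validity inequality
(u_conclusion ≤ usum + slack) while leaving the chance level untouched, so the
slack analyses remain on the same scale; the inequality uses a 1e-9 float
tolerance.  MP and MT are the forms p-validity restricts; AC and DA indicators
are computed but flagged descriptive.  Group summaries use a participant-level
bootstrap (mean of within-participant mean scores, 2000 resamples, percentile
95% CI, seeded) rather than any mixed model: with responses nested in
participants, resampling participants is the assumption-light substitute this
package deliberately stops at.

## The dual-source model and its baselines

The knowledge-based component ξ is the conclusion point estimate implied by
the law of total probability from three elicited values: c, m, and the
probability of alternatives b = P(q|¬p).  For MP it is ξ = cm + b(1−m);
solving the same identity for the other conclusion marginals gives
DA: ξ = 1 − c(1−m) − bm, MT: ξ = 1 − (1−m−b)/(c−b), AC: ξ = (m−b)/(c−b).
When c = b (denominator below 1e-12) no MT/AC prediction exists; the
participant is excluded from all model fits, since the baseline is undefined
for them.  Incoherent elicitations can push ξ outside [0, 1]; it is clipped
with a flag so both readings (clip vs missing) remain recoverable.

The form-based component τ per inference is the mean endorsement across the
two abstract conditionals of the deductive task — data, not a parameter.  The
blended prediction is

    λ(τ + (1−τ)ξ) + (1−λ)ξ  =  ξ + λτ(1−ξ),    λ ∈ [0, 1],

nondecreasing in λ and τ and never below ξ.  Three models are fitted per
participant to the four conclusion responses with RMSD as criterion: BL (ξ
alone, no parameter), BL\* (b replaced by clip(s·b, 0, 1), one scaling
parameter s ≥ 0 absorbing bias in the post-inference b elicitation), and DS
(the mixture, one parameter λ).

**Optimization.**  Deterministic and derivative-free: a grid scan (step 0.001
on [0, 1]; BL\* adds 500 log-spaced points on (1, s_max]) followed by
golden-section refinement between the neighbours of the best grid point.
Ties — including numerically flat objectives, compared at 1e-12 — break toward
the smaller parameter, and the refined value is kept only when it improves the
objective by more than 1e-12, so a flat objective reports its smallest
parameter rather than an arbitrary interior point.  s_max defaults to 20: the
scaling parameter is unbounded in principle, but fitted values several times
larger than the b-scale ceiling of 1/b are indistinguishable once s·b clips at
1, and 20 leaves ample headroom over empirically plausible values while
keeping the search bounded and reproducible.  During the BL\* scan a candidate
s can itself produce c − s·b = 0 for MT/AC; that s simply has no prediction
and receives an infinite objective.

## Conditional-probability statistics

`equation_stats` pools all item-by-participant responses: pairwise Pearson
correlations of P(if p then q) with P(q|p), P(p∧q), P(¬p∨q) and P(q|¬p), and
a simultaneous least-squares regression on the four predictors.  Responses are
nested within participants and conditionals; every output carries that caveat
and the standard errors are labelled naive.  Zero-variance columns yield
undefined (NaN) correlations, never 0; a rank-deficient design raises an error
naming the collinear columns.  Rows missing any of the five items are dropped
listwise, and the row count is reported so the analyst can see what was used.
Mixed-effects or other model-based inference is intentionally out of scope.

## The synthetic generator

Raw data from deployments of this task are rarely shared, so the generator
produces experiments with the structure the analyses assume, plus a truth
table of all
latent values for recovery testing.

* **Latent joints.**  Per participant × conditional, the four joint cells are
  Dirichlet-distributed with pseudo-counts (1.0, 1.0, 0.8, 2.2) and a
  believability boost (default 0.6) added to the pq cell.  Under a Dirichlet,
  P(q|p) ~ Beta(w_pq + boost, w_p¬q) independently of the other cells, so the
  boost tilts conditionals toward believability exactly where intended.  The
  defaults give P(q|p) ~ Beta(1.6, 1) (mean 0.62, sd 0.26) and
  P(q|¬p) ~ Beta(0.8, 2.2) (mean 0.27, sd 0.22) — the response profile that
  moderately-to-highly believable everyday materials elicit.
* **Responses.**  Every non-conclusion item is the exact derived probability
  of the joint (with the conditional item equal to P(q|p): the two are
  independent noisy readings of one latent value) plus truncated Gaussian
  noise on the probability scale (default sd 0.05; the instrument's bounds
  make truncation the natural noise model).  The conclusion response follows
  the dual-source mixture with ξ the conclusion marginal of the noiseless
  joint, τ the form profile (default MP 0.95, MT 0.75, AC 0.55, DA 0.55,
  the usual deductive-task ordering MP > MT > AC ≈ DA), and a participant-level
  λ (default uniform(0, 0.7), covering the empirically plausible range).
  Deductive responses are τ plus noise.  Defaults: 30 participants, four
  blocks each, conditionals drawn without replacement from a pool of 16 and
  assigned to forms in randomized order; one master seed drives everything
  bit-for-bit.
* **Discretization.**  Noisy responses are rounded to the instrument's 0–100
  integer grid.  With noise_sd = 0 the generator instead emits exact
  probabilities: the noiseless mode exists to exercise theorems (coherent
  point estimates lie inside the ext-0 interval; MP/MT point estimates are
  p-valid at slack 0) that hold in exact arithmetic but can be broken by
  rounding premises and conclusion to the grid independently.  Pass
  `discretize` explicitly to override either default.
* **What it does not emulate.**  Item content and semantics, order and
  anchoring effects within a block, participant-level response styles beyond
  λ, heterogeneity of τ across participants, and any influence of the
  participants' earlier experimental session.  Passing tests therefore show
  that the pipeline recovers what it assumes from data that satisfy those
  assumptions — not that real reasoners satisfy them.

The coherent-reasoner checks fix λ = 0 as well as noise_sd = 0: with λ > 0 the
mixture deliberately lifts the conclusion above ξ and may leave the coherence
interval (e.g. a point interval when m = 1), whereas MP/MT p-validity survives
any λ because raising the response only lowers its uncertainty.

## Problem sizes and reproducibility

The test suite uses 250 noiseless participants (1000 records) for the theorem
checks, 1000 random premise pairs per form for the formula-vs-oracle sweep
(grid 1001), 50 noiseless and 200 noisy participants for λ recovery, and the
30-participant default condition for the end-to-end analyses — sizes at which
every property examined is already stable.  All randomness flows from
explicit seeds; the CLI stamps every output table with the seed and a
content-based digest, and identical invocations produce byte-identical files.

## Known limitations

Chance correction assumes uniform random responding as the null; coherence
interval width and truncated premise uncertainty are chance levels only under
that assumption.  The pooled equation statistics ignore nesting by design.
Exclusion of undefined-ξ participants follows the all-or-none rule rather
than dropping single inferences, so one degenerate elicitation costs a
participant's entire fit.  λ and s are fitted from four observations each:
point estimates are noisy by construction, which is why the recovery tests
target rank agreement rather than absolute error once noise is present.
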