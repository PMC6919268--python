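# Methods

## Task environment

The payoff schedule is fixed by the task design: two risky decks (A, B) with
gain menu {190, 200, 210} and loss menu {240, 250, 260}, two safe decks
(C, D) with gains {90, 100, 110} and losses {40, 50, 60}, a 50% win
probability per draw, an initial endowment of £2000 and 80 trials. Every
trial is either a win or a loss, never both, so the net outcome
x(t) = gain − loss is single-signed; money is stored as integer pounds. The
running total is tracked for display only and never enters a likelihood.

Validity filtering follows the task's conventions: a choice with reaction
time under 200 ms is *premature*, a missing choice is *omitted*, and both
are excluded from every behavioral denominator and every likelihood term.
By default an invalid trial also triggers no learning update — the outcome
is treated as unobserved. The alternative (update on the outcome anyway)
is exposed as `update_on_invalid` because the analysis convention for these
trials at the model level is genuinely underdetermined; it changes
log-likelihoods only for subjects who actually have invalid trials.

Block summaries partition trials 1..80 into four 20-trial spans by the
*original* trial index, so exclusions shrink a block's denominator but never
shift block boundaries.

## Models

All three models value the net outcome with the prospect-theoretic power
utility u(x) = x^α (x ≥ 0), −λ|x|^α (x < 0), and choose by softmax with
sensitivity θ = 3^c − 1. Expectancies and perseverance strengths start at
zero for all decks. Parameter supports follow the conventions of the
hierarchical IGT-modeling framework this package mirrors: A ∈ [0,1],
α ∈ [0,2], c ∈ [0,5], λ ∈ [0,10], k ∈ [0,1], ω ∈ [0,1], ε_p/ε_n unbounded.
The perseverance branch uses the standard sign convention — ε_p is the
increment after a nonnegative net outcome, ε_n after a negative one; a tie
(x = 0) takes the ε_p branch, though it is unreachable under the default
schedule. VPP with ω = 1 reduces exactly to PVL-Delta, which the tests
exploit as a nesting check.

Log-likelihoods are computed in log space throughout (log-sum-exp softmax),
since θ·ΔV can exceed 700 for consistent subjects and the choice
probabilities themselves underflow double precision.

## Hierarchical model and sampler

For a group of n subjects and a model with P parameters, each parameter p
has a group-level location μ_p ~ Normal(0, 1) and scale σ_p ~ HalfNormal(1)
on an unconstrained scale, and subject deviates z_ip ~ Normal(0, 1)
(non-centered). Bounded parameters map to their support through the probit
link Φ(·)·upper; ε_p/ε_n use the identity link. Groups are always fitted
independently, because model comparison sums WAIC over per-group fits.

No gradient-based sampler backend is part of this package's dependency
footprint, so posterior sampling uses a composite Markov kernel written
here:

1. **Subject block** — componentwise adaptive random-walk Metropolis on the
   z deviates, proposed for all subjects simultaneously (subjects are
   conditionally independent given the group level), accepted per subject;
   two passes per sweep by default.
2. **Group block** — componentwise random-walk Metropolis on each of the 2P
   group scalars (μ_p and log σ_p), followed by several joint proposals on
   the whole group vector using a covariance estimated from the warmup
   history (adaptive Metropolis). The joint step is what lets the sampler
   move along the strong α–c–λ–ω ridges of these likelihoods.
3. **Interweaved centered step (ASIS)** — holding each subject's raw value
   y_ip = μ_p + σ_p z_ip fixed (so the likelihood is unchanged), μ_p has a
   conjugate normal conditional and log σ_p a cheap univariate conditional
   sampled by slice sampling; z is then recomputed. Without this step the
   non-centered parameterization leaves μ_p nearly frozen for parameters
   whose subject-level values the data pin down tightly (the perseverance
   increments especially).

Proposal scales adapt during warmup toward acceptance 0.44 (componentwise)
and 0.234 (joint) on a Robbins–Monro schedule and are frozen afterwards.
Chains are initialized near a pooled maximum-a-posteriori point found by
multi-start Nelder–Mead (10 starts): the pooled VPP surface is multimodal —
a perseverance-dominated mode (ω ≈ 0) can imitate an RL-dominated one
(ω ≈ 1) — and single-start optimization regularly lands in the wrong basin.
Because all chains start jittered around the best mode, split-R-hat
validates within-mode mixing rather than mode coverage; this is stated
rather than hidden. Convergence is flagged (never silently passed) when any
split-R-hat exceeds 1.1 or any group-level effective sample size falls below
100 per chain, both computed with ArviZ.

Defaults are 4 chains × (1000 warmup + 1000 draws); validation experiments
in the test suite use 2 × (500 + 500), which keeps a 20-subject VPP fit
around 20–30 s on one CPU with the numba likelihood kernel. The kernel is
checked against a pure-numpy path and an independent straight-line recursion
to 1e−10.

## Model comparison

WAIC uses the **participant** as the pointwise unit: the matrix entry for
draw s and subject i is the summed log-likelihood of subject i's whole
choice sequence, because trial-level terms are sequentially dependent. Then
lppd = Σ_i log mean_s exp(ll_si) (log-sum-exp), p_waic = Σ_i var_s(ll_si)
with the S−1 denominator (documented because WAIC references differ; ArviZ
uses S, and the cross-check test rescales accordingly), and
waic = −2(lppd − p_waic). A model's overall score is the sum of its
per-group WAICs; the smallest total wins, ties are reported as ties. No
standard error of WAIC differences is reported by default.

## Group contrasts

Contrasts are computed on the **group-level means on the constrained
scale** — the scale on which parameter tables are reported — not on pooled
subject-level draws (the alternative is noted; it mixes between-subject
spread into what is meant to be a group-mean comparison). Since group fits
are independent, any pairing of their draws yields the correct difference
distribution in expectation: draws are shuffled with a generator seeded per
(seed, group label) — so identical fits difference to exactly zero and
swapping the operands negates the draws exactly — truncated to the shorter
chain and paired by index. The 95% HDI is the shortest contiguous window
containing ⌈0.95·S⌉ sorted draws, ties broken toward the lower window; a
parameter "differs" between groups when that interval excludes zero. No
multiplicity correction is applied, matching the per-parameter rule the
analysis mirrors; the full 8-parameter × 3-pair table is emitted so readers
can judge multiplicity themselves.

## Synthetic cohorts

`default_presets()` encodes the three study groups — control (n = 20), ASD
(n = 24), OCD (n = 20) — as VPP generator specs whose constrained-scale
group means and SDs are the published group estimates (e.g., control
c = 3.16 (0.33), ω = 0.94 (0.01); ASD k = 0.63 (0.17)). Two assumptions are
deliberate and documented:

* The published SDs are treated as **between-subject** spreads. They may in
  fact be posterior uncertainties of the group means; treating them as
  spreads is the conservative choice for recovery experiments (more
  heterogeneity, harder recovery), but it means, e.g., that subjects' ω
  values in the control preset differ by only ~0.01.
* Bounded parameters are realized as probit-squashed normals whose raw-scale
  location and scale are **moment-matched** numerically (the squashed mean
  has a closed form; the second moment is a bivariate-normal orthant
  probability; a 1-D root solve recovers σ). ε_p/ε_n are plain normals.

Agents are clean by default (no omissions or premature responses); an
optional contamination rate converts a random fraction of trials to
premature/omitted records to exercise the filters.

What the generator does *not* emulate: reaction-time distributions,
within-session drift or fatigue, deck-order effects, and any behavioral
feature outside the three models' scope. Passing recovery tests therefore
show that the estimation machinery is correct *under the assumed generative
family*, not that real adolescents behave like VPP agents. Notably, cohorts
generated from the published ASD/OCD parameter sets show strong safe-deck
preference while the control preset hovers near 0.5 — the original groups
did **not** differ behaviorally, which is a visible mismatch between the
fitted-parameter tables and observed behavior; it does not affect the
validity of the recovery harness, which compares against its own generating
values.

## Validation results and known limitations

* Parameter recovery (control preset, 20 subjects × 80 trials, reduced
  MCMC): 6–8 of 8 group means inside their 95% credible intervals across
  the seeds examined; subject-level rank correlation ≈ 0.5–0.8 for c and
  ≈ 0.7–0.9 for ε_p/ε_n.
* Subject ordering in ω is **not recoverable** under the control preset:
  with a generating between-subject SD of 0.01 and a per-subject posterior
  SD an order of magnitude larger, the rank correlation for ω hovers near
  zero. This is an information limit of 80 trials, not a sampler defect —
  at the recovery seed the sampled region has higher total likelihood than
  the generating parameters themselves, reflecting the α–c–ω trade-off.
* Model recovery: VPP-generated cohorts under all three presets are
  correctly selected by summed WAIC even at 5 subjects per group with short
  chains; the margin is large (hundreds of WAIC units).
* The sampler is a random-walk/Gibbs composite, not HMC: effective sample
  sizes per sweep are far lower than a gradient sampler would achieve, and
  short chains can leave R-hat above 1.1 for the slow directions (c, ω).
  Diagnostics are always attached to the fit; `--strict` mode turns them
  into a nonzero exit code.
* Problem sizes in the test suite (5–20 subjects, 300–500 iteration chains)
  were chosen to keep a full validation round on one CPU in a few minutes;
  they are stated with each experiment.
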