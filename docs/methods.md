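# Methods

## Task environment

The modified IGT presents four decks of 60 cards. Card-by-card amounts
are a deterministic packaged table chosen to reproduce the task's stated
structure rather than any specific commercial deck: decks A and B pay
wins varying around a $100 block-1 mean, decks C and D around $50; deck
A carries five losses per ten cards summing to −$1250, deck B a single
−$1250 loss, deck C five losses summing to −$250, deck D one −$250 loss.
Every 10-card block is therefore net −$250 for A/B and net +$250 for C/D
at block 1, preserving the disadvantageous/advantageous long-run
structure. Amounts in block k are the base amounts times
`1 + escalation_rate·(k−1)` (default rate 0.1), applied to wins and
losses alike and rounded to whole dollars; rounding is monotone, so
amounts never decrease across blocks for a fixed within-block position.

Sessions run 100 trials by default. A deck chosen for the 60th time is
depleted; the trial on which that happens is the last one used for model
fitting (the choice was still made among four decks), and later trials
are excluded from likelihoods but retained for behavioral metrics, which
the depletion rule does not affect. The simulator restricts its softmax
to non-depleted decks, so a session can never overdraw a deck.

## Cognitive models

All three models share: expectancies initialized to zero (uniform first
choice), softmax choice probabilities computed with max-subtraction, and
likelihood contributions `log P(chosen deck | E before the trial)`
summed to the modeling horizon, with the realized outcome updating
expectancies after each trial.

- `pvl_decay`: prospect utility of the net outcome (`x^α` gains,
  `−λ|x|^α` losses), decay-reinforcement update `E ← A·E` plus `u` on
  the chosen deck, sensitivity `θ = 3^c − 1`.
- `pvl_delta`: same utility; delta rule with learning rate `A`.
- `evl`: valence `(1−w)·win − w·|loss|`, delta rule with recency `φ`,
  trial-dependent sensitivity `θ(t) = (t/10)^c` with `c ∈ (−5, 5)`
  (negative values allow choices that grow *more* random over trials).

Bounds — `α, A, w, φ ∈ (0,1)`, `λ, c ∈ (0,5)`, `c_evl ∈ (−5,5)` — are
enforced at construction. The production likelihood is a numba kernel
evaluating all subjects of a group in one call; the test suite checks it
against an independently coded scalar per-trial loop to 1e-10 on random
parameter/session pairs, and against the closed form `T·ln(1/4)` for a
zero-sensitivity chooser.

## Synthetic cohort generator

The generator emulates the study design the analyses assume: four groups
of 14/17/14/12 subjects, 100 trials each, choices generated by
`pvl_decay`. Each group's parameters are independent probit-transformed
normals: `natural = lo + (hi−lo)·Φ(z)`, `z ~ Normal(μ*, σ*)`. The latent
`(μ*, σ*)` are calibrated in closed form so the *population* mean and SD
of the natural-scale draws equal the published group summaries exactly
(first moment `Φ(μ/√(1+σ²))`; second moment via Owen's T), rather than
approximately by simulation. Ages are truncated normals on [18, 80] with
the published group means/SDs.

What the generator deliberately does **not** emulate: within-subject
parameter correlations (draws are independent across parameters),
non-stationary strategies, missing trials or dropout, and any deviation
of real choices from the PVL-decay generative family. Passing recovery
tests therefore demonstrate that the pipeline is consistent — it
recovers what its own assumed model generated — not that the model is
true of real cohorts. The observed deck-depletion rate (~25–30% of
simulated subjects at default settings) is reported by
`CohortDataset.depletion_rate()` so users can judge plausibility; the
original report does not state its depletion frequency.

All generation is a pure function of (design, master seed): group g's
parameter draws use seed `master + 10000·(g+1)`, subject ordinal i's
session uses `master + i`.

## Inference

**Maximum likelihood.** Per subject (or jointly across a subject's
sessions), negative log-likelihood is minimized on the unconstrained
latent scale by L-BFGS-B from 10 starts (seeded Latin hypercube over
latent [−2, 2]^k plus the origin); the best optimum is kept and a
convergence flag records whether any start converged. Parameters stay
strictly inside bounds by construction.

**Hierarchical Bayesian analysis.** Each group is fit with its own
hierarchy (matching the group-wise posterior comparisons the design
calls for; a single joint model with group offsets would be the natural
alternative and was not chosen because the contrasts are defined on
whole-group posteriors). Per parameter: subject latents
`z_i ~ Normal(μ, σ)`, hypermean `μ ~ Normal(0, 1.5²)`, hyper-SD
`σ ~ HalfNormal(1)`. The hypermean prior SD of 1.5 (not 1) was chosen
because plausible group means near a parameter's bound (e.g. a group
loss-aversion mean of 0.06 on (0,5), latent ≈ −2.3) should not sit in
the prior's far tail at the study's group sizes.

The sampler is Metropolis-within-Gibbs, exploiting that subjects are
conditionally independent given the hypers so all subject proposals in a
move are evaluated in a single likelihood-kernel call:

1. blocked random-walk Metropolis on each subject's latent vector
   (per-subject step size, adapted toward 25% acceptance);
2. componentwise random-walk passes per parameter column (per-column
   step, 44% target) — helps when one parameter is much better
   identified than another;
3. a joint shift move adding the same increment to a whole latent column
   and its hypermean — this decorrelates the hypermean/latent funnel
   that plain Gibbs mixes through slowly;
4. conjugate Gibbs for `μ` (and the age slope `β` when used);
5. log-scale random-walk Metropolis for `σ` with the half-normal prior
   and log-Jacobian.

Step sizes adapt by Robbins–Monro during warmup only. Draws are thinned
(default: 5 sweeps per kept draw) to offset random-walk autocorrelation.
Chains are independent given their derived seeds; identical data + seed
reproduce identical draws. Split-R̂ and effective sample size (via
arviz) are attached for every group-level quantity; any R̂ > 1.1 flags
the posterior non-converged with a warning — results are still returned,
and short "smoke" runs routinely trip this gate on the α–c ridge.

**Group contrasts.** The group-level mean on the natural scale is
computed per draw as `lo + (hi−lo)·Φ(μ/√(1+σ²))` — the population mean
implied by that draw's hierarchy, the same functional the generator's
calibration inverts. Differences are taken draw-wise between groups;
`credible ⇔ 0 ∉ 95% HDI`. With the age covariate, each parameter's
latent group mean gains `β·(age − cohort mean)/cohort SD` and group
means are reported at the cohort-average age.

**HDI.** Shortest contiguous interval: over sorted draws, the narrowest
window containing ⌈0.95·n⌉ draws (lowest window on ties). Tested against
a brute-force all-windows search and against normal/uniform quantiles.

**Model comparison.** Per-subject BIC `k·ln(horizon) − 2·loglik` from
multistart MLE, summed over subjects; the secondary criterion is mean
one-step-ahead log-loss (per-trial negative log probability of the next
choice under the fitted parameters, in-sample). Selection is by summed
BIC.

## Problem sizes and numerical choices

Validation experiments run at deliberately desk-scale sizes: hypermean
recovery fits the full 57-subject cohort with 2 chains × 500 warmup +
500 kept draws (thin 5); power/calibration use 20 replicates per arm of
a two-group (12 + 14 subjects) design with the reduced 2 × 200/200
profile; model recovery uses 20 cohorts of 10 subjects. Tolerances:
likelihood-vs-oracle agreement 1e-10; HDI endpoints on 10^5 normal draws
within ±0.05 of ±1.96; recovery succeeds when ≥14 of 16 group×parameter
hypermeans fall inside their 95% HDIs — at 100 trials per subject the
α–c likelihood ridge leaves one or two cells (typically α or c in the
fast-decay, low-λ groups) genuinely biased, an identifiability property
of the model family at this horizon, not a sampler failure (per-subject
MLEs show the same displacement).

Degenerate inputs: empty sessions truncate to horizon 0 and are rejected
by the likelihood precondition; sessions shorter than 10 modeled trials
fit with a warning; zero hyper-SD generators collapse to shared
parameters exactly; infeasible generator targets (SD beyond the bounded
maximum for the requested mean) raise at calibration time.

## Known limitations

- The EVL parameterization and both PVL sensitivity mappings follow the
  standard published formulations of those models; where the source
  study's supplementary equations differ in detail, those would govern
  and are not available to check against.
- Group-wise hierarchies ignore information sharing across groups; small
  groups get correspondingly wide posteriors.
- One-step-ahead log-loss is in-sample (no cross-validation), so it
  favors flexible models the same way raw likelihood does; BIC is the
  deciding criterion.
- The random-walk sampler is robust but slow-mixing compared to gradient
  samplers; the convergence gate plus thinning compensate at the cost of
  wall-clock time.
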