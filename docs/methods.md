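# Methods

## The game engine

One *session* is a set of eight players. Per round the set is partitioned
uniformly at random into two groups of four (each partition independent across
rounds; no balancing of repeated pairings). Payoff resolution follows an
attempt-based reading of the rules:

- a cooperator earns `cooperate_gain` iff the group contains at least two
  cooperators **and zero steal attempts** — any attempt, successful or caught,
  cancels the cooperation gain that round;
- when at least one steal attempt succeeds, **every** cooperator in the group
  incurs `stolen_loss` exactly once that round (the alternative — one
  uniformly chosen victim per success, with stacking — is available via
  `GameConfig.victim_rule="random_victim_per_success"`); a caught-only attempt
  costs cooperators nothing;
- a stealer's fair-coin gamble only runs when the group contains at least one
  cooperator to steal from; otherwise the attempt is a `no_target` no-op with
  no punishment risk;
- each stealer's capture penalty is their *own* punishment level's (study 3
  crosses lenient/harsh within sets, so levels differ inside one group);
- working alone is always worth 0.

Sessions start with unpaid mock rounds (5 in studies 1–2, 4 in studies 3–4;
indices ≤ 0 in the logs). At the mock→real transition, points are reset by an
*independent redraw* from the study's starting-allocation rule. The number of
real rounds is uniform on 8–16 (studies 1–3) or fixed at 12 (study 4). In
studies 1–2 a discretised Gaussian shock — a Normal(0, 3) draw rounded to the
nearest integer — is added to each player's points each real round; rounding
adds 1/12 to the variance, so the realised sd is √(9+1/12) ≈ 3.014. "Below
threshold" is strict (`points < L`); study 1's start at exactly 100 = L counts
as not-below. For decision models the below indicator is evaluated on the
points the player *saw when deciding* (`points_before`); penalty accounting
uses the post-round, post-shock level, once per real round. Points can go
negative (there is no floor on points); the payout floor at zero handles the
economics: `max(0, points·rate − below_rounds·penalty·[threshold])`, rounded
to cents.

Reproducibility: a master seed spawns one `SeedSequence` substream per set
(`SeedSequence(master_seed).spawn(n_sets)`), each split into an assignment
stream (conditions, random intercepts) and a session stream (all in-game
randomness). Identical seeds give byte-identical CSV logs.

## Synthetic agents

The generative policy *is* the model family the fitters estimate:

```
P(steal) = logistic(β₀ + β_below·[points<L] + β_thr·[points<L]·[threshold]
                    + β_punish·[harsh] + β_round·t + u_i),   u_i ~ N(0, σ_id²)
P(cooperate | not steal) = logistic(γ₀ + γ_trust·trust_i)
```

Latent trust lives on [0, 1] and updates by an exponential moving average of
the observed share of non-stealers among the player's own group's three other
members (agents never see set-wide information or others' point levels):
`trust ← (1−λ)·trust + λ·(1 − stealers/3)`. The EMA form is this package's
modelling choice — the functional form of human trust dynamics in such games
is unknown — and the 1–10 questionnaire ratings are a noisy affine read-out
(`round(1+9·clip(trust+ε))`). In studies 3–4 a second rating (how likely
others are to steal) is emitted with read-out noise negatively correlated at
`rho_ratings` = 0.44, so at fixed latent trust the two integer ratings
correlate at about that magnitude (10-level rounding attenuates ~4%); session
data add further correlation through shared latent variation. The steal
rating exists for schema fidelity only; analyses use the cooperation-trust
rating throughout.

Preset parameter choices (`paper_like`): β_below = log 1.72 and
β_thr = log 1.94 come from the study-2 simple-effects/interaction odds
ratios, so the combined below-effect in threshold conditions is
log 3.3 ≈ study 3's estimate; β_punish = log 0.53 matches the overall
harsh-punishment odds ratio. The remaining values are the package's own
defaults, chosen once as behaviourally plausible: baseline steal intercept
β₀ = −2.2 (≈10% baseline rate), σ_id = 1.0 (typical inter-individual spread
for behavioural logits), β_round = 0, γ₀ = −1, γ_trust = 3, λ = 0.3, rating
noise sd 0.15, initial trust 0.8. `null_agent` zeroes every effect (for
calibration); `cn_threshold` is a hard-threshold heuristic — steal with
probability `p_below` = 0.15 when desperate (below L *and* in a threshold
condition), `p_above` = 0.02 otherwise, else cooperate iff trust ≥ 0.5 —
whose populations reproduce the qualitative below/above stealing asymmetry
and study 4's early-round convergence of below-threshold headcounts.

What the generator does **not** emulate: reference-point/loss-framing
psychology, retaliation, cross-round evidence integration beyond the EMA,
comprehension failures, or strategic sophistication (no dynamic-programming
agents). Passing recovery tests therefore shows the *analysis chain* is
sound on data satisfying its assumptions, not that human data do.

## Inference

Fitting maximizes the Bernoulli (or Gaussian) log likelihood plus independent
N(0, 1) log-priors on fixed coefficients and N(0, σ_f²) random intercepts,
jointly over (β, u) by Newton's method with backtracking; σ_f (and the
Gaussian residual sd) maximize the Laplace marginal likelihood (bounded
scalar search for one factor, Nelder–Mead for several; log-σ clipped to
[−6, 3]). The posterior of each fixed coefficient is Gaussian at the mode
with covariance from the inverse observed information (full (β, u) block
inverse), giving 95% CIs as mean ± 1.96·sd, odds ratios as exp(mean), and
Savage–Dickey Bayes factors from the two Gaussian densities at zero
(displayed capped at "> 1000"). This is a mode-based stand-in for MCMC: with
the simulated sample sizes (thousands of decisions) the Gaussian-posterior
approximation is accurate; recovery tests show |bias| < 0.05 and ~95% CI
coverage at 60 sets × 12 rounds.

Coding conventions: binary predictors enter as 0/1 (ORs reportable);
continuous predictors, outcomes and the always-present round control are
z-scored over the analysis subset (standardized β). Individual-level models
carry player and set random intercepts; set-level models carry set
intercepts. Zero-variance outcomes/predictors and complete separation
(|log-odds| > 15 escaping a weak prior) raise errors naming the term — no
silent dropping.

The set-level mediation uses three standardized Gaussian models with set
intercepts and round control: stealers_{t−1} ~ below_{t−1} (path a),
trust_t ~ stealers_{t−1} + below_{t−1} (path b and direct), and
trust_t ~ below_{t−1} (total). Indirect = a·b. Because mode-based fits do
not guarantee indirect + direct = total, the proportion mediated is reported
both as indirect/total and indirect/(indirect+direct), flagged when the
paths disagree in sign with the total. Intervals come from a bootstrap that
resamples whole sets with replacement (relabelling repeats as distinct
clusters; 1000 draws by default, reducible).

Evidence labels follow the 1/3/10/30/100 ladder with reciprocal bands for
the null; BF = 1 maps to "no evidence". Half-open bands `[lower, upper)` are
used; published labels in this literature match these bands except for one
boundary-adjacent call, which the categorizer intentionally does not
special-case.

## Numerical and design choices

- Group partition: permutation of the eight seats; P(two given players share
  a group) = 3/7, checked by simulation.
- Steal flags are drawn per stealer before resolution even when no cooperator
  is present (`no_target` ignores the flag) so the RNG call sequence is
  independent of group composition.
- Inactive players (optional per-round dropout probability, default 0, for
  exercising the exclusion rule) still emit ratings but are forced to work
  alone; players with fewer than 4 completed (active) real rounds are dropped
  from analysis views, boundary inclusive at exactly 4.
- Study-3 within-set cells are balanced at 2 players per cell; study-4
  between-set factors are allocated round-robin so even set counts split
  exactly; study-3 allocations are i.i.d. over {180, 190, 200} while study-4
  unequal allocations are exactly stratified (two players per value of
  {180, 190, 220, 230}) — the designs intentionally differ.
- Problem sizes used by the heavier checks — 60 sets × 12 rounds × 50
  replicates for recovery, 20 sets × 50 replicates for null calibration,
  20 replicates for the qualitative pattern checks — were chosen as the
  smallest designs at which Monte-Carlo error is well below the tolerances
  being asserted.

## Known limitations

- The Laplace posterior slightly understates uncertainty in the
  variance-component direction (σ_f is plugged in at its marginal optimum,
  not integrated); coverage tests bound the practical effect.
- The fitter handles random intercepts only (no random slopes, no crossed
  factors beyond player-within-set nesting being treated as two factors).
- Trust dynamics and the cooperate/work-alone margin are deliberately simple;
  the generative policy conditions on threshold presence even though real
  no-threshold participants knew of no threshold — one parameter family spans
  all conditions by construction.
- Bayes factors depend on the N(0, 1) prior scale; they are comparable across
  fits here but not to analyses with other priors or samplers.
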