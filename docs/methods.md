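# Methods

`entromatch` quantifies how animals (or simulated agents) respond locally to
reward in dynamic two-option choice tasks, and how that local behavior shapes
global matching. This note records the models, conventions, and design
choices behind the implementation.

## Data model

The unit of raw data is a long-format trial table: one row per trial with a
session id, a contiguous block id, a 1-based trial index, the chosen option
(`A`/`B`, or the literal `MISS` for no-response trials), a status
(`go`/`no_go`/`miss`), a 0/1 reward, and the block's base reward
probabilities for both options. The option with the larger base probability
is the block's *better* option. Miss and no-go rows are retained in files
for fidelity and removed only when strategy events or likelihoods are
derived, where they are treated as though the trial had not existed — an
event can therefore span a deleted trial.

A *strategy event* pairs two consecutive retained trials and records whether
the animal stayed or switched, whether the previous trial was a win or a
loss, and whether the previous (and current) choice was the better or worse
option of its own block. Because block switches are unsignalled, events
cross block boundaries by default: the event is assigned to the current
trial's block while the previous trial's option role is judged against the
previous trial's block. A `within_block_only` flag drops crossing events for
sensitivity analyses. The first trial of a session has no predecessor and
enters no event, so all event-based probabilities (including p(win) and
p(stay)) are frequencies over events, not trials; this convention is
explicit rather than an attempt to guess any particular lab's bookkeeping.

## Behavioral metrics

All metrics are computed per block from plug-in frequencies with no
smoothing. Deviation from matching is

    UM = (Choice_F − Reward_F) · sign(Reward_F − ½),   sign(0) = 1,

with the choice and reward fractions referenced to the block's better
option, so UM < 0 always means undermatching regardless of which side or
stimulus is better. The reward fraction (and hence UM) is undefined in a
block with no rewards.

Win-stay and lose-switch are the conditional frequencies P(stay|win) and
P(switch|lose) over a block's events. Repetition indices subtract the
chance stay probability of an i.i.d. chooser: RI_LR uses the marginal side
frequencies; the better/worse version is computed from joint event
frequencies, RI_B = P(better(t), better(t−1)) − P(better)², likewise RI_W,
with RI_BW defined as their sum. (The equivalent p(stay)-based form
coincides whenever option roles are stable across consecutive trials; for
events crossing a reversal a stay can map better→worse, and the joint form
keeps the decomposition exact.) Marginals for the chance terms are taken
over the events' current trials.

The entropy family conditions the stay/switch strategy on features of the
previous trial, in bits with 0·log₂0 ≡ 0:

* ERDS = H(str | win/lose),
* EODS = H(str | better/worse) (or left/right),
* ERODS = H(str | win/lose × better/worse).

Each decomposition component is the joint-probability-weighted entropy of
its conditioner cell, e.g. ERODS_W− = P(lose, worse)·H(str | lose, worse),
so defined components sum exactly to their parent. A component whose cell
contains no events — a block in which the animal never lost on the worse
option, say — is *undefined*, not zero, and is excluded from downstream
regressions; the parent remains defined from the nonempty cells. This
undefined-propagation rule is what produces the block exclusions in the
regression stage. Pairwise sums with an undefined addend (e.g. ERODS_W when
ERODS_W+ is empty) are undefined.

## Generative models

Nine trial-wise models share one interface. Values start at 0.5 (the
midpoint of the 0/1 reward range), memory traces at 0, at the start of each
session — and of each monkey superblock, since fresh stimuli appear there.
The per-trial order is fixed: the choice probability for trial *t* uses the
state entering the trial; after the outcome, the loss-memory update runs
first (its prediction error |R − Q_C| uses the chosen value *before* the
value update, since that value was the prediction), then the value update,
then the choice-memory update. State is *not* reset at mouse block switches
because those are unsignalled.

Update rules: the chosen value moves toward the reward with rate α_rew
(rewarded) or α_unrew (unrewarded); RL2 additionally decays the unchosen
value toward zero at `decay_rate` (RL1 leaves it untouched). The
choice-memory trace relaxes toward the indicator of the current choice at
rate γ. The loss-memory value is 0 after a win and −E_rpe after a loss,
where E_rpe tracks the expected unsigned reward-prediction error at rate γ;
its weight ω_LM therefore scales with expected uncertainty. Decision values
add ω_CM·C to both options and ω_LM·L to the previously chosen option only.
Choice is logistic in β(DV_A − DV_B) with β ∈ [0, 100]; ω_CM, ω_LM ∈
[−1, 1] (or [0, 1] in the sign-restricted `RL2+CM+` / `RL2+LM+` variants).
γ is a fitted parameter by default ("mouse-style") or tied to
mean(α_rew, α_unrew) ("monkey-style") via `gamma_mode`. A single γ is
shared by the CM and LM components.

The multiple-timescales model learns values in parallel at τ = 2, 20, 100
trials — each timescale identical to RL2 with α_rew = α_unrew = decay = 1/τ
— and chooses by the ratio rule DV_A/(DV_A+DV_B); the degenerate 0/0 case
returns ½. Its three mixing weights are fitted in [0, 1] and normalized to
sum to one, so they count as two free parameters.

Likelihood evaluation over a session runs through numba-compiled kernels for
speed; the public per-trial operations define the identical computation and
the two paths are tested to agree to 1e-12 per trial.

## Fitting and comparison

One parameter set is fitted per mouse session or monkey superblock by
multi-start bounded L-BFGS-B on the negative log likelihood (10 starts by
default, Latin-hypercube within bounds; starting β values are log-uniform in
[0.1, 10] because the likelihood is nearly flat in β at large values;
convergence ftol 1e-10). Only fitted parameters count toward p in
AIC = −2 logL + 2p: a tied γ and the fixed τ's do not, and the normalized
weight triple counts as two. Akaike weights apply the softmax of −ΔAIC/2 to
per-model mean AICs; McFadden R² compares pooled log likelihood to the
coin-flip null n·ln ½. When a model set is nested, each larger model is
additionally warm-started from the embedded optimum of its fitted submodels
(extra parameters at neutral values, the embedded point itself kept as a
candidate), which makes the nested-dominance property
logL(super) ≥ logL(sub) hold by construction up to optimizer tolerance.

## Task simulators

The mouse environment draws block lengths uniformly on [40, 80] trials (the
range covering the bulk of analyzed blocks; a wider range is configurable),
samples a schedule from {40/10, 40/5} and a better side at each switch —
rejecting an exact repeat of the previous assignment so every switch changes
the contingencies — and baits rewards: each unarmed side arms with its base
probability at trial start, an armed reward persists until that side is next
chosen, so P(armed after k unvisited trials) = 1 − (1−p)^k. 5% of trials
are no-go (the sampled response goes unrewarded) and ~0.9% are misses
(about 3.6 per 400-trial session); neither updates the agent nor consumes
bait. The monkey environment builds 80-trial superblocks with one reversal
at a trial drawn uniformly from {30,…,50}, schedules from {80/20, 70/30},
no baiting, and no miss/no-go trials; each superblock is emitted as its own
session. Environment and agent randomness come from separate streams
spawned from the master seed.

The heterogeneous-cohort generator draws per-unit RL2 parameters — learning
rates uniform on (0.02, 0.98), β log-uniform on [0.25, 40], decay fixed at
0.1 — spanning near-random to near-greedy agents, which produces wide
variation in both the entropy metrics and deviation from matching.

What the synthetic data do not emulate: inter-trial timing, side-bias block
adjustments, lick/saccade kinematics, the 16-schedule mouse variant or the
deterministic 100/0 monkey variant as defaults (both expressible through
the configuration). Passing tests on these cohorts demonstrate the internal
consistency and recoverability of the method, not properties of any real
dataset.

## Regression stage

Stepwise regression adds the candidate with the smallest partial-F p value
while p < 1e-4 and removes included terms whose p exceeds 1.1e-4 (worst
first), iterating to stability with a cap of 100 sweeps; blocks with any
undefined value among the candidates are dropped listwise beforehand. Main
effects only. Cross-validated prediction uses seeded shuffled 10-fold
splits of the complete cases with a plain linear model. Correlation
matrices report Pearson and Spearman coefficients on pairwise-complete
observations with a 1e-4 significance cutoff. Distributional comparisons of
observed vs model-simulated metric tables use the two-sided two-sample KS
statistic (asymptotic p by default, exact available for small samples).

## Problem sizes used in the checks

The packaged acceptance checks use 1,000 random event blocks of 10–500
events for the entropy oracle and conservation properties; 10 sessions of
~480 trials for parameter recovery (10 optimizer starts); 20 replicate
10-session cohorts for model-selection recovery (4 starts plus nested warm
starts); a 250-unit heterogeneous cohort (≥2,000 blocks) for the
metric–matching correlation; 10,000 Monte-Carlo repetitions for the
environment checks; and 200 replicates for the stepwise null-entry rate.

## Known limitations

* Probabilities are plug-in frequencies; short blocks give noisy, sometimes
  undefined metrics by design rather than being shrunk toward a prior.
* The optimizer is a local method with multiple starts; recovery is
  validated by simulation, not by any guarantee of the global optimum.
* The monkey simulator treats choice as stimulus-bound and does not model
  the random left/right placement of stimuli.
* No hierarchical pooling across sessions; each unit is fitted
  independently, as in the per-session analysis the package reproduces.
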