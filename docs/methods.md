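# Methods

## The model family

Choices are modeled as noisy value comparisons. On each trial the value of
cooperating is the sum of a stable intrinsic term, a reciprocity term, an
optional group-size term and a partner-prediction term:

    V_t^C = V_0^C + V_t^R + V_t^GS + V_t^P,      p(C) = logistic(τ V_t^C)

with defection's value fixed at 0 and the inverse temperature τ fixed to 1
(the two are not jointly identifiable with a free value scale). The
reciprocity term weights the subjective probability of the current
partner's previous choice:

    V_t^R  = V^RC p(P_i C) − V^RD p(P_i D)
    MR_t   = k^ID                      (memory retention)
    p(true previous choice) = 0.5 MR_t + 0.5

so the remembered choice's probability decays from certainty toward chance
(never below 0.5) as the interaction distance ID grows; forgetting is
F_t = 1 − k^ID. On first encounters both probabilities are 0.5. The
prediction term uses a delta rule per partner, initialized at 0.5 and
updated after every interaction with learning rate α; the estimate used on
a trial is the value available *before* the current outcome is observed.
`V^RC` is fixed to 1 (only the difference of reciprocity weights is
identified).

The 2×3 factorial model space crosses the group-size effect (absent,
present) with the memory regime (none k≡0, perfect k≡1, free decay):
M1–M6, with M3 = free decay without a group effect. Fixed-regime variants
are exact restrictions of the free-decay variant (asserted by tests), so
model comparison is a nested-model analysis.

A note on the choice rule's sign: the conventional softmax with negative
exponents would make larger cooperation value *less* likely to produce
cooperation, contradicting the model's semantics and the positive fitted
intrinsic values; the implementation uses p(C) = logistic(+τV), which is
the intended reading.

### Predictor standardization

Group size and the cooperation prediction enter the value function
standardized. Standardizing with per-session empirical moments cannot be
simulated forward (an agent cannot know its whole session's moments while
generating it), and any generator/fitter mismatch would bias parameter
recovery. Both generation and likelihood therefore use fixed reference
moments: group size (GS − 3.0)/1.4, matching the stationary group-size
distribution of the default environment, and prediction (pred − 0.5)/0.25,
its prior center and the approximate stationary SD of a delta-rule tracker
of Bernoulli outcomes at the fitted learning rate (√(α/(2−α))·0.5 ≈ 0.3
at α ≈ 0.57). Exactly one transform is used everywhere.

## Task environment

The simulator reproduces the task's generative structure: 180 trials per
session; newcomer trials at base probability 0.10 (forbidden twice in a
row, zero at the five-partner cap, halved after two consecutive participant
defections); switch opportunities at 0.20, independent of the defection
rule; uniform partner selection among active partners otherwise; a pause
slot followed by a forced newcomer when the group empties (the first trial
is a forced newcomer). Payoffs are 30 (mutual cooperation), 60
(defecting on a cooperator), −30 (cooperating with a defector), 0 (mutual
defection), accumulated across trials.

Partner agents are reconstructions — the published description is
qualitative — with cooperation probability

    P(C) = logistic( w_r (recip − 0.5) + w_m sin(2πt/22 + φ) + b )

where `recip` is a delta-rule estimate of the participant's cooperativeness
toward that partner (rate 0.5), the mood term has a 22-trial period with a
uniform per-partner phase, and the constants are calibrated: b = −0.3719
solves E[P(C)] = 0.418 over a uniform phase, reproducing the documented
58.2% defection rate of unconditioned partners on newcomer trials;
w_r = 8.0 and w_m = 1.0 make partners reciprocate sustained cooperation
while staying moody enough to be only partly predictable. Stay/switch
rules are logistic in the recent (last ≤3 interactions) defection count of
the other side — partners: logistic(−2.6 + 1.1·d) floored at 0.05;
the default participant rule: logistic(−3.8 + 1.1·d) — jointly calibrated
so link-break outflow roughly balances newcomer inflow: empirical newcomer
fractions land at 0.088–0.091, switch at ~0.20, and the group-size trace
spans 1..5 with mean ≈ 2.9. Partners whose link breaks are retired and
never reappear. Each session draws every random quantity from one seeded
generator, so sessions are bit-reproducible.

## Synthetic cohorts

Each simulated participant is the cognitive model itself acting as a
policy in the environment (one code path for generation, posterior
prediction and likelihood). True parameters are drawn from beta
distributions rescaled to the parameter ranges, with means at the
group-level posterior means of the winning model (V0C 1.366, VRD 3.481,
VP 2.536, k 0.638, α 0.567) and concentration 8, giving value-weight SDs
of ~2.4 native units and rate SDs of ~0.15. That heterogeneity matches the
study population's reported spread (cooperation SD 14% across
participants, about a quarter defect-dominant, occasional near-total
defectors) and is the scale the Gamma(1,1) hyperpriors of the fitted
hierarchy themselves expect — much tighter truth clusters are structurally
disfavoured by those hyperpriors (an Exp(1) density on each beta shape
puts its mass at concentrations near 2) and make fits drift toward a
degenerate boundary mode. The >95%-defection exclusion rule is applied as
a *flag* in the truth table, never as a silent drop.

What the generator does **not** emulate: human strategy heterogeneity
beyond the model family (grim triggers, always-defect heuristics,
theory-of-mind), reaction times, and the exact partner algorithm of the
deployed task script. Passing tests therefore certify the pipeline's
internal consistency (simulation → inference → evaluation), not fidelity
to any particular human dataset.

One emergent property deserves emphasis: in the fully closed-loop ecology,
participants with low prosocial baselines lose partners, so their
(defection-heavy) trials concentrate at small groups and short interaction
distances. Pooled cooperation consequently *rises* with ID even though
within cooperative participants the forgetting mechanism pulls mildly the
other way — a compositional confound of dynamic-group designs. Simulated
cohorts reproduce the documented group-size effects (cooperation rising,
reciprocity falling) and the reciprocity-distance decline, but not the
negative marginal cooperation-distance association seen in the original
human data.

## Hierarchical inference

Participant-level parameters live on a raw (0,1) scale with Beta(α_p, β_p)
group priors, Gamma(1,1) hyperpriors on both shapes, and the affine map
p = p_raw(UB − LB) + LB to native ranges: V0C, VRD ∈ (−10,10), VGS, VP ∈
(−5,5), k, α ∈ (0,1). The group mean is μ_p = α_p/(α_p+β_p)·(UB−LB)+LB.

No gradient-based PPL is part of the dependency set, so the sampler is
implemented here. Per sweep:

1. **Participant block** — Hamiltonian updates in logit-raw space with
   analytic gradients from a compiled kernel (the delta-rule recursion is
   differentiated by forward accumulation). Trajectories use 12–24
   leapfrog steps through a per-participant Cholesky preconditioner
   estimated from warmup samples; acceptance is per participant (their
   conditionals are independent given the hypers), step sizes adapt toward
   0.85 acceptance during warmup only.
2. **Prior-independence proposals** — fresh raws drawn from the current
   Beta(α_p, β_p); prior and proposal cancel, so weakly informed
   participants (whose conditional posterior follows a possibly bimodal
   U-shaped beta) can jump between modes.
3. **Hyper moves** — repeated Metropolis updates of each (α_p, β_p) pair
   on the log scale, as mean-preserving and concentration-preserving
   moves.
4. **Group translation moves** — every participant shifted by one common
   vector drawn from the adapted covariance of the population-mean
   trajectory, with occasional 3×-scale proposals. These target the
   slowest mode: the population sliding coherently along the weakly
   identified (V0C, VRD, k) ridge, where a larger anti-reciprocity weight
   with faster decay and a higher baseline mimics the same short-distance
   behavior contrast.

Convergence is monitored with split R-hat (threshold 1.04); a failed fit
is automatically refit once with doubled draws and then carries a hard
warning — never silenced. Model fit uses PSIS-LOO (via arviz, with
per-observation Pareto-k counts above 0.7 reported) and WAIC computed from
its defining formula (sample-variance penalty), both on the deviance
(−2·elpd) scale so that lower is better. HDIs are the narrowest contiguous
interval at the requested mass, ties broken toward the lower bound. The
comparison table reports deltas to the best model and flags deltas beyond
the 8-point visualization threshold (a plotting convention, not a decision
rule). Numerical guards: logit-space positions clipped at ±35, stable
log-logistic likelihood, probabilities clipped 1e-12 from the boundaries.

### Problem sizes used by the shipped checks

Desk-scale schedules keep the full pipeline on one CPU: model comparison
fits all six variants to a 20-participant × 180-trial cohort with 2 chains
× 1000–1200 draws (half warmup); the recovery study runs three
simulations of 12 participants × 180 trials with 4 chains × 3000–3500
draws. The default `fit_model` schedule remains 4 chains × 2000 draws
with 1000 warmup. The full study-scale design (83 × 180) generates in seconds;
only the MCMC budget is scaled down, and the recovery report records its
scale.

### Known limitations

Two channels of the value function can carry the same signal: the
reciprocity term responds to the partner's previous choice weighted by
memory retention, while the prediction term tracks the partner's choice
history as a cached delta-rule average with no distance dependence. At
high learning rates the cached average approximates "the partner's last
choice", so a perfect-memory reciprocity channel (k = 1) is nearly
indistinguishable from an inflated prediction weight with k ≈ 0. The
decay signature — dependence on interaction distance — is what separates
the channels, and it exists only for 0 < k < 1. Consequently fits of the
free-decay variant to *perfect-memory* synthetic data may place k near 0
with a larger VP rather than near 1; identification of the forgetting
variant on forgetting-model data is unaffected. Checks of the
perfect-memory restriction therefore use cohorts where the channels
separate, and treat the k-location as cohort-dependent.

The (V0C, VRD, k) ridge makes the posterior weakly bimodal at desk scale:
per-participant likelihoods gain ~2.5 nats by sliding toward the VRD bound
(quasi-separation of near-deterministic post-defection behavior), and the
U-shaped tails of low-concentration beta priors make that region cheap.
Well-mixed fits spread honestly over both basins (wide HDIs that cover the
truth); under-sampled fits can sit in one basin with R-hat between 1.05
and 1.2, which split R-hat does not always flag. The recovery study
reports convergence per simulation; at the shipped schedule 90% HDIs cover
the generating group means at ~80% (12/15 intervals, statistically
compatible with the nominal rate), with the anti-reciprocity weight VRD
the most biased coordinate. Group-level conclusions of the model
comparison (the forgetting variant winning by LOOIC) are robust to this;
point estimates of VRD at small cohort sizes should be treated with
caution.

## Evaluation

Behavioral curves pool trials per group-size or distance bin with
nonparametric bootstrap (1000 resamples over participants) 95% bands;
reciprocity (repeating the partner's previous choice) is undefined, and
excluded, on first encounters. Posterior predictive checks report the
per-participant Pearson correlation between trial-wise predicted
cooperation probabilities (posterior-mean parameters) and 0/1 choices
(missing for constant choice sequences), plus cohort-level
cooperation/reciprocity ribbons from fresh sessions simulated at posterior
draws through the same environment code path. Mixed models delegate to
lme4/lmerTest through Rscript — logit links with per-participant random
slopes for the binary outcomes, identity links with random intercepts for
response-time structures (which require the caller to supply an `rt`
column; the simulator does not generate response times) — simplifying to
random intercepts on non-convergence or singular fits, as flagged in the
returned table.
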