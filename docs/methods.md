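# Methods

This note documents the models, the synthetic-data generator, the sampler and
the numerical choices behind `rlexpect`, and what the test suite does and
does not establish about real data.

## Task model

The probabilistic selection task presents three fixed pairs of stimuli with
complementary Bernoulli reward probabilities (80:20, 70:30, 60:40), 40 trials
per pair, 120 trials per participant. The schedule is a uniform random
permutation of the 120 (pair, position) slots, with each stimulus shown on
the left in exactly half of its pair's trials. "Optimal" always refers to
the stimulus with the higher *true* reward probability, not to empirical
reward frequency. Response-window and feedback durations are carried as
metadata only; no timing is simulated. Run-length constraints on the trial
order (e.g. capping repeats of one pair) are not imposed — nothing in the
task definition requires them, so a plain permutation is used.

## Model families

All families share the dual-rate Rescorla–Wagner core on stimulus values
`Q ∈ [0,1]` with rewards `r ∈ {0,1}`; only the chosen stimulus's value is
updated, by `α_gain` for positive and `α_loss` for negative prediction
errors. Initial values are 0 for every family (the extended model's decay
explicitly targets 0; for the plain dual-rate families 0 is adopted for
consistency across the family — the `AgentState` start is a single,
configurable site in the likelihood core, and with equal starting values the
first choice of every pair is at chance either way).

| family | parameters | response rule |
|---|---|---|
| `SWo`/`SSo` | α_gain, α_loss ∈ [0,1]; β ≥ 0 | softmax(Q/β), *inverse gain* |
| `SSh`/`SWh` | α_gain, α_loss ∈ [0,1]; β ∈ [0,20] | softmax(Q·β), *inverse temperature* |
| `ES` | + φ, ξ, Q₀ ∈ [0,1] | (1−ξ)·softmax(Q·β) + ξ/2 |
| `RLfCK` | α, φ, α_CK ∈ [0,1]; β ∈ [0,20]; τ ∈ [−5,5] | softmax(Q·β + CK·τ) |

The two dual-rate conventions agree exactly when β_temp = 1/β_gain (tested).
Larger inverse gain means noisier choice; larger inverse temperature means
more deterministic choice.

Per-trial operation order (the within-trial order is a modelling choice;
update-then-decay is used): (1) choice probability from the current state,
(2) reward observed, (3) `ES` only — on a pair's first trial the chosen
stimulus's value is set to the initial bias Q₀ *after* the choice (the first
choice is made from equal zero values) and *before* the reward update,
(4) Rescorla–Wagner update of the chosen stimulus, (5) forgetting decay
`Q ← (1−φ)·Q` of all six values (`ES`, `RLfCK`), (6) choice-kernel update of
the presented pair: chosen toward 1, unchosen toward 0, both by α_CK
(`RLfCK`; kernel values are not decayed).

Numerical choices: two-option softmax probabilities are computed through the
stable log-logistic `−log(1 + e^{−z})`; under the inverse-gain rule β is
clamped at 1e−6 from below and an exact value tie returns exactly 0.5 before
any division. Choice simulation draws a uniform threshold per trial; an
*exact* probability tie (both options at 0.5) is resolved by a fair coin —
tie detection uses exact equality, not a tolerance band. Trials without a
response are dropped from both the likelihood and the state updates, which
keeps the likelihood well defined without imputing choices.

## Synthetic cohorts

The generator emulates the study design: subjects are assigned i.i.d.
uniformly to the five purported-efficacy groups (0/25/50/75/100%), so group
sizes are unbalanced exactly as a client-side randomizer leaves them.
Subject parameters are drawn on the unconstrained scale around
`μ_θ0 + δ_θj` with spread `σ_θ`, then mapped through the family's
transforms. Three presets encode the competing hypotheses on the gain
learning rate (the single update rate for `RLfCK`):

* `null` — all offsets zero;
* `monotonic` — offsets (0, 0.2, 0.4, 0.6, 0.8) strictly increasing;
* `inverted_u` — offsets (0, 0.4, 0.8, 0.4, 0) peaking at the 50% group.

The peak magnitude 0.8 on the unconstrained scale matches the size of the
large pairwise standardized effects such designs aim to detect (d ≈ 0.8);
it is configurable (`peak_delta`). The within-group spread defaults to
σ = 0.5 for every parameter: large enough for clear individual differences
(baseline gain rates roughly 0.2–0.4 at ±1σ), small enough that group
effects of the stated size remain detectable at realistic sample sizes.
Baseline means put constrained values in the range typically estimated for
this task family (gain rate ≈ 0.3, loss rate ≈ 0.1, inverse gain ≈ 0.15,
inverse temperature ≈ 4, mild forgetting and noise).

What the generator does **not** emulate: reaction-time structure (optional
RTs are log-normal decorations so RT code paths run; they carry no model
content), attention lapses or non-stationary strategies, questionnaire
responses, and the response noisiness of human participants — synthetic
agents follow their generating model exactly, so point-parameter model
accuracy on synthetic cohorts (≈ 0.9 at the default inverse gain) is much
higher than the ≈ 0.6–0.65 typical of human data. Passing recovery tests
therefore show that the estimation machinery works when the model is true,
not that the model is true of people.

## Hierarchical inference

Unconstrained subject parameters are modelled as
`x_s ~ Normal(μ_θ0 + δ_θj, σ_θ)` componentwise, with the baseline group's
offset fixed at zero and offsets applied to *every* model parameter.
Subject-level parameters are independent normals per parameter (no
correlation structure). Two prior variants (normals parameterized by
standard deviation):

* **wide**: μ ~ Normal(0, 100), σ ~ Uniform(0, 100), δ ~ Normal(0, 3);
* **narrow**: μ ~ Normal(0, 1), σ ~ half-Normal(0, 0.2), δ ~ Normal(0, 3)
  (a normal prior on a positive spread is necessarily its positive half; the
  δ prior is left unchanged because the narrowing concerns μ and σ).

Bounded parameters use scaled-logit transforms `lo + (hi−lo)·logistic(x)`;
learning-rate-like parameters use the plain logit and the inverse gain the
log transform.

Sampling is Metropolis-within-Gibbs, a valid MCMC scheme targeting the same
joint density `log_joint` exposes:

* μ and each δ have conjugate normal full conditionals given the subject
  values and σ — exact Gibbs draws;
* each σ is updated by univariate slice sampling (stepping-out) on log σ
  with the Jacobian term included;
* the subject-level block is refreshed `n_subject_refresh` (default 10)
  times per retained sweep with a vectorized joint random-walk Metropolis
  proposal per subject; per-subject proposal scales adapt toward 35%
  acceptance during warmup only, so the post-warmup chain is Markov with the
  correct invariant distribution. Hyperparameter updates are interleaved
  with every subject refresh — they are cheap relative to a likelihood pass
  and the interleaving decorrelates the retained group-level draws.

Configurations: the full-scale preset runs 8 chains × 10,000 warmup +
10,000 sampling iterations (80,000 retained group-level draws); the test
preset (4 × 500/500) is the default for continuous integration and examples.
`target_accept` (0.99) and `max_tree_depth` (15) are carried as metadata —
they parameterize tree-based gradient samplers and are recorded for
comparability, while this sampler's own adaptation targets
`mh_target_accept`. Chains are seeded from a spawned `SeedSequence`, making
every fit bit-reproducible. Split R-hat and bulk ESS (via ArviZ) are computed
for all group-level parameters; any R-hat above 1.1 is flagged in the draw
metadata and warned about, never silently dropped.

Subject point estimates: the *unconstrained* posterior mean is the canonical
scale (it is what group comparisons and trend regressions use); on the
constrained scale both the transform-of-mean (canonical) and mean-of-
transform are exposed, since the two differ under nonlinear transforms and
downstream uses disagree on which they want.

The per-subject maximum-likelihood path (`fit_mle`) optimizes the sequence
likelihood on the unconstrained scale by multi-start Nelder–Mead (origin
plus random starts); it exists for recovery studies and tests, not as a
replacement for the hierarchy.

## Posterior hypothesis statistics

Pattern fractions count the posterior draws in which the five group-level
means `μ + δ_j` satisfy a *strict* inequality chain — ties fail, exactly as
written: monotonic `μ(0)<μ(25)<μ(50)<μ(75)<μ(100)`; inverted-U
`μ(0)<μ(25)<μ(50)>μ(75)>μ(100)`; and three-group variants omitting the 25%
and 75% conditions. The two five-group patterns are mutually exclusive per
draw (they disagree about μ(50) vs μ(75)).

Pairwise contrasts `μ_j − μ_k` are summarized by the posterior mean, the
equal-tailed 95% credible interval, the probability of direction
`pd = max(P(d>0), P(d<0))`, practical significance `ps` — the posterior mass
beyond the ROPE boundary in the direction of the median — and the percentage
of draws inside the ROPE [−0.1, 0.1] on the unconstrained scale. A
degenerate all-zero difference reports pd as missing with a warning rather
than an arbitrary 0.5.

The trend regression codes groups as centered values (−50…50) and compares a
linear-only OLS fit against linear+quadratic, reporting both R² values and
ΔR². The BIC Bayes factor defaults to `BF₁₀ = exp((BIC₀ − BIC₁)/2)` so that
values above 1 favor the alternative; the opposite orientation is available
as an explicit option for comparison with reports that print it that way.

## Model evaluation

*Model accuracy* is the mean likelihood the model assigns to the observed
choices at subject point parameters (posterior means); a draw-averaged
variant is available through the pointwise likelihood matrix, but the
point-parameter version is canonical. *Posterior predictive* simulation
re-runs every subject 20 times (configurable) on fresh schedules and reports
per within-pair trial index the mean optimal-choice rate. *PSIS-LOO* treats
the single trial as the observation unit, builds the draws × trials log
likelihood matrix from the retained subject-level draws, and delegates the
Pareto-smoothed importance sampling to ArviZ; `looic = −2·elpd_loo` by
construction, observations with Pareto k > 0.7 are counted and warned about.
*Parameter recovery* simulates agents from known parameters (cohort-sized,
120 trials), refits by MLE (default) or the full hierarchy, and reports the
Spearman rank correlation per parameter; a constant true parameter yields a
missing correlation rather than a spurious number.

With 120 trials per subject the loss learning rate is weakly identified —
its recovery correlations are routinely near zero while α_gain and β recover
clearly; this is a property of the design, not a defect of the fitter.

## Behavioral summaries

Stay probability is the fraction of within-pair windows of three consecutive
presentations whose first two choices agree and whose third repeats them;
windows are overlapping, never span pairs, and are broken by non-responses.
Cumulative curves are per-subject running means by within-pair trial index
with cross-subject mean and standard error. Sliding-window correlations move
a 20-trial window in steps of 1 over the subject-global trial order (the
first window, labeled 20, covers trials 1–20) and correlate a per-subject
statistic with the windowed behavioral mean across subjects, with an
uncorrected Fisher-z 95% interval; zero-variance windows are missing. The
exclusion rule removes subjects whose response count falls below the sample
mean minus three sample (n−1) standard deviations.

## Problem sizes used in the checks

The test suite runs the estimation studies at deliberate desk scale: exact
likelihood coherence by full enumeration of 2⁸ choice sequences (all four
families, ten random parameter sets each); MLE recovery with 50 agents × 120
trials; hierarchical recovery with a 30-subject inverted-U cohort under the
test sampler preset; LOOIC model selection between `RLfCK` and the dual-rate
model on a 12-subject strong-kernel cohort; PSIS-LOO validated against exact
leave-one-out refits of an enumerable grid-posterior Bernoulli toy.

## Known limitations

* The sampler is gradient-free; at full scale (8 × 10,000/10,000, n > 100)
  it is substantially slower than a tuned tree-based gradient sampler and
  the test preset is the intended day-to-day configuration.
* No within-subject parameter correlations and no covariates beyond the
  group factor.
* Reaction times are carried as metadata; there is no generative RT model.
* Strict five-way pattern fractions are conservative by construction: even
  under a true inverted-U, posterior uncertainty makes a full strict chain a
  demanding event, so fractions well below 1 are expected and comparisons
  between patterns matter more than absolute levels.
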