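# Methods

This note documents the models and procedures implemented in `hntwin`, the
defaults that matter, and what the synthetic study conditions do and do not
establish about real clinical data.

## The feature registry

Patients are described by 45 variables in five groups that structure a
single treatment cycle:

- **PTF** (pre-treatment, 20 variables): age; gender; ethnicity; race;
  smoking status and three smoking-quantity covariates; tumor site;
  AJCC version; p16/HPV status; laterality; T, N, M stage; enrollment
  status; four baseline MDASI-HN symptom scores.
- **ACTIONS** (3): definitive surgery (no/yes), induction chemotherapy
  (no/yes), radiotherapy (no / yes / yes-with-concurrent-chemotherapy).
- **PIO** (5): extranodal extension (ENE) and surgical margin — observed
  only after surgery; radiotherapy type, total dose, and fraction count —
  observed only when radiotherapy is given.
- **PRS** (16): fatigue, drymouth, swallow, taste at end of RT, week 6,
  month 3, month 12; integer 0–10 scores.
- **TPO** (1): relapse within three years (binary, largely unlabeled).

Two registry column names are kept verbatim although misspelled
(`status_at_enrollememt`, `p16_hpv_postive`) so the published tables remain
traceable; a clean-alias map is available at I/O.  Smoking-status codes
(1, 2, 4, 5, 7, 9, 10) are opaque categorical labels — the source table
prints them without a legend, and no ordinal meaning is assumed.

## Timeline reduction

Raw histories are day-stamped logs of actions and status assessments.
Treatment is segmented into cycles closed by a relapse/recurrence status.
Within a cycle, a chemotherapy and a radiation action at most
`merge_window_days` apart (default 45) merge into one concurrent
chemoradiotherapy action; chemotherapy further ahead of radiation counts as
induction.  The 45-day default separates the observed concurrent pairs
(~5 days apart) from distinct courses (months apart) with a wide margin and
is configurable.

A multi-cycle history reduces to the first-cycle action triple plus a
year-3 outcome: `relapse_yr3` is true iff a relapse occurs within
`horizon_days` (default 1095), false when follow-up reaches the horizon
without one, and missing when follow-up is too short to tell.  The year-3
*status* label is the assessment nearest the horizon within a ±90-day grace
window (observed "year-3" assessments can fall slightly past day 1095),
falling back to the latest pre-horizon status.  A patient can therefore
carry `relapse_yr3 = true` with a year-3 status of no-evidence-of-disease if
salvage therapy intervened — both facts are kept.

## Synthetic-cohort generator

The registry itself is private, so study conditions are emulated by a
generator whose parameters are read off the published tables: categorical
probabilities are printed counts over 676; numerical marginals are printed
(mean, SD); the first-cycle action triple follows the printed
eight-pattern frequency table (total 651).  Where the tables are silent the
defaults are documented package constants: swallow/taste score marginals
(chosen to resemble the printed fatigue/drymouth trajectories — a toxicity
spike at end of RT with partial recovery) and all planted effect sizes.

Design choices worth knowing:

- **Bounded scores.**  Symptom scores are clip-and-round Gaussians on the
  integer 0–10 grid.  Raw clipping biases low-mean scores upward (≈ +0.38
  for a mean-1.08, SD-2.02 score), so the pre-clip location is root-solved
  (Brent, on the exact Gaussian cell probabilities) so the post-clip-round
  mean equals the printed mean.  The post-clip SD is consequently slightly
  below the printed SD; means, not SDs, are the recovery targets.  The same
  correction is applied to the lower-bounded smoking covariates, which
  yields a realistic point mass at zero (never-smokers).
- **Planted dependencies.**  Downstream predictors need learnable signal,
  so dependencies are planted with Gaussian-copula couplings that preserve
  every printed marginal *exactly*: each categorical draw thresholds a
  standard-normal latent, and correlation enters by sharing latents.
  Actions are sampled hierarchically — surgery given T stage, induction
  given N stage (only without surgery), radiotherapy class given age with
  cell-conditional probabilities from the printed joint — so the printed
  pattern distribution is reproduced exactly while each action remains
  predictable from the pre-treatment profile.  ENE/margin couple to N
  stage, radiotherapy type to age, dose/fractions shift with concurrent
  chemotherapy (mean-centered, so marginals are unchanged).
- **Symptoms and relapse.**  Each patient carries a latent symptom
  propensity `u ~ N(0,1)` loading on every score with correlation 0.60
  (within-patient symptom correlation, the persistence real MDASI data
  shows), plus a treatment-intensity effect (points per unit intensity:
  1.5 / 1.1 / 0.8 / 0.5 at end-RT / wk6 / m3 / m12), centered at the
  population-mean intensity so marginals are untouched.  Treatment
  intensity is 0.5·surgery + 0.7·induction + {0, 1, 1.5} for the
  radiotherapy class.  Relapse is Bernoulli-logistic in centered intensity
  (log-odds −1.2 per SD — aggressive treatment lowers relapse), age (+0.3),
  and propensity (+0.5); the base log-odds is calibrated (Gauss–Hermite over
  the covariate distribution) so the labeled marginal equals the printed
  35/188.  Only a random 188/676 of patients carry a relapse label; symptom
  scores are missing completely at random at rate 0.05.
- **Effect-size defaults are package constants, not registry estimates.**
  They were chosen so the boosted chain beats the rule-based baselines
  detectably at the registry sample size (n = 676); they encode plausible
  clinical directions but no published effect magnitudes.

The planted truth (assigned pattern, intensity, propensity, true relapse
probability) is returned alongside every generated cohort to support
parameter-recovery tests.

What the generator does *not* emulate: inter-feature correlation among
pre-treatment variables (they are mutually independent, matching the
generator-side independence assumption of the VAE), informative missingness,
multi-cycle histories, time-to-event outcomes, and the full 28-item symptom
inventory.  Tests passing on this cohort therefore demonstrate that the
pipeline recovers known structure at realistic scale and noise — not that
it would achieve any particular accuracy on real registry data.

## Preprocessing

Z-scoring uses the population (divide-by-n) SD convention and is fitted on
training data only; constant columns pass through flagged.  Imputation is
family-specific: VAE/MLP inputs get train-mean (numerical) and
most-frequent-training-category (categorical) fills — the "median" of a
nominal variable is read as the mode, since nominal labels have no order —
while boosted trees receive missing values natively.  The split defaults to
the literal 539/137 partition (0.2 × 676 = 135.2, so a rounded 80/20 would
not reproduce the printed sizes).

## VAE

Encoder 64–64 ReLU with 16-dimensional mean/log-variance heads; decoder
mirrors the encoder with one linear head for the numerical block and one
softmax head per categorical feature; categorical inputs are one-hot.
Adam, learning rate 0.001, batch size 64.  The latent is drawn with the
reparameterization trick.  Losses are averaged over the batch and summed
over features; `kl_weight` scales the KL term under this convention
(default 1).  The reference epoch budget is 10,000; the package default is
300, which at this width and n = 676 reaches a stable loss plateau in
seconds — the desk-scale budget is a deliberate default, raisable via
`VaeConfig(epochs=...)`.  Sampling decodes `z ~ N(0, I)`; categorical heads
are sampled from the decoder probabilities (argmax available), numerical
outputs are denormalized and clipped to schema bounds.  The whole model is
NumPy with a hand-written backward pass (verified against finite
differences in the test suite) — at tabular scale no GPU framework is
needed.

## Predictor chain

Stage order is chronological; year-3 relapse is the final node even though
the published benchmark lists it mid-table, because it is the only variable
measured after month 12.  Every node conditions on all features of earlier
stages (the all-ancestors convention; the per-node conditioning sets of the
source diagrams are not published).  Classification nodes use
`binary:logistic` / `multi:softmax` objectives with balanced sample weights
(weight ∝ n / (k · class count), recomputed inside each CV training fold);
regression nodes use squared error on z-scored targets and report
denormalized predictions.  Grid search is 3-fold (stratified for
classification), scored by macro-F1 / negative MSE, ties broken toward
fewer trees then shallower depth; the full published ranges sit behind
`full_grid()`, and the default `fast_grid()` takes one value per
hyperparameter from the most regularized corner (learning rate 0.1, depth
4, min child weight 5, 100 trees, column subsample 0.5).  A target with a
single observed class yields a constant predictor with a warning.

Rollouts fill downstream features in chain order under a fixed action
triple, honoring structural rules (no pathology without surgery, no
radiotherapy parameters without radiotherapy).  Expected mode takes class
argmax / regression mean; sampled mode draws classes from predicted
probabilities and adds Gaussian noise at the node's training-residual SD
(no stochastic mechanism is prescribed by the reference design; this is the
package's choice), clipped to bounds.

Baselines: median/mean (categorical → lower median of schema-order integer
codes, a deterministic but admittedly arbitrary reduction for nominal
variables; numerical → train mean), random (draws proportional to training
frequencies / from the empirical distribution), and grid-searched sklearn
MLPs on imputed, one-hot, z-scored inputs.

## Evaluation

Generative fidelity: per-feature order-1 Wasserstein distance on raw
(denormalized) numerical values and total-variation distance for
categorical features (their Wasserstein distance under the 0/1 ground
metric — plain W1 is undefined for nominal labels), averaged over features.
Predictive: macro-F1 averaged over the *schema-declared* classes, so rare
classes absent from a test split count as zero — deliberate under heavy
class imbalance — and MSE on the denormalized scale, which preserves the
natural magnitudes (radiotherapy dose errors in the tens of thousands of
cGy²).  Wasserstein and macro-F1 are cross-checked in the tests against an
exhaustive linear-programming transport oracle and hand-computed cases.

## Decision environment

Three steps with discrete action spaces (2, 2, 3): surgery, induction,
radiotherapy class.  `reset(seed)` decodes one synthetic profile from the
trained VAE; intermediate steps append the action and fill
stage-appropriate predicted outcomes (pathology after surgery) so later
decisions can be state-dependent; the final step runs the full rollout.
Observations are the currently observed portion of the record (a named
series; PTF only at reset).  No canonical clinical reward exists, so the
default is a configurable construct:
`−relapse_weight · P(relapse) − symptom_weight · mean(end-RT burden)/10`,
with both weights 1.  Paired plan comparison replays identical episode
seeds under both plans, so patient sampling variance cancels and the
difference isolates the treatment effect.

## Numerical and testing notes

- Determinism: every stochastic routine takes an explicit seed; identical
  (parameters, n, seed) give bit-identical cohorts; VAE training and chain
  fitting are seed-reproducible (single-threaded XGBoost `hist`).
- Degenerate inputs: empty cohorts round-trip; one-hot sequence
  distributions produce constant draws; all-missing columns are hard
  errors for the normalizer; unknown columns, action labels, and category
  labels fail loudly with the offending name.
- Problem sizes in the test suite: cohorts of 676 (registry scale) for
  model fits, 10,000–40,000 draws for marginal-recovery checks, 300 VAE
  epochs, the one-point fast grid — sizes at which the full suite runs in
  about a minute while keeping every statistical check well-powered.
- One published demographic row (N-stage "n1", 446 with "65.7%") is
  internally inconsistent (446/676 = 66.0%); counts, not printed
  percentages, are treated as the source of truth.

## Known limitations

The chain is a sequence of conditional predictors, not a causal model: plan
comparisons are model rollouts under planted synthetic structure, not
counterfactual claims about patients.  The single-cycle reduction discards
salvage-therapy dynamics.  The environment reward is a stand-in for
whatever clinical utility a user actually intends.  Margin prediction rests
on ~60 observed training rows across seven classes and is correspondingly
fragile; the fraction-count node has almost no planted signal and the mean
baseline occasionally wins it.
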