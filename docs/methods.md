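# Methods

## Movement events from presence-only data

The unit of analysis is the gap between two consecutive detections of one
tagged individual. Gaps at the same receiver are recursions; gaps between
receivers are transitions. Extraction is per individual — detections of
different tags never combine — and an individual with fewer than two
detections contributes nothing. Pairs with non-positive gaps (clock
collisions across receivers) are dropped with a warning: a zero gap has
no defined RDET and no log-duration, and the tie carries no movement
information.

Inter-receiver distances are great-circle (haversine, R = 6 371 000 m) on
the mooring coordinates, ignoring depth and land/water routing; at
atoll scales (receivers 0.55–4.57 km apart) the geodesic is an adequate
proxy for the swimming path, and any systematic under-estimate of true
path length is absorbed by the conservative RDET threshold.

Filters, both strict inequalities exactly as stated by their defaults:

* recursions with gap < 360 s are removed — below the tag repeat rate a
  "return" is indistinguishable from a missed ping;
* transitions with RDET > 5 are removed — five times the sustainable
  swim speed indicates a false detection, not a movement.

The two filters act on disjoint subsets, so they commute and are
idempotent; both bounds are config keys.

## Threshold derivation

For each species, retained recursion gaps (minutes) and retained RDET
values are natural-log-transformed and split into k = 2 contiguous
classes by Fisher's optimal partitioning: an exact dynamic program over
the sorted values minimising the total within-class sum of squared
deviations from class means (the "fisher" style of the classInt
tradition; a brute-force enumeration over all contiguous 2-partitions is
the test oracle). The break is reported as the maximum value of the lower
class and back-transformed to the original scale. Because a monotone
transform of the values preserves contiguous partitions, the choice of
log base does not change which data point is the break.

Labelling: recursion out-of-range iff gap > θ_rec; transition
out-of-range iff RDET < θ_rdet; equality goes to restricted. The rule is
monotone in both directions. Thresholds are computed per species on the
full filtered data set before the cross-validation split — the
classification stage precedes, and is independent of, model validation.

## Model table

Each labelled movement carries species, sex, log total length (cm, natural
log), diel period and season, plus the two grouping factors. Diel/season
derive from the movement's **start** instant (departure is when the
behavioural decision happens; `anchor` switches to arrival) in the local
zone (default UTC+06:00): day is [07:00, 19:00) local, wet season is
October–March. The receiver grouping factor is the **destination**
receiver (`receiver_role` switches to origin); for recursions the two
coincide. Rows lacking sex or size are dropped with a logged count.

## The mixed model

Binomial GLMM, logit link, crossed (independent) random intercepts for
individual and receiver. Estimation is maximum likelihood under the
Laplace approximation: for a candidate pair of log-SDs, a penalized
Newton iteration (step-halving line search) finds the joint mode of
(β, u); the profiled objective

  ll(σ) = pen_ll(β̂, û) − ½ Σ_f q_f log σ_f² − ½ log det(H_uu)

is maximised over the two log-SDs by Nelder–Mead (xatol 1e-3, fatol
1e-6, warm-started across candidates from the global fit). H_uu is the
u-block of the penalized Hessian at the mode. With both SDs fixed at
zero the random terms vanish and the fit reproduces ordinary logistic
regression exactly (checked against statsmodels GLM to 1e-12 in tests);
with free SDs the fit matches lme4::glmer on the same data to ~0.01 on
coefficients (test oracle via Rscript).

Wald standard errors come from the (β, u) block inverse of the joint
Hessian, conditional on the estimated variance components, as in lme4;
intervals are estimate ± 1.96·SE and p values are two-sided normal.
Conditional modes are the û at the mode, their SDs the square roots of
the u-block diagonal of the inverse Hessian; a level is "significant"
when mode ± 1.96·SD excludes zero. A single-class response is flagged as
separation and the fit excluded from ranking rather than estimated.

* AICc = −2·logLik + 2k + 2k(k+1)/(n−k−1), with k = fixed coefficients +
  estimated variance components and n = movement rows (no
  effective-sample-size correction — none is defined for this design).
* Dredge: all marginality-respecting subsets of the global terms
  {species, sex, log_size, diel, season} ∪ {species:·} — 97 candidates
  for the full set — each refitted with warm-started variance
  components; random intercepts always retained.
* Nested-model removal: a candidate whose term set strictly contains a
  lower-AICc candidate's terms is dropped; Akaike weights are
  renormalised over the survivors.
* Selection: a sole survivor is reported as-is; otherwise the best model
  if its weight ≥ 0.9; otherwise **full (zero-substitution) model
  averaging** with unconditional SEs,
  SE_avg = √(Σ w_m (SE_m² + (β_m − β̄)²)). Full averaging (rather than
  natural averaging over models containing the term) is the default
  because the averaged coefficient is then interpretable as a
  population-level effect including model-selection uncertainty; the
  choice is config-switchable in spirit — the natural average is
  recoverable from the reported per-model tables.
* Nakagawa R²: R²m = σ²_f / (σ²_f + σ²_tag + σ²_rec + π²/3), with σ²_f
  the variance of the fixed-effect linear predictor over the data; R²c
  adds the random variances to the numerator.
* Cross-validation: movement-level 80/20 split, stratified by species,
  seeded; the final model is refitted on the training fraction and AUC
  computed on held-out labels, with unseen grouping levels predicted at
  the population level (zero random effect).
* VIF gate: each fixed-effect design column regressed on the others
  (plus intercept); VIF = 1/(1−R²), flagged above 5.0. The gate is
  reported, never silently enforced.
* Residual report (advisory): lag 1–20 autocorrelation of Pearson
  residuals in data order against the 2/√n white-noise band, and the
  max/min ratio of residual SDs across fitted-probability deciles.

## The synthetic generator

The generator emulates the observation process of a sparse atoll array,
not a continuous track. Receivers sit on a ring (or grid) with
adjacent spacing targeting 2.15 km and nearest-neighbour distances
validated against [0.55, 4.57] km. Each individual alternates:

* **residence bouts** (log-normal, median 40 min, log-SD 0.6) at one
  receiver, transmitting every U(60, 180) s with each transmission
  detected with probability 0.5;
* **movements**, whose latent state (restricted vs out-of-range
  excursion) is Bernoulli with
  logit p = β₀ + β_sp + β_night + β_wet + u_tag + u_receiver.

Restricted recursions last log-normal median 18 min, excursion
recursions 360 min (log-SD 0.55; mode ratio 20); transitions travel to
one of the 3 nearest receivers in direct-time × tortuosity, with
tortuosity log-normal median 2.5 (restricted) vs 25 (excursion), log-SD
0.45, floored at 0.8 — so restricted transitions have RDET around 0.4
and excursions around 0.04, the two signatures the classifier separates.

Defaults describe the emulated system: 102 gray reef and 75 silvertip
tags (sex ratios 76F/26M and 44F/31M; sizes N(119.15, 18.07) and
N(123.56, 19.14) cm), swim speeds 0.69/0.73 m/s, tag delay U(60, 180) s,
detection probability 0.5, and state-model coefficients of realistic
sign and magnitude (−0.475 intercept, +0.449 silvertip, +0.179 night,
+0.159 wet; random SDs 0.65/0.66). The
residence-bout and duration/tortuosity medians are the package's own
choices (nothing in the source system fixes them) and were set once to
realistic reef-shark values giving well-separated states; the default
window is one year from 2014-01-01 so both seasons appear.

Ground truth is recorded **per consecutive-detection gap**: a gap is
truly out-of-range iff at least one excursion-state movement occurred
inside it. This aligns one-to-one with what the pipeline can see — a
bout with zero detections merges its movement into the surrounding gap,
exactly as it would in the field. The raw per-movement state draws are
kept separately for law-of-large-numbers checks on the state model.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: environmental covariates of detection
probability (wind, noise, diel bias), tag collisions, receiver outages,
continuous-space movement between non-neighbouring stations, and
behavioural dependence between consecutive movements. Recovery results
show the estimator chain is correct under the stated model, not that the
model is true of any particular array.

## Problem sizes

Simulation-heavy checks run at reduced scale, chosen once: the
classification-recovery bundle uses 18 tags over 45 days (≈10⁴ labelled
movements); parameter recovery uses 50 replicate tables of 150
individuals × 40 movements (6 000 rows each) with a
species/diel/season global term set; the acceptance script uses 35 tags
over a 120-day window spanning the season boundary. At these sizes the
full suite and the acceptance script each run in minutes on one CPU
while leaving the acceptance margins (coverage, sign recovery, label
accuracy) comfortably wide.

## Known limitations

* Attenuation by design: surviving within-bout gaps (missed pings) are
  truly restricted and dilute the modelled covariate effects relative to
  the generator's movement-level coefficients; the recovered signs and
  ranking are unaffected, absolute magnitudes are conservative.
* The Laplace likelihood is approximate for binary responses with few
  observations per group; variance components can be mildly biased low
  in very sparse designs (the classical Laplace-vs-quadrature gap).
* Model averaging reports coefficient-scale averages; averaged
  predictions on the probability scale are not provided.
* Thresholds are global per species; arrays whose spacing varies wildly
  across regions may warrant per-region thresholds, which the config
  does not currently express.
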