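# Methods

`relapsekit` re-implements, as a tested pipeline over synthetic cohorts, the
computational core of a longitudinal relapse-prediction analysis in alcohol
use disorder (AUD): a prospect-theory model of risk-based choice fit by
maximum likelihood, integral-mode fNIRS oxy-Hb activation analysis during an
emotional go/no-go task and a verbal fluency task (VFT), behavioral task
scoring, and the group-comparison / logistic-regression prognosis stage.

## Risk-based decision model

Each trial offers two gambles (win magnitude `x` JPY with probability `p`).
Option value is

    SV(p, x) = exp(-(-ln p)^γ) · (x / x_scale)^λ

— the one-parameter Prelec probability weight times a power utility.  λ = 1 is
risk-neutral, λ < 1 risk-averse, λ > 1 risk-seeking; γ = 1 is rational
weighting, γ < 1 overweights small and underweights large probabilities (fixed
point at 1/e for every γ).  `x_scale` is the largest magnitude in the
schedule, so utilities live in (0, 1] and the softmax temperature absorbs the
scale.  Choices follow a logistic rule

    P(choose A) = 1 / (1 + exp(-τ (SV_A - SV_B)))

with inverse temperature τ > 0.  The exact utility and choice-rule forms are
not uniquely determined by the qualitative description of the task family;
power utility + one-parameter Prelec + logistic link is the standard
parameterization for this model class and is treated here as an explicit
modeling assumption.  τ is a per-subject nuisance parameter: it is estimated
jointly but never compared across groups.

**Task schedule.** 120 main trials over 3 sessions; probabilities from
{0.1, ..., 0.9}, magnitudes from {500, ..., 10,000} JPY (the original option
set is unpublished; these grids are a design choice).  Main-trial pairs are
non-dominated — one option has the higher probability, the other the larger
magnitude.  Eight catch trials (equal magnitude, strictly higher probability
on one side, e.g. 30%/5,000 vs 50%/5,000) are inserted one per block of 15
main trials, after a random trial of the block.  Catch trials and trials with
no response are excluded from the likelihood; catch accuracy is a QC metric
with a configurable exclusion threshold (default: flag below 6/8).

**Fitting.** Bounded multi-start MLE in log-parameter space (L-BFGS-B),
λ, γ ∈ [0.05, 5], τ ∈ [0.01, 100], default 20 starts: one at
λ = γ = τ = 1 plus log-uniform draws.  The likelihood is multi-modal in
(γ, τ), hence the multi-start; an audit against dense random search (4,000
points) confirms the winner is the global optimum on simulated data.
Estimates pinned at a box edge are flagged `at_bound` (e.g. a pure
response-bias agent drives τ to a bound, the documented non-identifiable
case).  A minimum of 30 usable trials is required.

**Estimation noise at 120 trials.** Parameter recovery is unbiased at the
group medians (checked by simulation), but single-subject fits carry
substantial multiplicative noise and mild shrinkage toward mid-range values —
at small λ the utility curve is nearly flat, so λ is weakly identified from
120 binary choices.  Consequences for the calibrated experiments are discussed
under "What the generator does and does not emulate".

## fNIRS integral-mode analysis

Recordings are channels 22–52 (31 channels over frontal/temporal cortex) at
0.1 s sampling, grouped as: frontopolar {25–28, 36–38, 46–49}, left
frontotemporal {29–31, 39–42, 50–52}, right frontotemporal {22–24, 32–35,
43–45}.  Region labels follow the channel numbers; no anatomical gyrus claims
are made (the source's anatomical captions are internally inconsistent while
the channel numbers are not).

Processing per recording:

1. **Moving average**, 5 s centered window (51 samples at 10 Hz), truncated at
   the edges so series length is preserved; constant and interior-affine
   signals pass through unchanged.
2. **Artifact channel rejection**, deterministic criteria replacing the
   original's manual blinded deletion: band-power fraction in 0.6–2.5 Hz above
   0.5 (`rhythmic_power`), more than 1% of samples beyond 6 robust-z units of
   the smoothing residual (`amplitude_spike`; the residual scale is floored at
   5% of the channel SD so smooth noise-free signals are never flagged), or SD
   below 1e-10 (`flatline`).  All thresholds are config.  The dominant
   cardiac-band frequency is reported per subject as QC only.
3. **Integral-mode baseline**: the original description of the baseline is
   garbled; implemented as the standard two-anchor integral mode — the mean of
   the last 10 s of the pre-task period and the mean of the last 10 s of the
   post-task period, each anchored at the centroid of its averaging window,
   joined linearly and subtracted.  The correction is idempotent and exactly
   annihilates affine signals.  Pre/post periods are the gaps between a task
   block and its neighboring blocks.
4. **Integral activation**: rectangle-rule integral (Δt = 0.1 s) of the
   corrected series over the task block, averaged over kept channels within
   each region (contrast is computed region-wise after channel aggregation,
   matching the three-region reporting granularity).  A region with no
   surviving channels is missing, never zero.
5. **Emotional contrast**: emotional-block integral minus neutral-face-block
   integral, per region.

The whole chain is linear in the input signal, which the tests exploit.

## Behavioral scoring

Go/no-go (32 trials per run, 50% go): false-alarm rate = responses on no-go /
all no-go trials; omission rate = non-responses on go / all go trials (the
source's denominator text is garbled; the symmetric standard definition is
used, consistent with rates printed in multiples of 1/16 and 1/32); RT is the
mean over correct hits only, no outlier trimming by default.  N-back: percent
correct = hits on targets + correct rejections on non-targets over all trials,
per load, plus hit RT.  VFT: number of distinct inflection-group keys across
the three 20 s production blocks — repeats and inflected variants share a key
and count once; keys are taken as given (no linguistic processing).

## Group statistics and prognosis model

Median+IQR-style (skewed/ordinal) variables are compared with the Mann-Whitney
U test (exact p for combined n ≤ 20 without ties, otherwise the tie-corrected
normal approximation; the reported statistic is min(U_x, U_y)); mean±SD-style
variables with Student's t; the sex split with chi-squared.  The test
assignment per variable mirrors the summary style of the study's demographic
table and is configurable.  Spearman's ρ associates the right-frontotemporal
contrast with clinical scores per group.  No multiple-testing correction is
applied anywhere, deliberately mirroring the analysis being reproduced.

The prognosis model is a binomial logistic regression of relapse on six
standardized predictors (right-FT contrast, λ, age of onset, AUDIT, ARRS-SV,
age): Wald 95% CIs (symmetric on the log-odds scale), in-sample sensitivity
and specificity at a 0.5 cutoff with relapse as the positive class, preceded
by a Box-Tidwell linearity check (x·ln x interaction terms added to the
logit; x and x·ln x are near-collinear, so only non-convergence or unstable
Wald SEs mark the check undetermined).  Six predictors for ~41 subjects is a
serious events-per-variable problem inherited from the reproduced design; it
is documented here as a caveat, not repaired.  Perfect separation is flagged
and CIs reported unbounded, with a lightly ridged GLM providing the predicted
classes.

## Synthetic-cohort generator

Defaults are the study's conditions: 24 abstainers (21 M / 3 F) and 17
relapsers (14 M / 3 F); sex is assigned as exact counts.  Mean±SD covariates
are normal; median+IQR covariates are lognormal matched to the median
(exactly) and the quartile ratio (σ = ln(q75/q25)/(2·0.6745)) — printed IQRs
are generally not log-symmetric, so a two-parameter family cannot match both
quartiles, and the ratio is the matched quantity.  One printed row
(abstainer BDI-II) has its median outside its own IQR and borrows the other
group's quartile ratio.

Injected effects (everything else is a configured null):

* λ truth: lognormal with medians 0.530 (relapsers) vs 0.241 (abstainers) and
  IQR-matched spreads; γ lognormal centered at 1 with σ = 0.25 in both groups;
  τ lognormal, median 10, σ = 0.4 — a realistic choice-consistency level
  (~80–90% of choices follow the higher subjective value at typical SV gaps),
  chosen once and never revisited.
* Right-FT emotional contrast truth: normal, 30.5 (SD 77.2) vs −33.6
  (SD 74.9), means and SDs from the reported medians/IQRs; other regions and
  all VFT integrals are group-free.
* Non-emotional go/no-go RT: lognormal medians 600.29 vs 528.73 ms; emotional
  RT 724.81 vs 659.81 ms.  Error probabilities fixed per group at the reported
  medians (FA 3.13% both; omission 6.25% vs 3.13%).  With only 16 no-go trials
  per block, the median of observed per-subject rates sits below the
  generating probability (binomial discreteness); this is left as-is.
* ARRS-SV is drawn jointly with the contrast truth via a Gaussian copula,
  ρ = −0.439 in abstainers and −0.067 in relapsers.
* N-back: 1-back 95% / 550 ms, 2-back 85% / 650 ms, identical across groups
  (the reproduced analysis reports only "no significant differences"); VFT
  counts Poisson with means 14.5 / 14.0.

fNIRS recordings are built per channel as boxcar(block) ⊗ double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6 — purely a test-harness choice), plus
1/f noise (SD 0.3), white noise (SD 0.05), a cardiac sinusoid near 1.1 Hz
(amplitude 0.15), Poisson motion spikes (0.3/min, amplitude ~3), and
per-channel gain jitter (SD 0.15), in the same concentration units as the
target integrals.  Go/no-go runs use 48 s blocks (32 trials × 1.5 s) with 30 s
rests in the order control–emotional–control–neutral–control; VFT timing is
the printed 30 s pre / 60 s production / 70 s post.  Block amplitudes are
back-computed from each subject's target contrast through the unit-response
integral of the *actual* processing chain, so with all noise amplitudes at
zero the pipeline recovers the configured truth to floating-point accuracy —
the closed-loop oracle used throughout the tests.

An optional closed-loop mode assigns relapse by a logistic model on the
generated markers (β = ln 0.161, ln 7.037 on standardized contrast and ln λ,
intercept at the study's base rate) instead of drawing markers conditional on
a pre-assigned group; the default mode is group-first.

**What the generator does and does not emulate.**  It reproduces the reported
group-level distributions, the direction and size of the three injected
effects, and raw-stream structure (trial counts, sampling rate, block design).
It does not emulate within-group correlations between markers (assumed
independent), real fNIRS optics (no Beer-Lambert stage, no short channels),
real RT distributions beyond lognormality, or lexical content.  A passing
suite therefore demonstrates that the pipeline recovers what the generator
encodes at the study's printed effect sizes and sample sizes — not that the
original clinical findings would replicate.

One consequence is quantified rather than hidden: the reported λ quartiles
come from *fitted* values, which already contain estimation noise.  Drawing
*true* λ from those quartiles and refitting (as the calibration experiments
prescribe) counts that noise twice and adds the 120-trial shrinkage described
above, so the synthetic 17-vs-24 Mann-Whitney comparison is noticeably less
powerful than the single observed study realization: across seeded replicates
its median p sits in the 0.02–0.2 range rather than below 0.01.  Group medians
of the refit λ remain within ±25% of the calibration values, and the large-n
recovery experiments (170/240 subjects) are unbiased.

## Problem sizes and numerical choices

Default experiment sizes: 120 trials/subject, 41 subjects/cohort, 20-replicate
summaries for seed-level claims; recovery experiments use 10× group sizes
(170/240); logistic recovery uses n = 20,000.  Optimization tolerances are
scipy defaults; NLL is computed with `logaddexp` for stability; rectangle-rule
quadrature at 10 Hz differs from trapezoid by < 1% on smooth responses (tested).
Ties in the dominance check (equal p and equal x) are not valid catch pairs.
All generators and fits are deterministic under (config, seed); per-subject
streams come from spawned `SeedSequence` children.

## Known limitations

* The utility/choice-rule forms and the artifact-rejection thresholds are
  reconstructions of under-specified procedures; both are config-exposed.
* Sensitivity/specificity are in-sample at a fixed 0.5 cutoff — no
  cross-validation, matching the reproduced analysis.
* The events-per-variable imbalance of the 6-predictor logistic model is
  inherited and documented, not corrected.
* Within-group marker independence is an assumption; the config exposes the
  ARRS-contrast correlation only.
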